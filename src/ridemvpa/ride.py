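"""Residue iteration decomposition (RIDE) into S- and C-clusters.

RIDE separates event-related EEG into component clusters defined by their
latency behaviour: the S-cluster is locked to stimulus onset, while the
C-cluster has a latency that varies from trial to trial and must be
estimated iteratively.  No response-locked R-cluster is estimated here —
with rare responses (and none on Nogo trials) it cannot be estimated
reliably, so the C-cluster absorbs response-related activity.

The scheme alternates two steps until the latencies stabilize:

* **decompose** (given latencies): ``S = median over trials of
  (trial − C shifted to its latency)``, tapered to the S window, and
  ``C = median over trials of the S-residual aligned to the current
  latency``, tapered to the C window — themselves alternated a few times so
  the two clusters mutually separate within overlapping windows;
* **re-estimate** (given waveforms): per-trial latency maximizing the
  channel-summed cross-covariance of the C template with the S-residual
  inside the search window (ties break toward the smallest absolute shift).

Median (not mean) waveforms make the estimates robust to residual artifact
trials.  One latency is estimated per trial (shared across channels);
waveforms are estimated channel-wise.

Two numerical safeguards stabilize the iteration at single-trial SNR:
the cross-covariance is lightly smoothed over candidate shifts before the
peak is picked (suppressing narrow noise peaks), and each iteration's
latency update is confined to a shrinking trust region around the current
estimate, which prevents individual trials from locking onto distant noise
peaks and feeding them back into the template.  Initial latencies come from
matching each raw trial against the trial-median waveform windowed to the
*late half* of the C window — the part of the average least contaminated by
the stimulus-locked cluster, whose fixed latency would otherwise bias the
match toward a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal.windows import tukey

from .task_sim import Epochs

__all__ = ["RideConfig", "RideResult", "ride_decompose", "estimate_latencies",
           "single_trial_clusters"]


@dataclass(frozen=True)
class RideConfig:
    """RIDE windows (ms, stimulus-locked) and iteration controls.

    Defaults: S window −200..600 ms, C window (and search window) 150..800
    ms; convergence when the median absolute latency change drops to
    ``latency_tol_samples``.  ``n_inner`` alternating S/C updates run inside
    each latency iteration; ``score_smooth_ms`` is the width of the Gaussian
    applied to the template-matching score over candidate shifts, and the
    trust region shrinks geometrically from ``trust_init_ms`` to
    ``trust_min_ms``.
    """

    s_window_ms: tuple[float, float] = (-200.0, 600.0)
    c_window_ms: tuple[float, float] = (150.0, 800.0)
    c_search_window_ms: tuple[float, float] | None = None  # default: c_window_ms
    max_iter: int = 20
    latency_tol_samples: int = 1
    taper_fraction: float = 0.1  # cosine edge fraction of each window side
    n_inner: int = 10
    score_smooth_ms: float = 30.0
    trust_init_ms: float = 80.0
    trust_min_ms: float = 25.0
    trust_shrink: float = 0.7

    @property
    def search_window_ms(self) -> tuple[float, float]:
        return self.c_search_window_ms or self.c_window_ms


@dataclass
class RideResult:
    """S/C cluster waveforms plus per-trial C latencies.

    ``c_latency_samples`` are absolute sample indices on the epoch time axis
    marking where the C template centre sits on each trial;
    ``ref_latency_sample`` is the template's own anchor (the median initial
    latency), so the trial-``i`` C contribution is the template shifted by
    ``c_latency_samples[i] − ref_latency_sample``.
    """

    s_waveform: np.ndarray  # (channels, time)
    c_waveform: np.ndarray  # (channels, time), anchored at ref_latency_sample
    c_latency_samples: np.ndarray  # (trials,)
    ref_latency_sample: int
    s_latency_sample: int  # stimulus onset (sample index of t = 0)
    n_iterations: int
    converged: bool
    degenerate: bool = False
    latency_history: list[np.ndarray] = field(default_factory=list)
    times_ms: np.ndarray | None = None
    srate_hz: float | None = None

    def c_latency_ms(self) -> np.ndarray:
        return self.times_ms[self.c_latency_samples]


def _window_taper(times_ms: np.ndarray, window_ms: tuple[float, float],
                  frac: float) -> np.ndarray:
    """Cosine-edged (Tukey) taper supported on the window, zero outside."""
    mask = (times_ms >= window_ms[0] - 1e-9) & (times_ms < window_ms[1] - 1e-9)
    n = int(mask.sum())
    out = np.zeros_like(times_ms)
    if n:
        out[mask] = tukey(n, alpha=2.0 * frac)
    return out


def _shift_zero(x: np.ndarray, shift: int) -> np.ndarray:
    """Shift along the last axis with zero fill (positive = later)."""
    if shift == 0:
        return x.copy()
    out = np.zeros_like(x)
    if shift > 0:
        out[..., shift:] = x[..., :-shift]
    else:
        out[..., :shift] = x[..., -shift:]
    return out


def _match_scores(residuals: np.ndarray, template: np.ndarray,
                  search_window: tuple[int, int], ref_sample: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Channel-summed cross-covariance per trial over candidate shifts."""
    n_t = residuals.shape[-1]
    nfft = 1 << int(np.ceil(np.log2(2 * n_t)))
    ft = np.fft.rfft(template, nfft, axis=-1)
    fr = np.fft.rfft(residuals, nfft, axis=-1)
    # corr[..., d mod nfft] = sum_t template[t] * residual[t + d]
    corr = np.fft.irfft(fr * np.conj(ft), nfft, axis=-1).sum(axis=-2)
    shifts = np.arange(search_window[0] - ref_sample,
                       search_window[1] - ref_sample + 1)
    return shifts, np.atleast_2d(corr[..., shifts % nfft])


def estimate_latencies(residuals: np.ndarray, template: np.ndarray,
                       search_window: tuple[int, int],
                       ref_sample: int = 0,
                       smooth_sigma: float = 0.0,
                       current: np.ndarray | None = None,
                       trust: int | None = None) -> np.ndarray:
    """Template-matching latency estimate per trial.

    For each trial, returns the absolute sample index ``L`` inside
    ``search_window`` (inclusive bounds, in samples) maximizing the
    channel-summed cross-covariance between the template (anchored at
    ``ref_sample``) and the residual, optionally smoothed over shifts
    (``smooth_sigma`` in samples) and restricted to ``|L − current|
    <= trust``.  Ties break toward the smallest ``|L − ref_sample|``, then
    toward the earlier latency.
    """
    lo, hi = search_window
    if hi < lo:
        raise ValueError("empty search window")
    if not np.any(template):
        raise ValueError("template is all zero")
    shifts, scores = _match_scores(residuals, template, search_window, ref_sample)
    if smooth_sigma > 0:
        scores = gaussian_filter1d(scores, smooth_sigma, axis=-1)

    # candidate order implements the tie-break: smallest |shift|, then earlier
    order = np.lexsort((shifts, np.abs(shifts)))
    shifts_ord = shifts[order]
    scores_ord = scores[:, order]
    if trust is not None and current is not None:
        lat_ord = ref_sample + shifts_ord
        allowed = np.abs(lat_ord[None, :] - np.asarray(current)[:, None]) <= trust
        scores_ord = np.where(allowed, scores_ord, -np.inf)
    best = scores_ord.max(axis=1, keepdims=True)
    first_max = np.argmax(scores_ord >= best - 1e-12 * np.maximum(np.abs(best), 1.0),
                          axis=1)
    return ref_sample + shifts_ord[first_max]


def _initial_latencies(data: np.ndarray, times_ms: np.ndarray,
                       search: tuple[int, int], c_window_ms: tuple[float, float],
                       taper_frac: float, smooth_sigma: float) -> np.ndarray:
    """Initial latencies from matching trials against the late-window average.

    The template is the trial-median waveform tapered to the late half of
    the C window, where the stimulus-locked cluster has decayed; matching
    raw single trials against it yields latency estimates free of the
    constant-latency bias that a full-window average template would impose.
    """
    lo_ms = (c_window_ms[0] + c_window_ms[1]) / 2.0
    taper = _window_taper(times_ms, (lo_ms, c_window_ms[1]), taper_frac)
    template = np.median(data, axis=0) * taper
    if not np.any(template):
        return np.full(data.shape[0], (search[0] + search[1]) // 2)
    ref = int(np.argmax(np.abs(template).sum(axis=0)))
    return estimate_latencies(data, template, search, ref_sample=ref,
                              smooth_sigma=smooth_sigma)


def _decompose_given_latencies(data: np.ndarray, lat: np.ndarray, ref: int,
                               s_taper: np.ndarray, c_taper: np.ndarray,
                               n_inner: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Alternate S/C median estimates at fixed latencies until they separate."""
    c_wave = np.zeros(data.shape[1:])
    s_wave = np.zeros(data.shape[1:])
    resid = data
    for _ in range(n_inner):
        c_contrib = np.stack([_shift_zero(c_wave, int(li - ref)) for li in lat])
        s_wave = np.median(data - c_contrib, axis=0) * s_taper
        resid = data - s_wave
        aligned = np.stack([_shift_zero(resid[i], int(ref - lat[i]))
                            for i in range(len(lat))])
        c_wave = np.median(aligned, axis=0) * c_taper
    return s_wave, c_wave, resid


def ride_decompose(epochs: Epochs, config: RideConfig | None = None) -> RideResult:
    """Decompose epochs into stimulus-locked S and latency-variable C clusters."""
    cfg = config or RideConfig()
    if epochs.n_trials < 10:
        raise ValueError("RIDE needs at least 10 trials")
    times = epochs.times_ms
    step_ms = 1000.0 / epochs.srate_hz
    for w in (cfg.s_window_ms, cfg.c_window_ms, cfg.search_window_ms):
        if w[0] < times[0] - 1e-9 or w[1] > times[-1] + step_ms + 1e-9:
            raise ValueError(f"window {w} outside the epoch")

    data = epochs.data
    s_taper = _window_taper(times, cfg.s_window_ms, cfg.taper_fraction)
    c_taper = _window_taper(times, cfg.c_window_ms, cfg.taper_fraction)
    search_idx = (int(np.searchsorted(times, cfg.search_window_ms[0])),
                  int(np.searchsorted(times, cfg.search_window_ms[1], side="right")) - 1)
    smooth = cfg.score_smooth_ms / step_ms
    trust = max(1, int(round(cfg.trust_init_ms / step_ms)))
    trust_min = max(1, int(round(cfg.trust_min_ms / step_ms)))

    lat = _initial_latencies(data, times, search_idx, cfg.c_window_ms,
                             cfg.taper_fraction, smooth)
    ref = int(np.round(np.median(lat)))
    history = [lat.copy()]

    s_wave = np.zeros(data.shape[1:])
    c_wave = np.zeros(data.shape[1:])
    converged = False
    degenerate = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        s_wave, c_wave, resid = _decompose_given_latencies(
            data, lat, ref, s_taper, c_taper, cfg.n_inner)
        if np.max(np.abs(c_wave)) < 1e-12:
            degenerate = True
            converged = True
            c_wave = np.zeros_like(c_wave)
            break
        new_lat = estimate_latencies(resid, c_wave, search_idx, ref_sample=ref,
                                     smooth_sigma=smooth, current=lat, trust=trust)
        change = np.median(np.abs(new_lat - lat))
        lat = new_lat
        history.append(lat.copy())
        trust = max(trust_min, int(trust * cfg.trust_shrink))
        if change <= cfg.latency_tol_samples and n_iter >= 3:
            converged = True
            break

    return RideResult(
        s_waveform=s_wave,
        c_waveform=c_wave,
        c_latency_samples=lat,
        ref_latency_sample=ref,
        s_latency_sample=int(np.searchsorted(times, 0.0)),
        n_iterations=n_iter,
        converged=converged,
        degenerate=degenerate,
        latency_history=history,
        times_ms=times.copy(),
        srate_hz=epochs.srate_hz,
    )


def single_trial_clusters(epochs: Epochs, result: RideResult) -> tuple[Epochs, Epochs]:
    """Single-trial S- and C-cluster data for downstream ICA/MVPA.

    ``S-trial[i] = trial[i] − C template shifted to that trial's latency`` and
    ``C-trial[i] = trial[i] − S waveform``; shifts that would push the C
    template outside the epoch are zero-padded and flagged in a
    ``c_shift_clipped`` metadata column.  Both outputs inherit the trial
    metadata.
    """
    if result.c_latency_samples.shape[0] != epochs.n_trials:
        raise ValueError("result does not match these epochs")
    n_t = epochs.n_times
    support = np.flatnonzero(np.abs(result.c_waveform).max(axis=0) > 1e-12)
    s_data = np.empty_like(epochs.data)
    clipped = np.zeros(epochs.n_trials, dtype=bool)
    for i, li in enumerate(result.c_latency_samples):
        d = int(li - result.ref_latency_sample)
        s_data[i] = epochs.data[i] - _shift_zero(result.c_waveform, d)
        if support.size:
            clipped[i] = (support[0] + d < 0) or (support[-1] + d >= n_t)
    c_data = epochs.data - result.s_waveform[None]

    def _wrap(arr: np.ndarray) -> Epochs:
        trials = epochs.trials.copy()
        trials["c_shift_clipped"] = clipped
        return Epochs(data=arr, srate_hz=epochs.srate_hz,
                      times_ms=epochs.times_ms.copy(), montage=epochs.montage,
                      trials=trials, unit_label=epochs.unit_label)

    return _wrap(s_data), _wrap(c_data)
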