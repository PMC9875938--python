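"""Epoch-level preprocessing chain.

The chain mirrors a conventional ERP workflow and runs in a fixed order:
band-pass filter -> resample -> automated artifact rejection -> current
source density (CSD) transform -> baseline correction.  :func:`run_chain`
is the only entry point that applies more than one step and always uses
this order.

Rejection is threshold-based only (absolute amplitude and a sliding-window
flatline detector); there is no visual screening and no ocular ICA, since
the simulated data carry no ocular sources.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .task_sim import Epochs

__all__ = [
    "PreprocessConfig",
    "bandpass_filter",
    "resample",
    "reject_artifacts",
    "csd_transform",
    "baseline_correct",
    "run_chain",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the fixed preprocessing chain.

    Amplitude thresholds are in µV (trials beyond ±100 µV, or with less than
    0.5 µV peak-to-peak activity within any 100 ms window, are discarded).
    """

    low_hz: float = 0.5
    high_hz: float = 40.0
    filter_order: int = 4
    target_srate_hz: float = 256.0
    amp_limit: float = 100.0
    flat_limit: float = 0.5
    flat_window_ms: float = 100.0
    csd_stiffness: int = 4
    csd_lambda: float = 1e-5
    csd_n_legendre: int = 50
    baseline_window_ms: tuple[float, float] = (-300.0, 0.0)


def bandpass_filter(epochs: Epochs, low_hz: float = 0.5, high_hz: float = 40.0,
                    order: int = 4) -> Epochs:
    """Zero-phase Butterworth band-pass, applied forward-backward per trial/channel."""
    nyq = epochs.srate_hz / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges ({low_hz}, {high_hz}) invalid for srate {epochs.srate_hz}"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=epochs.srate_hz, output="sos")
    out = epochs.copy()
    out.data = signal.sosfiltfilt(sos, out.data, axis=-1)
    return out


def resample(epochs: Epochs, target_hz: float) -> Epochs:
    """Polyphase anti-aliased resampling; the time axis keeps its origin."""
    if target_hz <= 0:
        raise ValueError("target rate must be positive")
    if target_hz >= epochs.srate_hz:
        raise ValueError("target rate must be below the current rate")
    from fractions import Fraction

    frac = Fraction(target_hz / epochs.srate_hz).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(epochs.data, up, down, axis=-1)
    n_new = data.shape[-1]
    times = epochs.times_ms[0] + np.arange(n_new) * 1000.0 / target_hz
    return Epochs(data=data, srate_hz=target_hz, times_ms=times,
                  montage=epochs.montage, trials=epochs.trials.copy(),
                  unit_label=epochs.unit_label)


def reject_artifacts(
    epochs: Epochs,
    amp_limit: float = 100.0,
    flat_limit: float = 0.5,
    flat_window_ms: float = 100.0,
) -> tuple[Epochs, pd.DataFrame]:
    """Drop trials exceeding ±amp_limit or flat within any sliding window.

    A trial is flagged ``amplitude_exceeds`` if any channel sample leaves
    ±``amp_limit``, or ``flatline`` if any channel's peak-to-peak within some
    ``flat_window_ms`` window falls below ``flat_limit`` (dead channel /
    disconnected electrode signature).  Returns the kept epochs and a
    per-trial log (kept, reason, offending_channel).
    """
    if amp_limit <= 0 or flat_limit <= 0:
        raise ValueError("limits must be positive")
    win = int(round(flat_window_ms * epochs.srate_hz / 1000.0))
    if win > epochs.n_times:
        raise ValueError("flat window longer than the epoch")
    win = max(win, 2)

    data = epochs.data
    amp_bad = np.abs(data) > amp_limit  # (trials, ch, t)
    amp_bad_ch = amp_bad.any(axis=2)

    mx = maximum_filter1d(data, size=win, axis=-1)
    mn = minimum_filter1d(data, size=win, axis=-1)
    # restrict to window positions fully inside the epoch
    lo, hi = win // 2, data.shape[-1] - (win - 1 - win // 2)
    ptp = (mx - mn)[:, :, lo:hi]
    flat_ch = (ptp < flat_limit).any(axis=2)

    reasons, offenders, kept = [], [], []
    labels = epochs.montage.labels
    for i in range(epochs.n_trials):
        if amp_bad_ch[i].any():
            kept.append(False)
            reasons.append("amplitude_exceeds")
            offenders.append(labels[int(np.argmax(amp_bad_ch[i]))])
        elif flat_ch[i].any():
            kept.append(False)
            reasons.append("flatline")
            offenders.append(labels[int(np.argmax(flat_ch[i]))])
        else:
            kept.append(True)
            reasons.append("none")
            offenders.append(None)

    log = pd.DataFrame({"kept": kept, "reason": reasons, "offending_channel": offenders},
                       index=epochs.trials.index)
    keep_mask = np.asarray(kept)
    out = Epochs(data=data[keep_mask], srate_hz=epochs.srate_hz,
                 times_ms=epochs.times_ms.copy(), montage=epochs.montage,
                 trials=epochs.trials.loc[keep_mask].copy(),
                 unit_label=epochs.unit_label)
    return out, log


def csd_transform(epochs: Epochs, m: int = 4, lam: float = 1e-5,
                  n_legendre: int = 50) -> Epochs:
    """Spherical-spline surface Laplacian (current source density).

    Wraps MNE's spherical-spline CSD on a 9.5 cm sphere built from the
    montage's unit-sphere positions.  The output is reference-free: adding a
    constant to all channels leaves it unchanged.  Units become µV/m².
    """
    import mne

    mne.set_log_level("ERROR")
    pos = epochs.montage.positions
    if len(np.unique(np.round(pos, 9), axis=0)) != len(pos):
        raise ValueError("duplicate electrode positions make the spline system singular")

    head_radius = 0.095
    info = mne.create_info(list(epochs.montage.labels), epochs.srate_hz, "eeg")
    dig = mne.channels.make_dig_montage(
        ch_pos={lab: p * head_radius for lab, p in zip(epochs.montage.labels, pos)},
        coord_frame="head",
    )
    info.set_montage(dig)
    arr = mne.EpochsArray(epochs.data * 1e-6, info,
                          tmin=epochs.times_ms[0] / 1000.0, verbose="ERROR")
    csd = mne.preprocessing.compute_current_source_density(
        arr, sphere=(0.0, 0.0, 0.0, head_radius), lambda2=lam,
        stiffness=m, n_legendre_terms=n_legendre,
    )
    return Epochs(data=csd.get_data(copy=True) * 1e6, srate_hz=epochs.srate_hz,
                  times_ms=epochs.times_ms.copy(), montage=epochs.montage,
                  trials=epochs.trials.copy(), unit_label="CSD (µV/m²)")


def baseline_correct(epochs: Epochs, window_ms: tuple[float, float] = (-300.0, 0.0)) -> Epochs:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    mask = epochs.time_mask(*window_ms)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def run_chain(epochs: Epochs, config: PreprocessConfig | None = None,
              apply_csd: bool = True) -> tuple[Epochs, pd.DataFrame]:
    """Apply the full chain in its fixed order; returns epochs + rejection log."""
    cfg = config or PreprocessConfig()
    out = bandpass_filter(epochs, cfg.low_hz, cfg.high_hz, cfg.filter_order)
    if cfg.target_srate_hz < out.srate_hz:
        out = resample(out, cfg.target_srate_hz)
    out, log = reject_artifacts(out, cfg.amp_limit, cfg.flat_limit, cfg.flat_window_ms)
    if apply_csd:
        out = csd_transform(out, cfg.csd_stiffness, cfg.csd_lambda, cfg.csd_n_legendre)
    out = baseline_correct(out, cfg.baseline_window_ms)
    return out, log
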