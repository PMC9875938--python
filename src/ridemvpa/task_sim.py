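"""Simulated Simon Go/Nogo experiment with ground-truth EEG sources.

The generator emulates a hybrid Simon Go/Nogo task: on each trial a letter
("A" or "B") appears left or right of fixation; letter identity determines the
responding hand on Go trials, and the spatial correspondence between stimulus
side and responding hand defines congruency.  Nogo trials require withholding
the response; there, left-"A" and right-"B" count as congruent.

Simulated EEG epochs contain two ground-truth sources:

* an **S source** with fixed latency relative to stimulus onset
  (stimulus-locked, perceptual/attentional), and
* a **C source** whose single-trial latency varies and is coupled to the
  reaction time (central/translational, latency-variable),

each a unit-norm scalp topography times a Gaussian-windowed half-cycle
waveform, plus spatially correlated 1/f (pink) background noise and white
sensor noise.  Everything needed to score downstream recovery (topographies,
latencies, amplitudes, seeds) is returned in :class:`SimTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TaskDesign",
    "BehaviourParams",
    "TruthParams",
    "Montage",
    "Epochs",
    "SimTruth",
    "generate_trial_table",
    "simulate_behaviour",
    "simulate_epochs",
    "make_montage",
]

GO, NOGO = "Go", "Nogo"
CONGRUENT, INCONGRUENT = "congruent", "incongruent"

# Letter -> responding hand mapping of the task ("A" left hand, "B" right).
_HAND = {"A": "left", "B": "right"}
_OPPOSITE = {"left": "right", "right": "left"}


# ---------------------------------------------------------------------------
# parameter sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskDesign:
    """Trial-count structure of the Simon Go/Nogo session.

    Defaults follow the reference design: 720 trials, 70 % Go / 30 % Nogo,
    50 % congruent, 6 blocks of 120 trials with all four trial types evenly
    distributed across blocks.
    """

    n_trials: int = 720
    go_proportion: float = 0.70
    congruent_proportion: float = 0.50
    n_blocks: int = 6
    stim_duration_ms: float = 200.0
    response_deadline_ms: float = 1700.0
    iti_range_ms: tuple[float, float] = (1300.0, 1700.0)

    def validate(self) -> None:
        if not (0.0 <= self.go_proportion <= 1.0 and 0.0 <= self.congruent_proportion <= 1.0):
            raise ValueError("proportions must lie in [0, 1]")
        if self.n_blocks < 1 or self.n_trials < 1:
            raise ValueError("n_trials and n_blocks must be positive")
        if self.n_trials % self.n_blocks:
            raise ValueError(
                f"n_trials={self.n_trials} not divisible by n_blocks={self.n_blocks}"
            )
        per_block = self.n_trials // self.n_blocks
        for p_type in (self.go_proportion, 1.0 - self.go_proportion):
            n_type = per_block * p_type
            for p_cong in (self.congruent_proportion, 1.0 - self.congruent_proportion):
                cell = n_type * p_cong
                if abs(cell - round(cell)) > 1e-9:
                    raise ValueError(
                        "per-block cell counts are not integral under the given "
                        f"proportions (block size {per_block}, cell {cell:.3f})"
                    )

    @property
    def trials_per_block(self) -> int:
        return self.n_trials // self.n_blocks


@dataclass(frozen=True)
class BehaviourParams:
    """Behavioural generating model.

    Go RTs are log-normal (right-skewed, positive support) with a congruency
    effect on the mean; responses slower than the deadline become misses.
    Nogo outcomes are Bernoulli false alarms with a *higher* false-alarm rate
    on congruent trials (automatic response capture).  Default rates put the
    expected Nogo accuracies at 93.9 % (congruent) and 95.3 % (incongruent).
    """

    rt_mean_ms: dict[str, float] = field(
        default_factory=lambda: {CONGRUENT: 539.18, INCONGRUENT: 549.63}
    )
    rt_sd_ms: float = 80.0
    go_error_rate: float = 0.022
    nogo_false_alarm_rate: dict[str, float] = field(
        default_factory=lambda: {CONGRUENT: 0.061, INCONGRUENT: 0.047}
    )

    # between-subject heterogeneity (used by sample_subject_behaviour)
    subject_rt_shift_sd_ms: float = 15.0
    subject_congruency_effect_sd_ms: float = 12.0
    subject_fa_log_sd: float = 0.4

    def validate(self) -> None:
        if self.rt_mean_ms[CONGRUENT] >= self.rt_mean_ms[INCONGRUENT]:
            raise ValueError("congruent mean RT must be below incongruent mean RT")
        probs = [self.go_error_rate, *self.nogo_false_alarm_rate.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.nogo_false_alarm_rate[CONGRUENT] < self.nogo_false_alarm_rate[INCONGRUENT]:
            raise ValueError("congruent false-alarm rate must be >= incongruent rate")
        if self.rt_sd_ms < 0:
            raise ValueError("rt_sd_ms must be non-negative")


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth source model for :func:`simulate_epochs`.

    Amplitudes are in µV applied to unit-norm topographies; the C latency is
    ``c_intercept_ms + c_rt_slope * RT + jitter`` for trials with a response
    and uses a pseudo-RT from the same log-normal family for Nogo trials
    (which carry no response marker).  ``amplitude_by_condition`` maps
    congruency to ``(s_amp, c_amp)`` scale factors; the default 15 % C
    amplitude increase on incongruent trials is the planted condition effect.
    An optional box-car effect (topography times constant within
    ``effect_window_ms``, added to incongruent trials only) supports
    sensitivity analyses with a known effect window.
    """

    srate_hz: float = 500.0
    epoch_window_ms: tuple[float, float] = (-2000.0, 2000.0)
    s_latency_ms: float = 200.0
    s_width_ms: float = 150.0
    c_width_ms: float = 200.0
    s_amp: float = 35.0
    c_amp: float = 30.0
    amplitude_by_condition: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {CONGRUENT: (1.0, 1.0), INCONGRUENT: (1.0, 1.15)}
    )
    c_intercept_ms: float = 150.0
    c_rt_slope: float = 0.55
    c_jitter_sd_ms: float = 25.0
    pseudo_rt_mean_ms: dict[str, float] = field(
        default_factory=lambda: {CONGRUENT: 520.0, INCONGRUENT: 535.0}
    )
    pseudo_rt_sd_ms: float = 80.0
    pink_sd: float = 1.5
    white_sd: float = 1.0
    n_noise_patterns: int = 10
    effect_window_ms: tuple[float, float] | None = None
    effect_amp: float = 0.0


def sample_subject_behaviour(base: BehaviourParams, seed: int) -> BehaviourParams:
    """Draw one subject's behavioural parameters around the group values.

    A common RT shift (shared by both congruency conditions, so the
    within-subject congruency effect is preserved) and a log-normal
    multiplier on the false-alarm rates reproduce the between-subject
    spread that group-level effect sizes are computed against.
    """
    rng = np.random.default_rng(seed)
    shift = rng.normal(0.0, base.subject_rt_shift_sd_ms)
    base_effect = base.rt_mean_ms[INCONGRUENT] - base.rt_mean_ms[CONGRUENT]
    effect = max(0.5, base_effect
                 + rng.normal(0.0, base.subject_congruency_effect_sd_ms))
    # mean-one log-normal multiplier keeps the group-average rates intact
    sd = base.subject_fa_log_sd
    fa_mult = float(np.exp(rng.normal(-0.5 * sd**2, sd)))
    return replace(
        base,
        rt_mean_ms={
            CONGRUENT: base.rt_mean_ms[CONGRUENT] + shift,
            INCONGRUENT: base.rt_mean_ms[CONGRUENT] + shift + effect,
        },
        nogo_false_alarm_rate={
            k: min(1.0, v * fa_mult) for k, v in base.nogo_false_alarm_rate.items()
        },
    )


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Montage:
    """Electrode labels plus unit-sphere 3-D positions."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm rows

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("channel labels must be unique")
        if pos.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("electrode positions must lie on the unit sphere")

    @property
    def n_channels(self) -> int:
        return len(self.labels)


@dataclass
class Epochs:
    """Epoched multi-channel EEG: trials x channels x time, with metadata.

    The time axis is uniform and half-open: sample ``k`` sits at
    ``times_ms[0] + k * 1000 / srate_hz`` and the nominal window end is
    excluded.
    """

    data: np.ndarray  # (n_trials, n_channels, n_times)
    srate_hz: float
    times_ms: np.ndarray  # (n_times,)
    montage: Montage
    trials: pd.DataFrame
    unit_label: str = "µV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        n_tr, n_ch, n_t = self.data.shape
        if n_ch != self.montage.n_channels:
            raise ValueError("channel count does not match montage")
        if n_tr != len(self.trials):
            raise ValueError("trial count does not match trial table")
        if n_t != self.times_ms.size:
            raise ValueError("time axis length does not match data")
        step = 1000.0 / self.srate_hz
        if n_t > 1 and not np.allclose(np.diff(self.times_ms), step, atol=1e-6):
            raise ValueError("time axis must be uniform at 1/srate")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "Epochs":
        return Epochs(
            data=self.data.copy(),
            srate_hz=self.srate_hz,
            times_ms=self.times_ms.copy(),
            montage=self.montage,
            trials=self.trials.copy(),
            unit_label=self.unit_label,
        )

    def time_mask(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Boolean mask for the half-open window [start_ms, end_ms)."""
        return (self.times_ms >= start_ms - 1e-9) & (self.times_ms < end_ms - 1e-9)


@dataclass
class SimTruth:
    """Ground truth of one simulated session, for recovery scoring."""

    s_topography: np.ndarray
    c_topography: np.ndarray
    s_latency_ms: float
    c_latency_ms: np.ndarray  # per trial
    amplitude_by_condition: dict[str, tuple[float, float]]
    noise_params: tuple[float, float]
    seed: int
    s_waveform: np.ndarray | None = None  # canonical S time course on the epoch grid
    c_waveform_shape: np.ndarray | None = None  # C half-cycle, latency-centred


# ---------------------------------------------------------------------------
# trial table
# ---------------------------------------------------------------------------

def generate_trial_table(design: TaskDesign, seed: int) -> pd.DataFrame:
    """Build a randomized trial table with exact per-block balancing.

    Each block contains identical counts of the four trial-type x congruency
    cells; order is shuffled independently per block.  Letter identity is
    balanced within each cell, and stimulus side follows from congruency via
    the letter->hand mapping (side equals the responding-hand side on
    congruent trials, the opposite side on incongruent ones; the same rule
    encodes Nogo congruency as left-"A"/right-"B").
    """
    design.validate()
    rng = np.random.default_rng(seed)
    per_block = design.trials_per_block
    n_go = int(round(per_block * design.go_proportion))
    cells = []
    for trial_type, n_type in ((GO, n_go), (NOGO, per_block - n_go)):
        n_con = int(round(n_type * design.congruent_proportion))
        cells.append((trial_type, CONGRUENT, n_con))
        cells.append((trial_type, INCONGRUENT, n_type - n_con))

    rows: list[dict] = []
    for block in range(design.n_blocks):
        block_rows: list[dict] = []
        for trial_type, congruency, n_cell in cells:
            letters = np.array(["A", "B"])[(np.arange(n_cell) + block) % 2]
            for letter in letters:
                hand_side = _HAND[letter]
                side = hand_side if congruency == CONGRUENT else _OPPOSITE[hand_side]
                block_rows.append(
                    dict(
                        block=block,
                        trial_type=trial_type,
                        congruency=congruency,
                        letter=letter,
                        side=side,
                    )
                )
        order = rng.permutation(len(block_rows))
        rows.extend(block_rows[i] for i in order)

    table = pd.DataFrame(rows)
    table["rt_ms"] = np.nan
    table["outcome"] = pd.NA
    return table


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _draw_rt(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    mu, sigma = _lognormal_params(mean, sd)
    return rng.lognormal(mu, sigma, size=size)


def simulate_behaviour(
    trials: pd.DataFrame,
    behav: BehaviourParams | None = None,
    seed: int = 0,
    deadline_ms: float = 1700.0,
) -> pd.DataFrame:
    """Fill in RTs and outcomes.

    Go trials: log-normal RT (congruency effect on the mean); RTs past the
    deadline become misses; a small fraction of responded trials are errors.
    Nogo trials: Bernoulli false alarms (higher rate when congruent), with
    the false-alarm RT drawn from the same log-normal truncated at the
    deadline; everything else is a correct omission.
    """
    behav = behav or BehaviourParams()
    behav.validate()
    rng = np.random.default_rng(seed)
    out = trials.copy()
    out["rt_ms"] = np.nan
    out["outcome"] = pd.NA

    for congruency in (CONGRUENT, INCONGRUENT):
        go_idx = out.index[(out.trial_type == GO) & (out.congruency == congruency)]
        if len(go_idx):
            rt = _draw_rt(rng, behav.rt_mean_ms[congruency], behav.rt_sd_ms, len(go_idx))
            responded = rt < deadline_ms
            errors = rng.random(len(go_idx)) < behav.go_error_rate
            outcome = np.where(responded, np.where(errors, "error", "correct"), "miss")
            out.loc[go_idx, "rt_ms"] = np.where(responded, rt, np.nan)
            out.loc[go_idx, "outcome"] = outcome

        ng_idx = out.index[(out.trial_type == NOGO) & (out.congruency == congruency)]
        if len(ng_idx):
            fa = rng.random(len(ng_idx)) < behav.nogo_false_alarm_rate[congruency]
            out.loc[ng_idx, "outcome"] = np.where(fa, "false_alarm", "correct_omission")
            n_fa = int(fa.sum())
            if n_fa and behav.rt_sd_ms > 0:
                mu, sigma = _lognormal_params(behav.rt_mean_ms[congruency], behav.rt_sd_ms)
                dist = stats.lognorm(s=sigma, scale=np.exp(mu))
                u = rng.random(n_fa) * dist.cdf(deadline_ms)
                out.loc[ng_idx[fa], "rt_ms"] = dist.ppf(u)
            elif n_fa:
                out.loc[ng_idx[fa], "rt_ms"] = behav.rt_mean_ms[congruency]
    return out


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

def _fibonacci_cap(n: int) -> np.ndarray:
    """n points on a golden-angle spiral over the upper spherical cap."""
    i = np.arange(n)
    z = 1.0 - (i + 0.5) * 1.2 / n  # z in (~-0.2, 1): cap-like EEG coverage
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_montage(n_channels: int, scheme: str = "fibonacci-sphere") -> Montage:
    """Deterministic electrode layout.

    ``fibonacci-sphere`` places channels on a golden-angle spiral over the
    upper spherical cap (labels E01..).  ``ten-ten-subset`` takes the first
    ``n_channels`` positions of the standard 10-10 nomenclature (via MNE's
    standard_1020 montage) projected to the unit sphere.
    """
    if n_channels < 16:
        raise ValueError("need at least 16 channels")
    if scheme == "fibonacci-sphere":
        pos = _fibonacci_cap(n_channels)
        pos /= np.linalg.norm(pos, axis=1, keepdims=True)
        labels = tuple(f"E{i + 1:02d}" for i in range(n_channels))
        return Montage(labels=labels, positions=pos)
    if scheme == "ten-ten-subset":
        import mne

        try:
            std = mne.channels.make_standard_montage("colin27_1020")
        except ValueError:
            std = mne.channels.make_standard_montage("standard_1020")
        ch_pos = std.get_positions()["ch_pos"]
        labels, vecs = [], []
        for name, p in ch_pos.items():
            if name in ("A1", "A2", "M1", "M2", "T3", "T4", "T5", "T6"):
                continue  # duplicates/earlobes of the legacy 10-20 names
            labels.append(name)
            vecs.append(p)
            if len(labels) == n_channels:
                break
        if len(labels) < n_channels:
            raise ValueError("not enough standard 10-10 positions for this count")
        pos = np.asarray(vecs)
        pos = pos - pos.mean(axis=0) * 0.0  # head-frame origin is already central
        pos /= np.linalg.norm(pos, axis=1, keepdims=True)
        return Montage(labels=tuple(labels), positions=pos)
    raise ValueError(f"unsupported montage scheme: {scheme!r}")


def _blob_topography(montage: Montage, center: np.ndarray, width_rad: float) -> np.ndarray:
    """Unit-norm Gaussian blob over the scalp, centred on a direction."""
    c = np.asarray(center, dtype=float)
    c = c / np.linalg.norm(c)
    ang = np.arccos(np.clip(montage.positions @ c, -1.0, 1.0))
    topo = np.exp(-(ang**2) / (2.0 * width_rad**2))
    return topo / np.linalg.norm(topo)


# ---------------------------------------------------------------------------
# EEG epochs
# ---------------------------------------------------------------------------

def _half_cycle(times_ms: np.ndarray, center_ms: float, width_ms: float) -> np.ndarray:
    """Gaussian-windowed positive half-cycle, peak 1 at the centre."""
    t = times_ms - center_ms
    half = np.where(np.abs(t) <= width_ms, np.cos(np.pi * t / (2.0 * width_ms)), 0.0)
    return half * np.exp(-(t**2) / (2.0 * (width_ms / 1.5) ** 2))


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], srate: float) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise along the last axis."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / srate)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spectrum = (rng.standard_normal(shape[:-1] + (freqs.size,))
            + 1j * rng.standard_normal(shape[:-1] + (freqs.size,))) * scale
    x = np.fft.irfft(spectrum, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_epochs(
    trials: pd.DataFrame,
    truth_params: TruthParams | None = None,
    montage: Montage | None = None,
    seed: int = 0,
) -> tuple[Epochs, SimTruth]:
    """Synthesize ground-truth epochs for a (behaviour-filled) trial table.

    Each trial is ``s_amp * s_topo (x) s_wave(t - s_lat) +
    c_amp * c_topo (x) c_wave(t - c_lat[i]) + noise`` with condition-specific
    amplitude scale factors and RT-coupled C latencies.
    """
    tp = truth_params or TruthParams()
    montage = montage or make_montage(60, "fibonacci-sphere")
    rng = np.random.default_rng(seed)

    start, end = tp.epoch_window_ms
    n_times = int(round((end - start) * tp.srate_hz / 1000.0))
    times = start + np.arange(n_times) * 1000.0 / tp.srate_hz

    lat_margin = tp.c_width_ms
    if tp.s_latency_ms - tp.s_width_ms < start or tp.s_latency_ms + tp.s_width_ms > end:
        raise ValueError("S latency window extends beyond the epoch")

    s_topo = _blob_topography(montage, np.array([0.0, -0.1, 1.0]), 0.55)
    c_topo = _blob_topography(montage, np.array([0.0, 0.55, 0.85]), 0.45)

    n_trials = len(trials)
    rt = trials["rt_ms"].to_numpy(dtype=float)
    congruency = trials["congruency"].to_numpy()

    # C latency: RT-coupled when a response exists, pseudo-RT otherwise
    pseudo = np.empty(n_trials)
    for cond in (CONGRUENT, INCONGRUENT):
        m = congruency == cond
        pseudo[m] = _draw_rt(rng, tp.pseudo_rt_mean_ms[cond], tp.pseudo_rt_sd_ms, int(m.sum()))
    eff_rt = np.where(np.isfinite(rt), rt, pseudo)
    c_lat = (
        tp.c_intercept_ms
        + tp.c_rt_slope * eff_rt
        + rng.normal(0.0, tp.c_jitter_sd_ms, size=n_trials)
    )
    c_lat = np.clip(c_lat, start + lat_margin, end - lat_margin)

    s_wave = _half_cycle(times, tp.s_latency_ms, tp.s_width_ms)

    amps = np.array(
        [tp.amplitude_by_condition[c] for c in congruency], dtype=float
    )  # (n_trials, 2): s_amp_scale, c_amp_scale

    data = np.empty((n_trials, montage.n_channels, n_times))
    s_part = np.outer(s_topo, s_wave)
    for i in range(n_trials):
        c_wave_i = _half_cycle(times, c_lat[i], tp.c_width_ms)
        data[i] = (
            tp.s_amp * amps[i, 0] * s_part
            + tp.c_amp * amps[i, 1] * np.outer(c_topo, c_wave_i)
        )

    if tp.effect_amp and tp.effect_window_ms is not None:
        eff_topo = _blob_topography(montage, np.array([0.3, 0.55, 0.75]), 0.5)
        w0, w1 = tp.effect_window_ms
        box = ((times >= w0) & (times < w1)).astype(float)
        inc = congruency == INCONGRUENT
        data[inc] += tp.effect_amp * np.outer(eff_topo, box)[None, :, :]

    if tp.pink_sd > 0:
        k = tp.n_noise_patterns
        patterns = np.stack(
            [
                _blob_topography(montage, rng.standard_normal(3), 0.4 + 0.4 * rng.random())
                for _ in range(k)
            ],
            axis=1,
        )  # (channels, k)
        src = _pink_noise(rng, (n_trials, k, n_times), tp.srate_hz)
        pink = np.einsum("ck,ikt->ict", patterns, src)
        pink /= max(pink.std(), 1e-12)
        data += tp.pink_sd * pink
    if tp.white_sd > 0:
        data += tp.white_sd * rng.standard_normal(data.shape)

    epochs = Epochs(
        data=data,
        srate_hz=tp.srate_hz,
        times_ms=times,
        montage=montage,
        trials=trials.copy(),
    )
    truth = SimTruth(
        s_topography=s_topo,
        c_topography=c_topo,
        s_latency_ms=tp.s_latency_ms,
        c_latency_ms=c_lat,
        amplitude_by_condition=dict(tp.amplitude_by_condition),
        noise_params=(tp.pink_sd, tp.white_sd),
        seed=seed,
        s_waveform=s_wave,
        c_waveform_shape=_half_cycle(times, 0.0, tp.c_width_ms),
    )
    return epochs, truth


def null_truth_params(**overrides) -> TruthParams:
    """Truth parameters with no condition differences (null generator)."""
    base = TruthParams(
        amplitude_by_condition={CONGRUENT: (1.0, 1.0), INCONGRUENT: (1.0, 1.0)},
        effect_amp=0.0,
        effect_window_ms=None,
    )
    return replace(base, **overrides)
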