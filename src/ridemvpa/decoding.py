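"""Time-resolved MVPA and group-level cluster permutation statistics.

Per subject and component pair, congruent-vs-incongruent decoding runs a
linear SVM on channel amplitudes (one classifier per training time point,
features z-scored with training-fold statistics), scored as the area under
the ROC curve (AUC) on held-out folds of a repeated stratified k-fold
(default: fivefold, twice).  Temporal generalization additionally tests each
classifier at every other time point; sustained off-diagonal decoding
indicates temporally stable representational content.  Classes are balanced
by random undersampling beforehand.

Group inference uses Wilcoxon signed-rank tests against chance (AUC = 0.5)
at every time point, corrected with a cluster-based permutation test:
clusters of contiguous supra-threshold points (4-connected for temporal
generalization matrices) are scored by their summed signed-rank z, and
compared with the maximum cluster score under random per-subject sign flips
of (score − chance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import LinearSVC

__all__ = ["CVConfig", "DecodingResult", "ClusterStatsResult", "undersample",
           "decode", "group_cluster_test", "signed_rank_z", "stack_results"]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation setup: fivefold, applied twice, linear SVM."""

    n_folds: int = 5
    n_repeats: int = 2
    classifier: str = "linear-svm"
    decode_window_ms: tuple[float, float] = (0.0, 1000.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.classifier != "linear-svm":
            raise ValueError(f"unsupported classifier: {self.classifier!r}")


@dataclass
class DecodingResult:
    """Per-subject AUC time courses and temporal-generalization matrices."""

    subject_auc: np.ndarray  # (n_subjects, n_times)
    subject_tg: np.ndarray | None  # (n_subjects, n_times, n_times) or None
    times_ms: np.ndarray
    trial_counts: np.ndarray  # per-subject balanced per-class counts


@dataclass
class ClusterStatsResult:
    """Cluster permutation outcome for 1-D or 2-D score maps."""

    clusters: list  # (member index array, summed z statistic, p value)
    significant_mask: np.ndarray  # bool, same shape as the score map
    z_map: np.ndarray
    n_permutations: int
    alpha: float
    low_perm_warning: bool = False
    cluster_alpha: float = 0.05
    extra: dict = field(default_factory=dict)


def undersample(labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Indices balancing two classes by random majority-class subsampling."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("undersampling needs exactly two classes")
    rng = np.random.default_rng(seed)
    idx0 = np.flatnonzero(labels == classes[0])
    idx1 = np.flatnonzero(labels == classes[1])
    n = min(idx0.size, idx1.size)
    keep = np.concatenate([
        rng.choice(idx0, size=n, replace=False),
        rng.choice(idx1, size=n, replace=False),
    ])
    return np.sort(keep)


def _auc_columns(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """AUC of each column of decision values via the rank (Mann-Whitney) form."""
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = stats.rankdata(scores, axis=0)
    return (ranks[y == 1].sum(axis=0) - n1 * (n1 + 1) / 2.0) / (n0 * n1)


def _fold_auc(train_x, train_y, test_x, test_y, test_times):
    """Fit at one time point, score AUC at each requested test time.

    ``test_x`` is (trials, channels, times); decision values for all test
    times come from one tensor contraction with the fitted hyperplane.
    """
    mu = train_x.mean(axis=0)
    sd = train_x.std(axis=0)
    sd[sd == 0] = 1.0
    # fixed random_state: the dual solver is randomized and must not draw
    # from the global RNG (per-fold results must be reproducible)
    clf = LinearSVC(C=1.0, dual="auto", max_iter=20000, random_state=0)
    with warnings.catch_warnings():
        # near-separable folds occasionally hit the iteration cap with the
        # hyperplane already stable; decision values remain usable
        warnings.filterwarnings("ignore", message=".*Liblinear failed to converge.*")
        clf.fit((train_x - mu) / sd, train_y)
    w = (clf.coef_[0] / sd)
    dec = np.einsum("c,ict->it", w, test_x[:, :, test_times]) \
        - (w * mu).sum() + clf.intercept_[0]
    return _auc_columns(dec, test_y)


def decode(
    data_a: np.ndarray,
    data_b: np.ndarray,
    cv: CVConfig | None = None,
    generalize: bool = False,
    times_ms: np.ndarray | None = None,
) -> DecodingResult:
    """Binary decoding for one subject from two trials x channels x time tensors.

    Classes are balanced by undersampling; per training time point a linear
    SVM is fit on z-scored channel amplitudes and scored (AUC from decision
    values) on held-out folds at the same time point and, if ``generalize``,
    at every test time point.  Fold scores are averaged over the repeated
    k-fold.
    """
    cv = cv or CVConfig()
    cv.validate()
    x = np.concatenate([data_a, data_b], axis=0)
    y = np.concatenate([np.zeros(len(data_a), dtype=int), np.ones(len(data_b), dtype=int)])
    keep = undersample(y, seed=cv.seed)
    x, y = x[keep], y[keep]
    n_per_class = int((y == 0).sum())
    if n_per_class < cv.n_folds:
        raise ValueError("fewer trials per class than folds after balancing")

    if times_ms is not None:
        w0, w1 = cv.decode_window_ms
        tmask = (times_ms >= w0 - 1e-9) & (times_ms < w1 - 1e-9)
        x = x[:, :, tmask]
        out_times = times_ms[tmask]
    else:
        out_times = np.arange(x.shape[2], dtype=float)

    n_t = x.shape[2]
    rkf = RepeatedStratifiedKFold(n_splits=cv.n_folds, n_repeats=cv.n_repeats,
                                  random_state=cv.seed % (2**31))
    n_models = cv.n_folds * cv.n_repeats
    auc = np.zeros(n_t)
    tg = np.zeros((n_t, n_t)) if generalize else None
    all_times = np.arange(n_t)
    for train, test in rkf.split(x[:, :, 0], y):
        for t in range(n_t):
            test_times = all_times if generalize else np.array([t])
            row = _fold_auc(x[train, :, t], y[train], x[test], y[test], test_times)
            if generalize:
                tg[t] += row
                auc[t] += row[t]
            else:
                auc[t] += row[0]
    auc /= n_models
    if tg is not None:
        tg /= n_models

    return DecodingResult(
        subject_auc=auc[None, :],
        subject_tg=tg[None, :, :] if tg is not None else None,
        times_ms=out_times,
        trial_counts=np.array([n_per_class]),
    )


def stack_results(results: list[DecodingResult]) -> DecodingResult:
    """Stack single-subject results into one group container."""
    tg = None
    if all(r.subject_tg is not None for r in results):
        tg = np.concatenate([r.subject_tg for r in results], axis=0)
    return DecodingResult(
        subject_auc=np.concatenate([r.subject_auc for r in results], axis=0),
        subject_tg=tg,
        times_ms=results[0].times_ms,
        trial_counts=np.concatenate([r.trial_counts for r in results]),
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank machinery (vectorized over map points)
# ---------------------------------------------------------------------------

def signed_rank_z(d: np.ndarray) -> np.ndarray:
    """Signed-rank z (normal approximation, tie-corrected) per column.

    ``d`` is (n_subjects, n_points); zero differences are dropped per column
    (standard Wilcoxon convention).  Returns the z score of T+ (positive for
    predominantly positive differences).
    """
    d = np.atleast_2d(np.asarray(d, dtype=float))
    n_sub, n_pts = d.shape
    z = np.empty(n_pts)
    nonzero = d != 0
    simple = nonzero.all(axis=0)

    if simple.any():
        ds = d[:, simple]
        ranks = stats.rankdata(np.abs(ds), axis=0)
        t_plus = (ranks * (ds > 0)).sum(axis=0)
        n = n_sub
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_correction(np.abs(ds))
        z[simple] = (t_plus - mu) / np.sqrt(np.maximum(var, 1e-300))

    for j in np.flatnonzero(~simple):
        dj = d[nonzero[:, j], j]
        if dj.size == 0:
            z[j] = 0.0
            continue
        ranks = stats.rankdata(np.abs(dj))
        t_plus = ranks[dj > 0].sum()
        n = dj.size
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_correction(np.abs(dj)[:, None])[0]
        z[j] = (t_plus - mu) / np.sqrt(max(var, 1e-300))
    return z


def _tie_correction(absd: np.ndarray) -> np.ndarray:
    """Sum of (t^3 - t)/48 over tie groups, per column of |d|."""
    n, p = absd.shape
    out = np.zeros(p)
    srt = np.sort(absd, axis=0)
    ties = srt[1:] == srt[:-1]
    cols = np.flatnonzero(ties.any(axis=0))
    for j in cols:
        _, counts = np.unique(srt[:, j], return_counts=True)
        out[j] = ((counts**3 - counts).sum()) / 48.0
    return out


def _exact_p_one_sided(d: np.ndarray) -> np.ndarray:
    """Exact one-sided P(T+ >= observed) per column by sign enumeration."""
    n, p = d.shape
    ranks = stats.rankdata(np.abs(d), axis=0)  # (n, p)
    t_obs = (ranks * (d > 0)).sum(axis=0)
    signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)  # (2^n, n)
    t_null = signs @ ranks  # (2^n, p)
    return (t_null >= t_obs[None, :] - 1e-9).mean(axis=0)


def group_cluster_test(
    subject_scores: np.ndarray,
    chance: float = 0.5,
    n_perm: int = 1000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    seed: int = 0,
) -> ClusterStatsResult:
    """Cluster-based sign-flip permutation test of scores against chance.

    ``subject_scores`` is (n_subjects, T) or (n_subjects, T, T).  Point-wise
    one-sided Wilcoxon signed-rank tests (above chance) define supra-threshold
    points at p < ``cluster_alpha``; contiguous points (4-connected in 2-D)
    form clusters scored by their summed z.  The null is the maximum cluster
    score over random per-subject sign flips of (score − chance); cluster
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``.  The exact signed-rank
    distribution is enumerated below 12 subjects, the tie-corrected normal
    approximation is used otherwise.
    """
    scores = np.asarray(subject_scores, dtype=float)
    if scores.ndim not in (2, 3):
        raise ValueError("scores must be (subjects, T) or (subjects, T, T)")
    n_sub = scores.shape[0]
    if n_sub < 5:
        raise ValueError("need at least 5 subjects")
    low_perm = n_perm < 100
    if low_perm:
        warnings.warn("n_perm < 100: permutation p values will be coarse",
                      stacklevel=2)

    map_shape = scores.shape[1:]
    d = (scores - chance).reshape(n_sub, -1)  # (n, P)
    n_pts = d.shape[1]
    exact = n_sub < 12

    ranks = stats.rankdata(np.abs(d), axis=0)
    sgn = np.sign(d)
    mu = n_sub * (n_sub + 1) / 4.0
    var = n_sub * (n_sub + 1) * (2 * n_sub + 1) / 24.0 - _tie_correction(np.abs(d))
    sigma = np.sqrt(np.maximum(var, 1e-300))
    half_rsum = 0.5 * (ranks * (sgn != 0)).sum(axis=0)

    def z_from_signs(s: np.ndarray) -> np.ndarray:
        # s: (n_flip, n_sub) of ±1 -> z fields (n_flip, P)
        t_plus = half_rsum[None, :] + 0.5 * (s @ (ranks * sgn))
        return (t_plus - mu) / sigma[None, :]

    z_obs = z_from_signs(np.ones((1, n_sub)))[0]

    if exact:
        p_obs = _exact_p_one_sided(d)
        # permutation thresholding reuses the enumerated null per column
        signs_all = ((np.arange(2**n_sub)[:, None] >> np.arange(n_sub)) & 1).astype(float)
        t_null_sorted = np.sort(signs_all @ ranks, axis=0)  # (2^n, P)
        n_enum = t_null_sorted.shape[0]

        def supra_mask(t_plus_rows: np.ndarray) -> np.ndarray:
            # p = fraction of enumerated T+ >= value, per column
            pos = np.empty_like(t_plus_rows)
            for j in range(n_pts):
                pos[:, j] = n_enum - np.searchsorted(
                    t_null_sorted[:, j], t_plus_rows[:, j] - 1e-9)
            return (pos / n_enum) < cluster_alpha
        obs_mask = (p_obs < cluster_alpha)
    else:
        z_crit = stats.norm.isf(cluster_alpha)
        obs_mask = z_obs > z_crit

    structure = None
    if len(map_shape) == 2:
        structure = ndimage.generate_binary_structure(2, 1)  # 4-connectivity

    def cluster_max(z_field: np.ndarray, mask: np.ndarray) -> float:
        lab, n_lab = ndimage.label(mask.reshape(map_shape), structure=structure)
        if n_lab == 0:
            return 0.0
        sums = ndimage.sum(z_field.reshape(map_shape), lab, np.arange(1, n_lab + 1))
        return float(np.max(sums))

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    z_perm = z_from_signs(flips)
    if exact:
        t_plus_perm = half_rsum[None, :] + 0.5 * (flips @ (ranks * sgn))
        perm_masks = supra_mask(t_plus_perm)
    else:
        perm_masks = z_perm > stats.norm.isf(cluster_alpha)

    null_max = np.array([cluster_max(z_perm[p], perm_masks[p]) for p in range(n_perm)])

    lab, n_lab = ndimage.label(obs_mask.reshape(map_shape), structure=structure)
    clusters = []
    sig_mask = np.zeros(map_shape, dtype=bool)
    z_map = z_obs.reshape(map_shape)
    for k in range(1, n_lab + 1):
        members = np.flatnonzero(lab.ravel() == k)
        stat = float(z_map.ravel()[members].sum())
        p_val = float((1 + (null_max >= stat - 1e-12).sum()) / (1 + n_perm))
        clusters.append((members, stat, p_val))
        if p_val < alpha:
            sig_mask.ravel()[members] = True
    clusters.sort(key=lambda c: c[2])

    return ClusterStatsResult(
        clusters=clusters,
        significant_mask=sig_mask,
        z_map=z_map,
        n_permutations=n_perm,
        alpha=alpha,
        low_perm_warning=low_perm,
        cluster_alpha=cluster_alpha,
    )
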