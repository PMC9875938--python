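"""Cross-condition matching of IC scalp topographies (CORRMAP-style).

Components estimated separately for congruent and incongruent data come in
arbitrary order, sign and scale, so comparable component pairs are found by
correlating scalp topographies (the ICA inverse weights) across conditions.
Each component of either decomposition serves as a template seed; components
of the other decomposition whose topography correlates above threshold
(on |Pearson r| across channels — sign-invariant, since ICA polarity is
arbitrary) form its cluster, capped per condition.  Reported pairs are
reciprocal best matches, deduplicated so each component appears at most once
(best |r| wins, then the lowest index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .group_ica import GroupICAModel

__all__ = ["ICPairMatch", "match_components", "matches_to_frame"]


@dataclass(frozen=True)
class ICPairMatch:
    ic_congruent: int
    ic_incongruent: int
    topography_correlation: float  # signed r
    abs_correlation: float
    template_seed_ic: int
    cluster_id: int


def _topographies(model: GroupICAModel | np.ndarray) -> np.ndarray:
    topo = model.mixing if isinstance(model, GroupICAModel) else np.asarray(model)
    if topo.ndim != 2 or topo.shape[1] == 0:
        raise ValueError("model has no components")
    return topo


def match_components(
    model_a: GroupICAModel | np.ndarray,
    model_b: GroupICAModel | np.ndarray,
    threshold: float = 0.85,
    max_per_group: int = 3,
) -> list[ICPairMatch]:
    """Match components of two decompositions by topography correlation.

    ``model_a`` is treated as the congruent-condition model and ``model_b``
    as the incongruent one; either may be passed directly as a
    channels x components topography matrix.  Returns disjoint reciprocal
    best pairs with ``|r| >= threshold``, ordered by decreasing ``|r|``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    ta = _topographies(model_a)
    tb = _topographies(model_b)
    if ta.shape[0] != tb.shape[0]:
        raise ValueError("models must share the montage")

    za = (ta - ta.mean(axis=0)) / ta.std(axis=0)
    zb = (tb - tb.mean(axis=0)) / tb.std(axis=0)
    r = za.T @ zb / ta.shape[0]  # (n_a, n_b) signed Pearson r
    absr = np.abs(r)

    # cluster membership cap: each template seed keeps at most max_per_group
    # above-threshold matches per condition; matches beyond the cap are not
    # eligible for pairing (prevents overlapping clusters)
    eligible = absr >= threshold
    for i in range(absr.shape[0]):
        idx = np.flatnonzero(eligible[i])
        if idx.size > max_per_group:
            keep = idx[np.argsort(-absr[i, idx])][:max_per_group]
            eligible[i] = False
            eligible[i, keep] = True
    for j in range(absr.shape[1]):
        idx = np.flatnonzero(eligible[:, j])
        if idx.size > max_per_group:
            keep = idx[np.argsort(-absr[idx, j])][:max_per_group]
            eligible[:, j] = False
            eligible[keep, j] = True

    best_b = absr.argmax(axis=1)
    best_a = absr.argmax(axis=0)
    candidates = [
        (i, int(best_b[i]))
        for i in range(absr.shape[0])
        if eligible[i, best_b[i]] and best_a[best_b[i]] == i
    ]
    candidates.sort(key=lambda ij: (-absr[ij], ij[0], ij[1]))

    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[ICPairMatch] = []
    for i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append(
            ICPairMatch(
                ic_congruent=i,
                ic_incongruent=j,
                topography_correlation=float(r[i, j]),
                abs_correlation=float(absr[i, j]),
                template_seed_ic=i,
                cluster_id=len(matches),
            )
        )
    return matches


def matches_to_frame(matches: list[ICPairMatch]) -> pd.DataFrame:
    """Tabular view mirroring the pair-report layout (TSV-exportable)."""
    return pd.DataFrame(
        {
            "pair": [m.cluster_id + 1 for m in matches],
            "ic_congruent": [m.ic_congruent for m in matches],
            "ic_incongruent": [m.ic_incongruent for m in matches],
            "correlation": [m.abs_correlation for m in matches],
            "signed_correlation": [m.topography_correlation for m in matches],
        }
    )
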