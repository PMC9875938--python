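"""Group spatial ICA with back-reconstruction and rank-1 back-projection.

Subjects sharing a montage are analysed with a single spatial decomposition:
all subjects' samples (trials x time, flattened) are concatenated in channel
space, reduced by one group PCA, and unmixed with FastICA (``C = W X``:
independent components C from channel data X via the unmixing matrix W).
Per-subject activations are then recovered by applying the group unmixing to
each subject's own data ("back-reconstruction"), and any single component
can be re-expanded to rank-1 channel data ("back-projection") — the input
for component-wise decoding.

ICA sign and scale are indeterminate; stored topographies are unit-norm with
the maximal-|loading| channel positive, and the unmixing rows carry the
compensating factors so mixing @ unmixing is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA, FastICA

from .task_sim import Epochs

__all__ = ["GroupICAModel", "fit_group_ica", "back_reconstruct", "backproject_ic"]


@dataclass
class GroupICAModel:
    """Group ICA decomposition in channel space.

    ``mixing`` columns are component scalp topographies (unit-norm,
    sign-fixed); ``unmixing @ (x − mean)`` yields component activations.
    ``mixing @ unmixing`` is the projector onto the retained PCA subspace.
    """

    mixing: np.ndarray  # (channels, components)
    unmixing: np.ndarray  # (components, channels)
    mean: np.ndarray  # (channels,)
    pca_basis: np.ndarray  # (components, channels)
    n_components: int
    explained_variance_fraction: float
    subject_variance_fractions: np.ndarray
    seed: int
    cluster_tag: str = ""
    condition_tag: str = ""

    @property
    def topographies(self) -> np.ndarray:
        return self.mixing


def _as_channel_samples(subject_data: np.ndarray | Epochs) -> np.ndarray:
    """(channels, samples) view of one subject's trials x channels x time data."""
    arr = subject_data.data if isinstance(subject_data, Epochs) else np.asarray(subject_data)
    if arr.ndim != 3:
        raise ValueError("subject data must be trials x channels x time")
    return arr.transpose(1, 0, 2).reshape(arr.shape[1], -1)


def fit_group_ica(
    subject_data: list,
    n_components: int = 20,
    var_threshold: float = 0.98,
    seed: int = 0,
    max_restarts: int = 5,
    cluster_tag: str = "",
    condition_tag: str = "",
) -> GroupICAModel:
    """Fit the group decomposition: concatenation -> PCA -> FastICA.

    The retained PCA subspace must explain at least ``var_threshold`` of each
    subject's own variance (the per-subject eigenvalue-retention check) and
    of the pooled variance.  FastICA uses the tanh contrast with deflation,
    restarting with fresh seeds and falling back to the symmetric
    (parallel) scheme before giving up.
    """
    mats = [_as_channel_samples(s) for s in subject_data]
    n_ch = mats[0].shape[0]
    if any(m.shape[0] != n_ch for m in mats):
        raise ValueError("all subjects must share the montage")
    if not 1 <= n_components <= n_ch:
        raise ValueError("n_components must be in [1, n_channels]")

    x = np.concatenate(mats, axis=1)  # (channels, total samples)
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(x.T)
    evr = float(pca.explained_variance_ratio_.sum())
    rank = np.linalg.matrix_rank(x - x.mean(axis=1, keepdims=True))
    if rank < n_components:
        raise ValueError(f"data rank {rank} below n_components={n_components}")

    subj_fracs = []
    for m in mats:
        mc = m - pca.mean_[:, None]
        proj = pca.components_ @ mc
        tot = float((mc**2).sum())
        subj_fracs.append(float((proj**2).sum()) / tot if tot else 1.0)
    subj_fracs = np.asarray(subj_fracs)
    if evr < var_threshold or (subj_fracs < var_threshold).any():
        raise ValueError(
            f"retained variance below threshold {var_threshold:.2f} "
            f"(group {evr:.3f}, min subject {subj_fracs.min():.3f}); "
            "increase n_components"
        )

    scores = pca.transform(x.T)  # (samples, components)
    seeds_tried = []
    ica = None
    for attempt in range(max_restarts):
        algo = "deflation" if attempt < max_restarts - 1 else "parallel"
        trial_seed = (seed + 7919 * attempt) % (2**31)
        seeds_tried.append(trial_seed)
        cand = FastICA(n_components=n_components, fun="logcosh", algorithm=algo,
                       whiten="unit-variance", max_iter=1000, tol=1e-5,
                       random_state=trial_seed)
        import warnings

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cand.fit(scores)
        if not any("did not converge" in str(w.message) for w in caught):
            ica = cand
            break
    if ica is None:
        raise RuntimeError(f"FastICA did not converge; seeds tried: {seeds_tried}")

    # channel-space mixing/unmixing through the PCA basis
    mixing = pca.components_.T @ ica.mixing_  # (channels, components)
    unmixing = ica.components_ @ pca.components_  # (components, channels)

    norms = np.linalg.norm(mixing, axis=0)
    norms[norms == 0] = 1.0
    signs = np.sign(mixing[np.abs(mixing).argmax(axis=0), np.arange(mixing.shape[1])])
    signs[signs == 0] = 1.0
    fix = signs / norms
    mixing = mixing * fix
    unmixing = unmixing / fix[:, None]

    return GroupICAModel(
        mixing=mixing,
        unmixing=unmixing,
        mean=pca.mean_.copy(),
        pca_basis=pca.components_.copy(),
        n_components=n_components,
        explained_variance_fraction=evr,
        subject_variance_fractions=subj_fracs,
        seed=seed,
        cluster_tag=cluster_tag,
        condition_tag=condition_tag,
    )


def back_reconstruct(model: GroupICAModel, subject_data: np.ndarray | Epochs) -> np.ndarray:
    """Subject-level component activations: trials x components x time."""
    arr = subject_data.data if isinstance(subject_data, Epochs) else np.asarray(subject_data)
    if arr.ndim != 3 or arr.shape[1] != model.mixing.shape[0]:
        raise ValueError("subject data channel count does not match the model")
    centred = arr - model.mean[None, :, None]
    return np.einsum("kc,ict->ikt", model.unmixing, centred)


def backproject_ic(model: GroupICAModel, subject_data: np.ndarray | Epochs,
                   ic: int) -> np.ndarray:
    """Rank-1 channel-space data carried by one component (trials x ch x time)."""
    if not 0 <= ic < model.n_components:
        raise ValueError(f"component index {ic} out of range")
    acts = back_reconstruct(model, subject_data)
    return np.einsum("c,it->ict", model.mixing[:, ic], acts[:, ic, :])
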