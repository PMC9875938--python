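"""HDF5 container for pipeline artefacts, plus optional recording import.

One HDF5 file holds a whole run: ``/data``, ``/times``, ``/montage`` and
``/trials`` for the epochs, ``/truth/*`` for simulation ground truth,
``/ride/{condition}`` for decompositions and ``/ica/{cluster}/{condition}``
for group ICA models.  Trial tables round-trip through per-column datasets
(UTF-8 variable-length strings for categorical columns).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .group_ica import GroupICAModel
from .ride import RideResult
from .task_sim import Epochs, Montage, SimTruth

__all__ = ["save_epochs", "load_epochs", "save_truth", "load_truth",
           "save_ride", "load_ride", "save_ica", "load_ica", "read_recording"]

_STR = "utf-8"


def _write_frame(group, frame: pd.DataFrame) -> None:
    import h5py

    group.attrs["columns"] = list(frame.columns)
    for col in frame.columns:
        vals = frame[col]
        if vals.dtype == object or pd.api.types.is_string_dtype(vals):
            data = np.array(["" if pd.isna(v) else str(v) for v in vals],
                            dtype=h5py.string_dtype(_STR))
        elif pd.api.types.is_bool_dtype(vals):
            data = vals.to_numpy(dtype=bool)
        else:
            data = vals.to_numpy(dtype=float)
        group.create_dataset(col, data=data)


def _read_frame(group) -> pd.DataFrame:
    cols = {}
    for col in group.attrs["columns"]:
        arr = group[col][()]
        if arr.dtype.kind in ("O", "S"):
            vals = pd.Series([v.decode(_STR) if isinstance(v, bytes) else v for v in arr])
            vals = vals.replace("", pd.NA)
        else:
            vals = pd.Series(arr)
        cols[col] = vals
    return pd.DataFrame(cols)


def save_epochs(path: str, epochs: Epochs, mode: str = "w", prefix: str = "/") -> None:
    import h5py

    with h5py.File(path, mode) as f:
        g = f.require_group(prefix)
        g.create_dataset("data", data=epochs.data)
        g.create_dataset("times", data=epochs.times_ms)
        g.attrs["srate_hz"] = epochs.srate_hz
        g.attrs["unit_label"] = epochs.unit_label
        mg = g.create_group("montage")
        mg.create_dataset("labels",
                          data=np.array(epochs.montage.labels,
                                        dtype=h5py.string_dtype(_STR)))
        mg.create_dataset("positions", data=epochs.montage.positions)
        _write_frame(g.create_group("trials"), epochs.trials)


def load_epochs(path: str, prefix: str = "/") -> Epochs:
    import h5py

    with h5py.File(path, "r") as f:
        g = f[prefix]
        labels = tuple(v.decode(_STR) for v in g["montage/labels"][()])
        montage = Montage(labels=labels, positions=g["montage/positions"][()])
        return Epochs(data=g["data"][()], srate_hz=float(g.attrs["srate_hz"]),
                      times_ms=g["times"][()], montage=montage,
                      trials=_read_frame(g["trials"]),
                      unit_label=str(g.attrs["unit_label"]))


def save_truth(path: str, truth: SimTruth, mode: str = "a") -> None:
    import h5py

    with h5py.File(path, mode) as f:
        g = f.require_group("truth")
        g.create_dataset("s_topography", data=truth.s_topography)
        g.create_dataset("c_topography", data=truth.c_topography)
        g.create_dataset("c_latency_ms", data=truth.c_latency_ms)
        g.attrs["s_latency_ms"] = truth.s_latency_ms
        g.attrs["noise_params"] = truth.noise_params
        g.attrs["seed"] = truth.seed
        amp = g.create_group("amplitude_by_condition")
        for cond, (s_a, c_a) in truth.amplitude_by_condition.items():
            amp.attrs[cond] = (s_a, c_a)


def load_truth(path: str) -> SimTruth:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["truth"]
        amps = {k: tuple(v) for k, v in g["amplitude_by_condition"].attrs.items()}
        return SimTruth(
            s_topography=g["s_topography"][()],
            c_topography=g["c_topography"][()],
            s_latency_ms=float(g.attrs["s_latency_ms"]),
            c_latency_ms=g["c_latency_ms"][()],
            amplitude_by_condition=amps,
            noise_params=tuple(g.attrs["noise_params"]),
            seed=int(g.attrs["seed"]),
        )


def save_ride(path: str, result: RideResult, condition: str, mode: str = "a") -> None:
    import h5py

    with h5py.File(path, mode) as f:
        g = f.require_group(f"ride/{condition}")
        g.create_dataset("s_waveform", data=result.s_waveform)
        g.create_dataset("c_waveform", data=result.c_waveform)
        g.create_dataset("c_latency_samples", data=result.c_latency_samples)
        g.create_dataset("times_ms", data=result.times_ms)
        g.attrs.update(
            ref_latency_sample=result.ref_latency_sample,
            s_latency_sample=result.s_latency_sample,
            n_iterations=result.n_iterations,
            converged=result.converged,
            degenerate=result.degenerate,
            srate_hz=result.srate_hz,
        )


def load_ride(path: str, condition: str) -> RideResult:
    import h5py

    with h5py.File(path, "r") as f:
        g = f[f"ride/{condition}"]
        return RideResult(
            s_waveform=g["s_waveform"][()],
            c_waveform=g["c_waveform"][()],
            c_latency_samples=g["c_latency_samples"][()],
            ref_latency_sample=int(g.attrs["ref_latency_sample"]),
            s_latency_sample=int(g.attrs["s_latency_sample"]),
            n_iterations=int(g.attrs["n_iterations"]),
            converged=bool(g.attrs["converged"]),
            degenerate=bool(g.attrs["degenerate"]),
            times_ms=g["times_ms"][()],
            srate_hz=float(g.attrs["srate_hz"]),
        )


def save_ica(path: str, model: GroupICAModel, cluster: str, condition: str,
             mode: str = "a") -> None:
    import h5py

    with h5py.File(path, mode) as f:
        g = f.require_group(f"ica/{cluster}/{condition}")
        for name in ("mixing", "unmixing", "mean", "pca_basis",
                     "subject_variance_fractions"):
            g.create_dataset(name, data=getattr(model, name))
        g.attrs.update(
            n_components=model.n_components,
            explained_variance_fraction=model.explained_variance_fraction,
            seed=model.seed,
            cluster_tag=model.cluster_tag,
            condition_tag=model.condition_tag,
        )


def load_ica(path: str, cluster: str, condition: str) -> GroupICAModel:
    import h5py

    with h5py.File(path, "r") as f:
        g = f[f"ica/{cluster}/{condition}"]
        return GroupICAModel(
            mixing=g["mixing"][()],
            unmixing=g["unmixing"][()],
            mean=g["mean"][()],
            pca_basis=g["pca_basis"][()],
            n_components=int(g.attrs["n_components"]),
            explained_variance_fraction=float(g.attrs["explained_variance_fraction"]),
            subject_variance_fractions=g["subject_variance_fractions"][()],
            seed=int(g.attrs["seed"]),
            cluster_tag=str(g.attrs["cluster_tag"]),
            condition_tag=str(g.attrs["condition_tag"]),
        )


def read_recording(path: str) -> "object":
    """Import a BrainVision (.vhdr) or EDF recording as an MNE Raw object.

    Convenience import for real recordings; epoching into the
    :class:`~ridemvpa.task_sim.Epochs` container is left to the caller, as
    event semantics are study-specific.
    """
    import mne

    mne.set_log_level("ERROR")
    lower = str(path).lower()
    if lower.endswith(".vhdr"):
        return mne.io.read_raw_brainvision(path, preload=True)
    if lower.endswith(".edf"):
        return mne.io.read_raw_edf(path, preload=True)
    raise ValueError("supported formats: BrainVision .vhdr, EDF .edf")
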