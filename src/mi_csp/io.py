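"""File I/O: competition MAT-files, HDF5 interchange containers, CSV reports.

The interchange format is a plain HDF5 file with self-describing datasets
(``data``, ``labels``, ``fs``, ``channel_labels`` ...) and a ``kind``
attribute, so recordings, epoch sets and CSP models round-trip bit-exactly.
Continuous competition recordings are read from level-5 MAT-files holding a
``cnt`` signal matrix (samples x channels), an ``mrk`` marker struct and an
``nfo`` metadata struct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import loadmat

from .csp import CspModel, FeatureMatrix
from .errors import ConfigurationError, FormatError
from .types import EpochSet, Recording

__all__ = [
    "DatasetManifest",
    "read_competition_mat",
    "save_recording",
    "load_recording",
    "write_epochs",
    "read_epochs",
    "save_csp_model",
    "load_csp_model",
    "write_features_csv",
    "write_report_csv",
]

logger = logging.getLogger(__name__)

_FORMAT_VERSION = 1
_STR = h5py.string_dtype(encoding="utf-8")


@dataclass(frozen=True)
class DatasetManifest:
    """Summary metadata of one subject's recording."""

    subject_id: str
    n_channels: int
    fs: float
    class_labels: tuple[str, str]
    n_trials: int


# ---------------------------------------------------------------------------
# competition MAT-files
# ---------------------------------------------------------------------------

def _attr(struct, name, context):
    try:
        return getattr(struct, name)
    except AttributeError:
        raise FormatError(f"MAT variable {context!r} is missing field {name!r}") from None


def read_competition_mat(path: str | Path, scale: float | None = None) -> Recording:
    """Read a continuous-recording MAT-file in the competition layout.

    Expected variables: ``cnt`` (signal, samples x channels), ``mrk`` with
    fields ``pos`` (1-based onset samples) and ``y`` (class labels, NaN for
    unlabeled/test trials), and ``nfo`` with fields ``fs`` and ``clab``.

    Parameters
    ----------
    scale : float, optional
        Microvolts per stored unit.  If omitted, integer-typed signals are
        scaled by 0.1 uV/unit (the competition's stated quantization) and
        floating signals are taken as microvolts already.

    Markers with a missing (NaN) class are dropped with a logged count;
    the remaining labels are mapped to {1, 2} in first-appearance order.
    """
    try:
        mat = loadmat(path, squeeze_me=True, struct_as_record=False)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read MAT-file {path}: {exc}") from exc
    for var in ("cnt", "mrk", "nfo"):
        if var not in mat:
            raise FormatError(f"MAT-file {path} is missing variable {var!r}")
    cnt = np.asarray(mat["cnt"])
    if cnt.ndim != 2:
        raise FormatError(f"variable 'cnt' must be 2-D, got shape {cnt.shape}")
    if scale is None:
        scale = 0.1 if np.issubdtype(cnt.dtype, np.integer) else 1.0
    data = cnt.astype(np.float64).T * float(scale)  # -> channels x samples

    nfo = mat["nfo"]
    fs = float(_attr(nfo, "fs", "nfo"))
    clab = _attr(nfo, "clab", "nfo")
    labels = [str(c) for c in np.atleast_1d(clab)]
    if len(labels) != data.shape[0]:
        raise FormatError(
            f"'nfo.clab' lists {len(labels)} channels but 'cnt' has {data.shape[0]}"
        )

    mrk = mat["mrk"]
    pos = np.atleast_1d(_attr(mrk, "pos", "mrk")).astype(np.float64)
    y = np.atleast_1d(_attr(mrk, "y", "mrk")).astype(np.float64)
    if pos.shape != y.shape:
        raise FormatError(
            f"'mrk.pos' ({pos.shape}) and 'mrk.y' ({y.shape}) have different shapes"
        )
    valid = np.isfinite(y)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("dropping %d marker(s) with undefined class labels", n_dropped)
    pos, y = pos[valid], y[valid]

    # map raw class codes (e.g. -1/+1) to {1, 2} in first-appearance order
    mapping: dict[float, int] = {}
    for v in y:
        if v not in mapping:
            mapping[v] = len(mapping) + 1
    if len(mapping) > 2:
        raise FormatError(f"expected two classes, found codes {sorted(mapping)}")
    markers = [(int(p) - 1, mapping[v]) for p, v in zip(pos, y)]  # MAT is 1-based

    return Recording(data=data, fs=fs, channel_labels=labels, markers=markers)


# ---------------------------------------------------------------------------
# HDF5 interchange containers
# ---------------------------------------------------------------------------

def _require(f: h5py.File, name: str, path) -> h5py.Dataset:
    if name not in f:
        raise FormatError(f"{path}: missing dataset {name!r}")
    return f[name]


def _check_kind(f: h5py.File, kind: str, path) -> None:
    found = f.attrs.get("kind")
    if found != kind:
        raise FormatError(f"{path}: expected a {kind!r} container, found {found!r}")


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a continuous recording to the HDF5 interchange container."""
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "recording"
        f.attrs["format_version"] = _FORMAT_VERSION
        f.create_dataset("data", data=rec.data)
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset("channel_labels", data=np.array(rec.channel_labels, dtype=_STR))
        markers = np.array(rec.markers, dtype=np.int64).reshape(-1, 2)
        f.create_dataset("markers", data=markers)


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        _check_kind(f, "recording", path)
        data = _require(f, "data", path)[()]
        fs = float(_require(f, "fs", path)[()])
        labels = [c.decode() if isinstance(c, bytes) else str(c)
                  for c in _require(f, "channel_labels", path)[()]]
        markers = [tuple(row) for row in _require(f, "markers", path)[()]]
    return Recording(data=data, fs=fs, channel_labels=labels, markers=markers)


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write an epoch set losslessly; refuses an empty trial list."""
    if epochs.n_trials == 0:
        raise ConfigurationError("refusing to write an empty epoch set")
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "epochs"
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["n_trials"] = epochs.n_trials
        f.attrs["n_channels"] = epochs.n_channels
        f.attrs["n_samples"] = epochs.n_samples
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("fs", data=float(epochs.fs))
        f.create_dataset("window", data=np.array(epochs.window, dtype=np.float64))
        f.create_dataset(
            "channel_labels", data=np.array(epochs.channel_labels, dtype=_STR)
        )


def read_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        _check_kind(f, "epochs", path)
        data = _require(f, "data", path)[()]
        labels = _require(f, "labels", path)[()]
        fs = float(_require(f, "fs", path)[()])
        window = tuple(_require(f, "window", path)[()])
        clab = [c.decode() if isinstance(c, bytes) else str(c)
                for c in _require(f, "channel_labels", path)[()]]
    return EpochSet(data=data, labels=labels, fs=fs, window=window, channel_labels=clab)


def save_csp_model(model: CspModel, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "csp_model"
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["m"] = model.m
        f.create_dataset("P", data=model.whitener)
        f.create_dataset("filters", data=model.filters)
        f.create_dataset("W2m", data=model.filter_bank)
        f.create_dataset("eigvals_a", data=model.eigvals_a)
        f.create_dataset("eigvals_b", data=model.eigvals_b)
        f.create_dataset("class_order", data=np.array(model.class_order, dtype=np.int64))


def load_csp_model(path: str | Path) -> CspModel:
    with h5py.File(path, "r") as f:
        _check_kind(f, "csp_model", path)
        return CspModel(
            whitener=_require(f, "P", path)[()],
            filters=_require(f, "filters", path)[()],
            filter_bank=_require(f, "W2m", path)[()],
            eigvals_a=_require(f, "eigvals_a", path)[()],
            eigvals_b=_require(f, "eigvals_b", path)[()],
            m=int(f.attrs["m"]),
            class_order=tuple(int(c) for c in _require(f, "class_order", path)[()]),
        )


# ---------------------------------------------------------------------------
# CSV outputs
# ---------------------------------------------------------------------------

def write_features_csv(features: FeatureMatrix, path: str | Path) -> None:
    """Feature matrix as CSV: one row per trial, label column first."""
    df = pd.DataFrame(
        features.values,
        columns=[f"logvar_{j + 1}" for j in range(features.values.shape[1])],
    )
    df.insert(0, "label", features.labels)
    df.to_csv(path, index=False)


def write_report_csv(report, path: str | Path, subject: str = "sim") -> None:
    """Cross-validation report as long-format CSV
    (subject, classifier, fold, accuracy, mean)."""
    report.to_dataframe(subject=subject).to_csv(path, index=False)
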