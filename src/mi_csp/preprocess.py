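"""Preprocessing: channel selection, band-pass filtering, ICA cleaning, epoching.

The fixed stage order is channel selection -> 8-15 Hz Butterworth band-pass
(zero-phase) -> ICA artifact rejection -> epoch extraction.  ICA decomposes
the sensor signal Y into statistically independent sources S = W (Y - mean);
blink/ocular components are flagged by excess kurtosis and/or correlation
with low-pass-filtered frontal channels, and the cleaned signal is
reconstructed from the retained columns of the mixing matrix A.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal, stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .errors import ConfigurationError, EpochingError, EstimationError
from .types import EpochSet, Recording

__all__ = [
    "IcaModel",
    "select_channels",
    "butter_bandpass",
    "fit_ica",
    "flag_artifact_components",
    "remove_components",
    "extract_epochs",
    "amari_index",
]

logger = logging.getLogger(__name__)

DEFAULT_BAND = (8.0, 15.0)
DEFAULT_WINDOW = (0.5, 2.5)
DEFAULT_KURTOSIS_THRESH = 5.0
DEFAULT_CORR_THRESH = 0.8
#: cutoff (Hz) of the low-pass used to isolate ocular activity on frontal channels
EOG_LOWPASS_HZ = 4.0


# ---------------------------------------------------------------------------
# channel selection
# ---------------------------------------------------------------------------

def select_channels(
    rec: Recording,
    strategy: str = "all",
    *,
    keep: Sequence[str] | None = None,
    peripheral: Sequence[str] | None = None,
) -> Recording:
    """Restrict a recording to a subset of channels, order preserved.

    Parameters
    ----------
    strategy : {"all", "drop-peripheral", "explicit"}
        ``"all"`` returns the recording unchanged; ``"drop-peripheral"``
        removes the channels annotated as peripheral/outermost in
        ``peripheral``; ``"explicit"`` keeps exactly the labels in ``keep``
        (in their original relative order).
    """
    labels = rec.channel_labels
    if strategy == "all":
        retained = list(labels)
    elif strategy == "explicit":
        if keep is None:
            raise ConfigurationError("strategy 'explicit' requires a keep list")
        missing = [c for c in keep if c not in labels]
        if missing:
            raise ConfigurationError(f"channels not in recording: {missing}")
        keep_set = set(keep)
        retained = [c for c in labels if c in keep_set]
    elif strategy == "drop-peripheral":
        if peripheral is None:
            raise ConfigurationError(
                "strategy 'drop-peripheral' requires a peripheral channel annotation"
            )
        drop = set(peripheral)
        retained = [c for c in labels if c not in drop]
    else:
        raise ConfigurationError(f"unknown channel-selection strategy {strategy!r}")
    if not retained:
        raise ConfigurationError("channel selection retained no channels")
    if len(retained) < len(labels):
        logger.info("channel selection: %d -> %d channels", len(labels), len(retained))
    idx = [labels.index(c) for c in retained]
    return Recording(
        data=rec.data[idx],
        fs=rec.fs,
        channel_labels=retained,
        markers=list(rec.markers),
    )


# ---------------------------------------------------------------------------
# band-pass filtering
# ---------------------------------------------------------------------------

def butter_bandpass(
    rec: Recording,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 4,
) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    output is not time-shifted relative to the cue markers and the effective
    attenuation order is doubled.
    """
    if not 0 < low < high:
        raise ConfigurationError(f"need 0 < low < high, got ({low}, {high})")
    if high >= rec.fs / 2:
        raise ConfigurationError(
            f"high edge {high} Hz is not below Nyquist ({rec.fs / 2} Hz)"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=1))


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

@dataclass
class IcaModel:
    """Fitted ICA decomposition of a (band-passed) recording.

    ``sources = unmixing @ (data - mean)`` with every source normalized to
    unit variance; ``mixing @ unmixing`` is the identity on the retained
    subspace.  Source sign and order are not identifiable in general; here
    components are ordered by decreasing explained sensor variance and each
    mixing column has its largest-magnitude entry made positive, which pins
    a unique representative for reproducibility.
    """

    unmixing: np.ndarray  # (k, n_channels)
    mixing: np.ndarray    # (n_channels, k)
    sources: np.ndarray   # (k, n_samples)
    mean: np.ndarray      # (n_channels,)
    n_iter: int
    tol: float
    n_restarts: int = 0
    artifact_idx: set[int] = field(default_factory=set)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]


def _data_rank(X: np.ndarray) -> int:
    # numerical rank of the channel covariance
    Xc = X - X.mean(axis=1, keepdims=True)
    ev = np.linalg.eigvalsh(Xc @ Xc.T / X.shape[1])
    return int(np.sum(ev > 1e-10 * max(ev.max(), 1e-300)))


def fit_ica(
    rec: Recording,
    n_components: int | None = None,
    seed: int = 0,
    *,
    tol: float = 1e-4,
    max_iter: int = 1000,
    max_restarts: int = 8,
) -> IcaModel:
    """Fixed-point ICA (negentropy maximization, log-cosh contrast).

    Uses symmetric decorrelation with PCA whitening to ``n_components``
    dimensions.  The fit is deterministic given ``seed``; on non-convergence
    it is restarted with a fresh derived seed up to ``max_restarts`` times
    before raising :class:`EstimationError`.

    Each restart relaxes the convergence tolerance tenfold (capped at
    1e-2).  Narrowband EEG mixtures contain a nearly rotation-invariant
    subspace of weakly non-Gaussian background components in which the
    symmetric fixed-point update has no sharp optimum; the strongly
    non-Gaussian components of interest (discriminative sources, blinks)
    stabilize long before the global criterion is met, so accepting a looser
    criterion on such data is preferable to failing.  The tolerance actually
    achieved is recorded in ``IcaModel.tol``.

    Raises
    ------
    EstimationError
        If ``n_components`` exceeds the numerical rank of the data, or the
        algorithm fails to converge after all restarts.
    """
    X = rec.data
    k = rec.n_channels if n_components is None else int(n_components)
    if k > rec.n_channels:
        raise ConfigurationError(
            f"n_components={k} exceeds n_channels={rec.n_channels}"
        )
    rank = _data_rank(X)
    if k > rank:
        raise EstimationError(
            f"requested {k} components but data has numerical rank {rank}; "
            "reduce n_components or drop redundant channels"
        )

    last_n_iter = 0
    for attempt in range(max_restarts):
        attempt_tol = min(tol * 10.0**attempt, 1e-2)
        ica = FastICA(
            n_components=k,
            algorithm="parallel",
            fun="logcosh",
            whiten="unit-variance",
            tol=attempt_tol,
            max_iter=max_iter,
            random_state=seed + attempt,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                S = ica.fit_transform(X.T).T  # (k, n_samples)
            except ConvergenceWarning:
                last_n_iter = max_iter
                logger.warning(
                    "ICA did not converge at tol=%g (attempt %d/%d); restarting",
                    attempt_tol,
                    attempt + 1,
                    max_restarts,
                )
                continue
        unmixing = ica.components_          # (k, n_ch)
        mixing = ica.mixing_                # (n_ch, k)
        mean = ica.mean_

        # order by explained sensor variance (sources are unit variance,
        # so the variance a component explains is ||A[:, k]||^2)
        order = np.argsort(-np.linalg.norm(mixing, axis=0))
        unmixing, mixing, S = unmixing[order], mixing[:, order], S[order]
        # sign convention: largest-|entry| of each mixing column positive
        for j in range(k):
            i = int(np.argmax(np.abs(mixing[:, j])))
            if mixing[i, j] < 0:
                mixing[:, j] *= -1
                unmixing[j] *= -1
                S[j] *= -1
        return IcaModel(
            unmixing=unmixing,
            mixing=mixing,
            sources=S,
            mean=mean,
            n_iter=int(ica.n_iter_),
            tol=attempt_tol,
            n_restarts=attempt,
        )
    raise EstimationError(
        f"ICA failed to converge after {max_restarts} restarts "
        f"(max_iter={max_iter}, tol={tol}, last iteration count {last_n_iter})"
    )


def flag_artifact_components(
    model: IcaModel,
    rec: Recording,
    frontal_labels: Iterable[str] = (),
    kurtosis_thresh: float = DEFAULT_KURTOSIS_THRESH,
    corr_thresh: float = DEFAULT_CORR_THRESH,
) -> set[int]:
    """Flag independent components that look like ocular artifacts.

    A component is flagged when its excess kurtosis exceeds
    ``kurtosis_thresh`` in magnitude (blinks are impulsive, hence strongly
    super-Gaussian) OR when its absolute correlation with any
    low-pass-filtered (< 4 Hz) frontal channel exceeds ``corr_thresh``.
    Setting ``corr_thresh >= 1`` disables the correlation criterion;
    ``kurtosis_thresh = inf`` disables the kurtosis criterion.

    ``rec`` must be the recording the model was fitted on.
    """
    flagged: set[int] = set()
    kurt = stats.kurtosis(model.sources, axis=1, fisher=True, bias=False)
    if np.isfinite(kurtosis_thresh):
        flagged |= set(np.nonzero(np.abs(kurt) > kurtosis_thresh)[0].tolist())

    if corr_thresh < 1.0:
        frontal_idx = [
            rec.channel_labels.index(c) for c in frontal_labels if c in rec.channel_labels
        ]
        if not frontal_idx:
            raise ConfigurationError(
                "correlation criterion requested but none of the frontal labels "
                f"{list(frontal_labels)} are present in the recording"
            )
        sos = signal.butter(4, EOG_LOWPASS_HZ, btype="lowpass", fs=rec.fs, output="sos")
        eog = signal.sosfiltfilt(sos, rec.data[frontal_idx], axis=1)
        for j in range(model.n_components):
            s = model.sources[j]
            for e in eog:
                denom = s.std() * e.std()
                if denom == 0:
                    continue
                r = np.abs(np.mean((s - s.mean()) * (e - e.mean())) / denom)
                if r > corr_thresh:
                    flagged.add(j)
                    break
    if flagged:
        logger.info("flagged %d artifact component(s): %s", len(flagged), sorted(flagged))
    return flagged


def remove_components(model: IcaModel, rec: Recording, idx: Iterable[int]) -> Recording:
    """Reconstruct the recording with the components in ``idx`` zeroed out.

    Output is ``A[:, keep] @ S[keep, :]`` plus the per-channel means, i.e. a
    linear projection of the input: applying it twice with the same ``idx``
    equals applying it once.  With ``idx`` empty (full-rank model) the input
    is reproduced; with all components removed only the channel means remain.
    """
    idx = set(int(i) for i in idx)
    bad = [i for i in idx if not 0 <= i < model.n_components]
    if bad:
        raise IndexError(
            f"component indices {bad} out of range [0, {model.n_components})"
        )
    keep = [j for j in range(model.n_components) if j not in idx]
    clean = model.mixing[:, keep] @ model.sources[keep] + model.mean[:, None]
    return rec.with_data(clean)


def amari_index(W: np.ndarray, A: np.ndarray) -> float:
    """Permutation- and scale-invariant unmixing error, normalized to [0, 1].

    ``W`` is an estimated unmixing matrix and ``A`` the true mixing matrix;
    the index is 0 iff ``W @ A`` is a scaled permutation (perfect recovery).
    """
    P = np.abs(np.asarray(W) @ np.asarray(A))
    n = P.shape[0]
    rows = (P.sum(axis=1) / P.max(axis=1) - 1).sum()
    cols = (P.sum(axis=0) / P.max(axis=0) - 1).sum()
    return float((rows + cols) / (2 * n * (n - 1)))


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def extract_epochs(
    rec: Recording, window: tuple[float, float] = DEFAULT_WINDOW
) -> EpochSet:
    """Cut fixed-length trials around each cue marker.

    The window is in seconds relative to the marker onset; samples are taken
    from the half-open index range
    ``[onset + round(start * fs), onset + round(start * fs) + n)`` with
    ``n = round((end - start) * fs)``, so a (0.5, 2.5) window at 100 Hz
    yields exactly 200 samples per trial.
    """
    start_s, end_s = float(window[0]), float(window[1])
    if end_s <= start_s:
        raise ConfigurationError(f"window end must exceed start, got {window}")
    n = int(round((end_s - start_s) * rec.fs))
    offset = int(round(start_s * rec.fs))
    trials = []
    labels = []
    for t, (onset, label) in enumerate(rec.markers):
        i0 = onset + offset
        i1 = i0 + n
        if i0 < 0 or i1 > rec.n_samples:
            raise EpochingError(
                f"trial {t} (onset sample {onset}): window {window} spans samples "
                f"[{i0}, {i1}) outside the recording of {rec.n_samples} samples"
            )
        trials.append(rec.data[:, i0:i1])
        labels.append(label)
    if not trials:
        raise EpochingError("recording has no markers to epoch")
    return EpochSet(
        data=np.stack(trials),
        labels=np.asarray(labels, dtype=np.int64),
        fs=rec.fs,
        window=(start_s, end_s),
        channel_labels=list(rec.channel_labels),
    )
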