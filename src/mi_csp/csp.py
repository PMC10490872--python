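"""Common spatial patterns and log-variance features for two-class trials.

CSP finds spatial filters w that maximize the variance of the filtered
signal for one class while minimizing it for the other.  With trace-
normalized, class-averaged covariances C_a and C_b, the construction is:

1.  Composite covariance  C = C_a + C_b = U diag(s) U^T.
2.  Whitening  P = diag(s)^{-1/2} U^T,  so  P C P^T = I.
3.  The whitened class covariances  S_a = P C_a P^T  and  S_b = P C_b P^T
    share eigenvectors V, and their paired eigenvalues sum to one:
    lambda_a[i] + lambda_b[i] = 1.
4.  Filters are the columns of  W = P^T V, sorted by lambda_a descending;
    the first m and last m columns (the filters most discriminative for
    class a and class b respectively) form the 2m-column bank W_2m.

Each trial X is projected to Z = W_2m^T X and summarized by the feature
vector f_j = log(var(Z_j)), giving 2m log-variance features per trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, EstimationError
from .types import EpochSet

__all__ = [
    "CspModel",
    "FeatureMatrix",
    "normalized_trial_covariance",
    "fit_csp",
    "apply_filters",
    "logvar_features",
    "csp_logvar",
]

_RANK_RTOL = 1e-10


@dataclass
class CspModel:
    """Fitted CSP filter bank.

    Attributes
    ----------
    whitener : ndarray (n_channels, n_channels)
        P with P (C_a + C_b) P^T = I.
    filters : ndarray (n_channels, n_channels)
        Full filter matrix W = P^T V, one filter per column, sorted by
        ``eigvals_a`` descending.  Sign convention: the largest-magnitude
        entry of every column is positive.
    filter_bank : ndarray (n_channels, 2m)
        First m and last m columns of ``filters``.
    eigvals_a, eigvals_b : ndarray (n_channels,)
        Paired eigenvalue spectra of the whitened class covariances;
        ``eigvals_a`` is descending and ``eigvals_a + eigvals_b == 1``
        element-wise.
    m : int
        Filters kept per end of the spectrum.
    class_order : (int, int)
        The labels (label_a, label_b) the spectra refer to, ascending.
    """

    whitener: np.ndarray
    filters: np.ndarray
    filter_bank: np.ndarray
    eigvals_a: np.ndarray
    eigvals_b: np.ndarray
    m: int
    class_order: tuple[int, int]

    @property
    def n_channels(self) -> int:
        return self.filters.shape[0]

    @property
    def patterns(self) -> np.ndarray:
        """Spatial patterns (columns), the pseudo-inverse transpose of the
        full filter matrix; pattern j is the sensor topography of the source
        that filter j extracts."""
        return np.linalg.pinv(self.filters.T)


@dataclass
class FeatureMatrix:
    """Per-trial log-variance features: ``values`` is (n_trials, 2m)."""

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2 or len(self.labels) != self.values.shape[0]:
            raise ConfigurationError("feature matrix must be (n_trials, n_features)")
        if not np.isfinite(self.values).all():
            raise DegenerateInputError("feature matrix contains non-finite entries")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


def normalized_trial_covariance(trial: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance of one trial.

    Per-channel means are removed, then ``C = X X^T / trace(X X^T)``: a
    symmetric positive-semidefinite matrix with unit trace, invariant to the
    overall amplitude of the trial.
    """
    X = np.asarray(trial, dtype=np.float64)
    if X.ndim != 2:
        raise ConfigurationError(f"trial must be 2-D (channels x samples), got {X.ndim}-D")
    X = X - X.mean(axis=1, keepdims=True)
    C = X @ X.T
    tr = np.trace(C)
    if not np.isfinite(tr) or tr <= 0:
        raise DegenerateInputError("trial has zero (or non-finite) total variance")
    return C / tr


def fit_csp(epochs: EpochSet, m: int = 3) -> CspModel:
    """Estimate CSP filters from a two-class epoch set.

    Per-class covariances are the average of the trace-normalized trial
    covariances.  Filters are sorted by the class-a eigenvalue descending and
    the bank keeps ``m`` filters from each end of the spectrum (2m filters
    total; the default m=3 gives six).

    Raises
    ------
    EstimationError
        On single-class input, fewer than two trials in a class, or a
        rank-deficient composite covariance (suggesting channel reduction).
    ConfigurationError
        If ``2m`` exceeds the channel count.
    """
    classes = np.unique(epochs.labels)
    if classes.size != 2:
        raise EstimationError(
            f"CSP requires exactly two classes, got labels {classes.tolist()}"
        )
    n_ch = epochs.n_channels
    if m < 1 or 2 * m > n_ch:
        raise ConfigurationError(
            f"need 1 <= m and 2m <= n_channels, got m={m}, n_channels={n_ch}"
        )
    label_a, label_b = int(classes[0]), int(classes[1])

    cov_mean = {}
    for lab in (label_a, label_b):
        trials = epochs.data[epochs.labels == lab]
        if trials.shape[0] < 2:
            raise EstimationError(f"class {lab} has {trials.shape[0]} trial(s); need >= 2")
        cov_mean[lab] = np.mean(
            [normalized_trial_covariance(t) for t in trials], axis=0
        )
    Ca, Cb = cov_mean[label_a], cov_mean[label_b]

    C = Ca + Cb
    s, U = np.linalg.eigh(C)
    if s.min() < _RANK_RTOL * s.max():
        raise EstimationError(
            "composite covariance is rank-deficient; remove linearly dependent "
            "channels or reduce the channel set before CSP"
        )
    P = (U / np.sqrt(s)).T  # diag(s)^{-1/2} U^T

    Sa = P @ Ca @ P.T
    Sb = P @ Cb @ P.T
    la, V = np.linalg.eigh(Sa)          # ascending
    order = np.argsort(la)[::-1]
    la = la[order]
    V = V[:, order]
    # V diagonalizes Sb as well (Sa + Sb = I); measure lambda_b explicitly
    lb = np.einsum("ij,jk,ki->i", V.T, Sb, V)

    W = P.T @ V
    for j in range(n_ch):  # deterministic sign: largest-|entry| positive
        i = int(np.argmax(np.abs(W[:, j])))
        if W[i, j] < 0:
            W[:, j] *= -1
    bank = np.concatenate([W[:, :m], W[:, n_ch - m :]], axis=1)
    return CspModel(
        whitener=P,
        filters=W,
        filter_bank=bank,
        eigvals_a=la,
        eigvals_b=lb,
        m=m,
        class_order=(label_a, label_b),
    )


def apply_filters(model: CspModel, epochs: EpochSet) -> np.ndarray:
    """Project every trial through the filter bank: ``Z = W_2m^T X``.

    Returns an array of shape ``(n_trials, 2m, n_samples)``.  The map is
    linear, so scaling a trial scales its projection.
    """
    if epochs.n_channels != model.n_channels:
        raise ConfigurationError(
            f"epochs have {epochs.n_channels} channels, model expects {model.n_channels}"
        )
    return np.einsum("cf,tcs->tfs", model.filter_bank, epochs.data)


def logvar_features(Z: np.ndarray, labels: np.ndarray) -> FeatureMatrix:
    """Log of the unbiased sample variance of each filtered signal.

    ``Z`` is the (n_trials, 2m, n_samples) output of :func:`apply_filters`;
    the result is one 2m-vector of natural-log variances per trial.  Filter
    sign is immaterial (variance is even), and scaling a trial by c adds
    2 ln c to every feature.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 3:
        raise ConfigurationError("Z must be (n_trials, n_filters, n_samples)")
    var = Z.var(axis=2, ddof=1)
    bad = np.argwhere(var <= 0)
    if bad.size:
        t, f = bad[0]
        raise DegenerateInputError(
            f"filtered signal has zero variance at trial {t}, filter {f}"
        )
    return FeatureMatrix(values=np.log(var), labels=labels)


def csp_logvar(epochs: EpochSet, m: int = 3) -> tuple[CspModel, FeatureMatrix]:
    """Convenience fit-and-transform: CSP filters plus log-variance features."""
    model = fit_csp(epochs, m=m)
    feats = logvar_features(apply_filters(model, epochs), epochs.labels)
    return model, feats
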