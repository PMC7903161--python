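"""Spatial filtering by joint diagonalization of narrowband covariances.

The during-stimulation covariance ``A`` and the stimulation-free covariance
``B`` of band-filtered full-length recordings are jointly diagonalized
(``A w_i = lambda_i B w_i``). Components with the largest power ratio
``lambda_i`` are attributed to the stimulation artifact and removed by the
projection ``P = pinv(W) S W`` with ``S`` zeroing the rejected components.
An SSP baseline (plain eigendecomposition of ``A``) is provided for
comparison. Models are always fit per dataset pair and never transferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import linalg

from .preprocess import FilterSpec, design_fir, filter_recording
from .recording import MultichannelRecording

_RIDGE_EPS = 1e-9
_COND_LIMIT = 1e10
_PINV_RTOL = 1e-12


@dataclass(frozen=True)
class SensorCovariance:
    """Symmetric PSD channel covariance tagged with band and condition."""

    matrix: np.ndarray
    band: tuple[float, float]
    condition: str  # "stim" | "no_stim"
    n_samples_used: int
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        if m.shape[0] != len(self.channel_labels):
            raise ValueError("labels must match covariance size")
        scale = max(np.abs(m).max(), 1.0)
        if np.abs(m - m.T).max() > 1e-10 * scale:
            raise ValueError("covariance not symmetric")
        w = np.linalg.eigvalsh((m + m.T) / 2)
        if w.min() < -1e-10 * max(np.trace(m), 1.0):
            raise ValueError("covariance not positive semi-definite")


@dataclass
class SassModel:
    """Generalized eigenfilters, power ratios, and the rejection projection."""

    W: np.ndarray  # rows are spatial filters w_i^T
    lambdas: np.ndarray  # power ratios, sorted descending
    band: tuple[float, float]
    channel_labels: tuple[str, ...]
    k_rejected: Optional[int] = None
    P: Optional[np.ndarray] = None
    selection_curve: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]


def band_covariance(
    rec: MultichannelRecording, band: tuple[float, float], condition: str = "stim"
) -> SensorCovariance:
    """Empirical covariance of the full-length band-filtered recording.

    Channel means are removed; the unbiased 1/(N-1) estimator is used (the
    choice is immaterial at full-recording sample counts). The recording is
    expected to be already filtered to ``band`` with bad channels removed.
    """
    x = rec.data
    if rec.n_samples < rec.n_channels:
        warnings.warn("fewer samples than channels: rank-deficient covariance",
                      stacklevel=2)
    variances = x.var(axis=1)
    if np.any(variances == 0):
        dead = [lb for lb, v in zip(rec.channel_labels, variances) if v == 0]
        raise ValueError(f"zero-variance channels should have been excluded: {dead}")
    cov = np.cov(x, ddof=1)
    return SensorCovariance(
        matrix=np.atleast_2d(cov),
        band=tuple(band),
        condition=condition,
        n_samples_used=rec.n_samples,
        channel_labels=tuple(rec.channel_labels),
    )


def joint_diagonalize(A: SensorCovariance, B: SensorCovariance) -> SassModel:
    """Solve ``A w = lambda B w`` for the full set of generalized eigenpairs.

    Filters are B-normalized (``w_i^T B w_i = 1``) and sorted by descending
    power ratio. ``B`` receives a small ridge when badly conditioned.
    """
    if A.channel_labels != B.channel_labels:
        raise ValueError("covariances computed on different channel sets")
    if A.band != B.band:
        raise ValueError("covariances computed on different bands")
    a = (A.matrix + A.matrix.T) / 2
    b = (B.matrix + B.matrix.T) / 2
    n = a.shape[0]
    if np.linalg.cond(b) > _COND_LIMIT:
        b = b + _RIDGE_EPS * np.trace(b) / n * np.eye(n)
    try:
        lam, vecs = linalg.eigh(a, b)
    except linalg.LinAlgError as err:
        raise ValueError(
            "B singular beyond regularization: exclude dead channels or add "
            "a stronger ridge"
        ) from err
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    W = vecs[:, order].T  # rows are filters; eigh returns B-orthonormal columns
    return SassModel(
        W=W, lambdas=lam, band=A.band, channel_labels=A.channel_labels
    )


def build_projection(model: SassModel, k: int) -> SassModel:
    """Attach the projection removing the ``k`` largest-ratio components."""
    n = model.n_channels
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, {n}]")
    if k == n:
        warnings.warn("k = n rejects all components: P is the zero matrix",
                      stacklevel=2)
    s = np.ones(n)
    s[:k] = 0.0  # lambdas (and W rows) are sorted descending
    W_pinv = np.linalg.pinv(model.W, rcond=_PINV_RTOL)
    P = W_pinv @ (s[:, None] * model.W)
    return replace(model, k_rejected=k, P=P)


def selection_mse_curve(
    model: SassModel, A: SensorCovariance, B: SensorCovariance
) -> np.ndarray:
    """Mean squared per-channel band-power mismatch for every candidate k.

    Per-channel power of the cleaned stimulation data equals
    ``diag(P A P^T)`` exactly, so the exhaustive 0..n search is closed-form
    and cheap.
    """
    n = model.n_channels
    target = np.diag(B.matrix)
    W_pinv = np.linalg.pinv(model.W, rcond=_PINV_RTOL)
    curve = np.empty(n + 1)
    for k in range(n + 1):
        s = np.ones(n)
        s[:k] = 0.0
        P = W_pinv @ (s[:, None] * model.W)
        cleaned = np.einsum("ij,jk,ik->i", P, A.matrix, P)
        curve[k] = np.mean((cleaned - target) ** 2)
    return curve


def select_component_count(
    model: SassModel,
    rec_stim_filtered: MultichannelRecording,
    rec_nostim_filtered: MultichannelRecording,
) -> int:
    """Choose the rejection count minimizing the band-power MSE to no-stim.

    Ties are broken toward the smaller k (reject least). The curve is
    stored on the model as ``selection_curve``.
    """
    A = band_covariance(rec_stim_filtered, model.band, "stim")
    B = band_covariance(rec_nostim_filtered, model.band, "no_stim")
    if A.channel_labels != model.channel_labels:
        raise ValueError("recording channels do not match the model")
    curve = selection_mse_curve(model, A, B)
    k = int(np.argmin(curve))  # argmin returns the first (smallest) k on ties
    model.selection_curve = curve
    return k


def apply_projection(
    P_or_model, rec: MultichannelRecording
) -> MultichannelRecording:
    """Apply a rejection projection sample-wise; metadata is untouched.

    Accepts a fitted :class:`SassModel` (labels are checked) or a bare
    matrix. Works on broadband or narrowband input alike.
    """
    if isinstance(P_or_model, SassModel):
        if P_or_model.P is None:
            raise ValueError("model has no projection: call build_projection")
        if tuple(rec.channel_labels) != P_or_model.channel_labels:
            raise ValueError("recording channels do not match the model")
        P = P_or_model.P
    else:
        P = np.asarray(P_or_model, dtype=float)
        if P.shape != (rec.n_channels, rec.n_channels):
            raise ValueError("projection size does not match the recording")
    return rec.copy(data=P @ rec.data)


def fit_sass(
    rec_stim: MultichannelRecording,
    rec_nostim: MultichannelRecording,
    band: tuple[float, float],
    k: Optional[int] = None,
    prefiltered: bool = False,
) -> SassModel:
    """Full fit: filter both recordings, diagonalize, select k, build P."""
    if tuple(rec_stim.channel_labels) != tuple(rec_nostim.channel_labels):
        raise ValueError("both recordings must share the channel set")
    if prefiltered:
        stim_f, nostim_f = rec_stim, rec_nostim
    else:
        kernel = design_fir(FilterSpec(*band), rec_stim.fs)
        stim_f = filter_recording(rec_stim, kernel)
        nostim_f = filter_recording(rec_nostim, kernel)
    A = band_covariance(stim_f, band, "stim")
    B = band_covariance(nostim_f, band, "no_stim")
    model = joint_diagonalize(A, B)
    if k is None:
        k = select_component_count(model, stim_f, nostim_f)
    return replace(build_projection(model, k),
                   selection_curve=model.selection_curve)


def harmonic_sass(
    rec_stim: MultichannelRecording,
    rec_nostim: MultichannelRecording,
    f0: float,
    harmonics: Sequence[int],
    half_width: float = 1.0,
) -> list[tuple[tuple[float, float], SassModel]]:
    """Independent SASS fit per harmonic band ``f0*h +/- half_width``."""
    bands = [(f0 * h - half_width, f0 * h + half_width) for h in harmonics]
    nyq = rec_stim.fs / 2
    for low, high in bands:
        if high >= nyq:
            raise ValueError(f"band ({low}, {high}) exceeds Nyquist {nyq}")
    for (l1, h1), (l2, h2) in zip(bands, bands[1:]):
        if h1 > l2:
            raise ValueError("harmonic bands overlap")
    return [(band, fit_sass(rec_stim, rec_nostim, band)) for band in bands]


def ssp_baseline(A: SensorCovariance, k: int) -> np.ndarray:
    """Orthogonal projection away from the top-k variance components of A."""
    n = A.matrix.shape[0]
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, {n}]")
    lam, vecs = np.linalg.eigh((A.matrix + A.matrix.T) / 2)
    keep = vecs[:, : n - k]  # eigh sorts ascending: drop the last k
    return keep @ keep.T
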