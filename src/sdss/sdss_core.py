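"""Covariance estimation, spatial smoothing, and adaptive beamforming.

The reconstruction chain implemented here is:

1. sample covariance ``R = (1/T) sum_t x(t) x(t)^H`` of the full array;
2. forward spatial smoothing -- the mean of the q overlapping
   unit-shift principal blocks of size ``l = M - q + 1``;
3. backward smoothing -- forward smoothing of the exchange-conjugated
   matrix ``J R* J``;
4. forward-backward (FB) averaging ``R_s = (R_s^f + R_s^b) / 2``, which
   is persymmetric and decorrelates fully coherent echoes (the clinical
   artifact case), restoring the covariance rank on the sub-array;
5. minimum-variance (Capon/MVDR) weights with diagonal loading
   ``w = (R_s + eps I)^{-1} a / (a^H (R_s + eps I)^{-1} a)`` applied on
   the sub-array, producing per-direction output power ``w^H R_s w``.

A delay-and-sum (DAS) baseline and two simplified post-filter
comparators (Wiener gain S/(S+N); SNR gain snr/(1+snr)) are included so
reconstructions can be compared with the same metrics harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .probe_sim import ArrayGeometry, SnapshotFrame, steering_vector

__all__ = [
    "CovarianceEstimate",
    "BeamformerWeights",
    "ReconImage",
    "sample_covariance",
    "forward_smooth",
    "backward_smooth",
    "fb_smooth",
    "mvdr_weights",
    "beamform_image",
    "wiener_postfilter",
    "snr_postfilter",
    "mainlobe_width",
]

_HERM_RTOL = 1e-10


@dataclass
class CovarianceEstimate:
    """Hermitian PSD covariance matrix with a provenance kind.

    kind ``sample`` lives on the full array (size M); kinds ``forward``,
    ``backward`` and ``fb`` live on the sub-array (size l = M - q + 1).
    """

    matrix: np.ndarray
    kind: str = "sample"
    source_frame_id: str | None = None

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=complex)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError("covariance matrix must be square")
        if self.kind not in {"sample", "forward", "backward", "fb"}:
            raise ValueError(f"unknown covariance kind {self.kind!r}")
        scale = max(np.abs(mat).max(), 1.0)
        if np.abs(mat - mat.conj().T).max() > _HERM_RTOL * scale:
            raise ValueError("covariance matrix is not Hermitian")
        # symmetrize away representation-level asymmetry
        mat = 0.5 * (mat + mat.conj().T)
        trace = float(np.real(np.trace(mat)))
        eigmin = float(scipy.linalg.eigvalsh(mat)[0]) if mat.size else 0.0
        if eigmin < -1e-10 * max(trace, 1.0):
            raise ValueError("covariance matrix is not positive semidefinite")
        self.matrix = mat

    @property
    def size(self) -> int:
        return self.matrix.shape[0]


@dataclass
class BeamformerWeights:
    """Complex weight vector plus the loading actually applied."""

    weights: np.ndarray
    loading_used: float
    method: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=complex).ravel()
        if self.loading_used < 0:
            raise ValueError("loading must be >= 0")


@dataclass
class ReconImage:
    """Nonnegative envelope raster; log compression is applied on demand."""

    pixels: np.ndarray
    dynamic_range_db: float = 60.0
    method: str = ""
    angles: np.ndarray | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ValueError("pixels must be finite and nonnegative")
        self.pixels = px

    def log_compressed(self) -> np.ndarray:
        """Envelope in dB relative to peak, clipped to the dynamic range."""
        peak = self.pixels.max()
        if peak <= 0:
            return np.full_like(self.pixels, -self.dynamic_range_db)
        db = 20.0 * np.log10(np.maximum(self.pixels, peak * 1e-30) / peak)
        return np.clip(db, -self.dynamic_range_db, 0.0)


def sample_covariance(frame: SnapshotFrame) -> CovarianceEstimate:
    """``(1/T) sum_t x(t) x(t)^H`` over all snapshots in the frame."""
    if frame.sample_count < 1:
        raise ValueError("frame must contain at least one snapshot")
    x = frame.data
    mat = (x @ x.conj().T) / frame.sample_count
    return CovarianceEstimate(matrix=mat, kind="sample")


def _check_smoothing_args(r: CovarianceEstimate, q: int) -> int:
    if r.kind != "sample":
        raise ValueError("smoothing expects a kind='sample' covariance of the full array")
    m = r.size
    if not 1 <= q <= m:
        raise ValueError(f"q must satisfy 1 <= q <= M={m}, got {q}")
    return m - q + 1


def forward_smooth(r: CovarianceEstimate, q: int) -> CovarianceEstimate:
    """Mean of the q overlapping unit-shift diagonal blocks of size M - q + 1."""
    sub = _check_smoothing_args(r, q)
    mat = r.matrix
    acc = np.zeros((sub, sub), dtype=complex)
    for i in range(q):
        acc += mat[i : i + sub, i : i + sub]
    return CovarianceEstimate(matrix=acc / q, kind="forward",
                              source_frame_id=r.source_frame_id)


def backward_smooth(r: CovarianceEstimate, q: int) -> CovarianceEstimate:
    """Forward smoothing of the exchange-conjugated matrix J R* J."""
    _check_smoothing_args(r, q)
    j = np.eye(r.size)[::-1]
    flipped = CovarianceEstimate(matrix=j @ r.matrix.conj() @ j, kind="sample",
                                 source_frame_id=r.source_frame_id)
    out = forward_smooth(flipped, q)
    return CovarianceEstimate(matrix=out.matrix, kind="backward",
                              source_frame_id=r.source_frame_id)


def fb_smooth(r: CovarianceEstimate, q: int) -> CovarianceEstimate:
    """Forward-backward smoothed covariance: the mean of forward and backward.

    The result is persymmetric (``J R_s* J = R_s``) by construction.
    """
    fwd = forward_smooth(r, q)
    bwd = backward_smooth(r, q)
    return CovarianceEstimate(matrix=0.5 * (fwd.matrix + bwd.matrix), kind="fb",
                              source_frame_id=r.source_frame_id)


def mvdr_weights(
    r_s: CovarianceEstimate,
    a: np.ndarray,
    loading: float | None = None,
    loading_delta: float = 0.01,
) -> BeamformerWeights:
    """Capon/MVDR weights with diagonal loading.

    ``w = (R_s + eps I)^{-1} a / (a^H (R_s + eps I)^{-1} a)`` so that the
    distortionless constraint ``w^H a = 1`` holds.  If ``loading`` is None
    it defaults to ``loading_delta * trace(R_s) / m`` (a fraction of the
    mean eigenvalue); pass ``loading=0`` to disable.
    """
    a = np.asarray(a, dtype=complex).ravel()
    m = r_s.size
    if a.size != m:
        raise ValueError(f"steering vector length {a.size} != covariance size {m}")
    if loading is None:
        loading = loading_delta * float(np.real(np.trace(r_s.matrix))) / m
    if loading < 0:
        raise ValueError("loading must be >= 0")
    loaded = r_s.matrix + loading * np.eye(m)
    try:
        ra = scipy.linalg.solve(loaded, a, assume_a="her")
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        raise np.linalg.LinAlgError(
            "loaded covariance is numerically singular; increase the diagonal loading"
        ) from exc
    denom = np.real(a.conj() @ ra)
    if not np.isfinite(denom) or denom <= 0:
        raise np.linalg.LinAlgError(
            "loaded covariance is numerically singular; increase the diagonal loading"
        )
    return BeamformerWeights(weights=ra / denom, loading_used=float(loading),
                             method="mvdr_sdss")


def das_weights(geometry: ArrayGeometry, angle: float) -> BeamformerWeights:
    """Delay-and-sum weights a(theta)/M on the full array."""
    a = steering_vector(geometry, angle)
    return BeamformerWeights(weights=a / geometry.num_elements, loading_used=0.0,
                             method="das")


def beamform_image(
    frame: SnapshotFrame,
    geometry: ArrayGeometry,
    angles: np.ndarray,
    method: str = "mvdr_sdss",
    q: int | None = None,
    loading_delta: float = 0.01,
    dynamic_range_db: float = 60.0,
) -> ReconImage:
    """Scan an angular grid and return the envelope (amplitude) image.

    ``das`` uses fixed weights a/M on the full array; ``mvdr_sdss``
    forms the FB-smoothed sub-array covariance (q sub-arrays) once per
    frame and steers Capon weights per direction.  Per-direction output
    power is ``w^H R w``; the stored pixels are its square root (the
    envelope).  Smoothing is applied per frame/direction set, not per
    pixel.
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size == 0:
        raise ValueError("angle grid must be nonempty")
    if method not in {"das", "mvdr_sdss"}:
        raise ValueError(f"unknown beamforming method {method!r}")

    r_full = sample_covariance(frame)
    power = np.empty(angles.shape, dtype=float)
    if method == "das":
        for i, th in enumerate(angles):
            w = das_weights(geometry, th).weights
            power[i] = max(float(np.real(w.conj() @ r_full.matrix @ w)), 0.0)
    else:
        q_eff = geometry.num_subarrays if q is None else int(q)
        r_s = fb_smooth(r_full, q_eff)
        sub = r_s.size
        for i, th in enumerate(angles):
            a_sub = steering_vector(geometry, th, length=sub)
            w = mvdr_weights(r_s, a_sub, loading_delta=loading_delta).weights
            power[i] = max(float(np.real(w.conj() @ r_s.matrix @ w)), 0.0)
    return ReconImage(pixels=np.sqrt(power), dynamic_range_db=dynamic_range_db,
                      method=method, angles=angles)


def _as_pixels(image) -> np.ndarray:
    px = image.pixels if isinstance(image, ReconImage) else np.asarray(image, float)
    if np.any(px < 0):
        raise ValueError("post-filters expect a nonnegative envelope image")
    return np.asarray(px, dtype=float)


def wiener_postfilter(image, noise_power: float) -> ReconImage:
    """Pixelwise Wiener gain S/(S + N) with S estimated as the pixel power.

    ``noise_power`` is in squared-envelope units; zero noise is the
    identity transform.
    """
    if noise_power < 0:
        raise ValueError("noise_power must be >= 0")
    px = _as_pixels(image)
    s = px**2
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(s + noise_power > 0, s / (s + noise_power), 0.0)
    if noise_power == 0:
        gain = np.ones_like(px)
    return ReconImage(pixels=px * gain, method="wiener_post",
                      angles=getattr(image, "angles", None))


def snr_postfilter(image, snr_map) -> ReconImage:
    """Pixelwise SNR gain snr/(1 + snr); snr_map is broadcast to the image."""
    px = _as_pixels(image)
    snr = np.broadcast_to(np.asarray(snr_map, dtype=float), px.shape)
    if np.any(snr < 0):
        raise ValueError("snr_map must be >= 0")
    gain = snr / (1.0 + snr)
    return ReconImage(pixels=px * gain, method="snr_post",
                      angles=getattr(image, "angles", None))


def mainlobe_width(angles: np.ndarray, envelope: np.ndarray,
                   drop_db: float = 3.0) -> float:
    """Width (radians) of the main lobe at ``drop_db`` below the peak.

    Walks outward from the global envelope peak to the first crossings of
    the -drop_db amplitude level and linearly interpolates the crossing
    angles.
    """
    angles = np.asarray(angles, float)
    env = np.asarray(envelope, float)
    if env.max() <= 0:
        raise ValueError("envelope has no peak")
    level = env.max() * 10.0 ** (-drop_db / 20.0)
    k = int(np.argmax(env))

    def cross(direction: int) -> float:
        i = k
        while 0 <= i + direction < env.size and env[i + direction] >= level:
            i += direction
        j = i + direction
        if j < 0 or j >= env.size:
            return angles[i]
        # linear interpolation between samples i (above) and j (below)
        frac = (env[i] - level) / (env[i] - env[j])
        return angles[i] + frac * (angles[j] - angles[i])

    return float(abs(cross(+1) - cross(-1)))
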