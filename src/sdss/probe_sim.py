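"""Synthetic linear-array echo simulation.

Implements the narrowband far-field array model used throughout the
package: an M-element uniform linear array observes K point sources, so
each snapshot is

    x(t) = A s(t) + n(t),        A = [a(theta_1), ..., a(theta_K)],

where ``a(theta)`` is the steering vector of the array, ``s(t)`` the
vector of complex source amplitudes and ``n(t)`` spatially white sensor
noise with covariance ``sigma^2 I``.  Signals and noise are circular
complex Gaussian.  The module also builds simple raster phantoms
(isolated points, anechoic cyst in speckle, pleural-line with comet-tail
streaks) that serve as ground truth for the image-quality metrics.

No pulse-echo propagation physics is simulated; see the methods note for
what this model does and does not emulate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ArrayGeometry",
    "SourceSet",
    "SnapshotFrame",
    "Phantom",
    "steering_vector",
    "simulate_snapshots",
    "make_phantom",
]


@dataclass(frozen=True)
class ArrayGeometry:
    """An M-element uniform linear array and its sub-array decomposition.

    Parameters
    ----------
    num_elements
        Number of physical elements M (>= 2).
    num_subarrays
        Number of overlapping sub-arrays q used by spatial smoothing,
        1 <= q <= M.  Sub-arrays shift by one element, so the sub-array
        length is ``M - q + 1``.
    element_pitch
        Element spacing in wavelengths.  Default 0.5 (half wavelength,
        no grating lobes).
    """

    num_elements: int
    num_subarrays: int = 1
    element_pitch: float = 0.5

    def __post_init__(self) -> None:
        if self.num_elements < 2:
            raise ValueError(f"num_elements must be >= 2, got {self.num_elements}")
        if not 1 <= self.num_subarrays <= self.num_elements:
            raise ValueError(
                f"num_subarrays must satisfy 1 <= q <= M={self.num_elements}, "
                f"got {self.num_subarrays}"
            )
        if self.element_pitch <= 0:
            raise ValueError("element_pitch must be positive")

    @property
    def subarray_length(self) -> int:
        """Length of each overlapping sub-array, l = M - q + 1."""
        return self.num_elements - self.num_subarrays + 1

    @property
    def element_positions(self) -> np.ndarray:
        """Element positions in wavelengths, uniformly spaced from 0."""
        return self.element_pitch * np.arange(self.num_elements, dtype=float)


@dataclass(frozen=True)
class SourceSet:
    """K far-field point sources: arrival angles (radians) and complex amplitudes."""

    angles: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        angles = np.atleast_1d(np.asarray(self.angles, dtype=float))
        amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=complex))
        if angles.shape != amplitudes.shape:
            raise ValueError("angles and amplitudes must have matching length")
        if angles.size and not np.all(np.abs(angles) < np.pi / 2):
            raise ValueError("all arrival angles must lie in (-pi/2, pi/2)")
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "amplitudes", amplitudes)

    @property
    def num_sources(self) -> int:
        return int(self.angles.size)


@dataclass
class SnapshotFrame:
    """Complex echo snapshots X of shape (M, T) plus the per-element noise variance."""

    data: np.ndarray
    noise_variance: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=complex)
        if data.ndim != 2:
            raise ValueError("snapshot data must be a 2-D (elements x time) array")
        if not np.all(np.isfinite(data)):
            raise ValueError("snapshot data must be finite")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")
        self.data = data

    @property
    def num_elements(self) -> int:
        return self.data.shape[0]

    @property
    def sample_count(self) -> int:
        return self.data.shape[1]

    def save(self, path: str | Path) -> None:
        """Serialize to an .npz container."""
        np.savez(path, data=self.data, noise_variance=self.noise_variance)

    @classmethod
    def load(cls, path: str | Path) -> "SnapshotFrame":
        with np.load(path) as npz:
            return cls(data=npz["data"], noise_variance=float(npz["noise_variance"]))


@dataclass
class Phantom:
    """Ground-truth reflectivity raster plus the discrete scatterers placed in it."""

    truth_image: np.ndarray
    scatterers: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        img = np.asarray(self.truth_image, dtype=float)
        if img.ndim != 2 or min(img.shape) < 8:
            raise ValueError("truth_image must be 2-D and at least 8x8")
        if np.any(img < 0):
            raise ValueError("reflectivity must be nonnegative")
        self.truth_image = img

    def to_png(self, path: str | Path) -> None:
        """Write the truth image as 16-bit PNG (peak mapped to full scale)."""
        import imageio.v3 as iio

        peak = self.truth_image.max()
        scale = 65535.0 / peak if peak > 0 else 0.0
        iio.imwrite(Path(path), (self.truth_image * scale).astype(np.uint16))

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.truth_image, delimiter=",")


def steering_vector(
    geometry: ArrayGeometry, angle: float, length: int | None = None
) -> np.ndarray:
    """Narrowband steering vector a(theta) for the leading ``length`` elements.

    Entries are ``exp(-j 2 pi d n sin(theta))`` for element index
    n = 0..length-1 with pitch d in wavelengths; the first entry is 1
    (phase reference at element 0).

    Raises
    ------
    ValueError
        If ``angle`` is outside (-pi/2, pi/2) or ``length`` not in [1, M].
    """
    if not -np.pi / 2 < angle < np.pi / 2:
        raise ValueError(f"angle must lie in (-pi/2, pi/2), got {angle}")
    m = geometry.num_elements if length is None else int(length)
    if not 1 <= m <= geometry.num_elements:
        raise ValueError(f"length must satisfy 1 <= length <= M, got {m}")
    n = np.arange(m)
    return np.exp(-2j * np.pi * geometry.element_pitch * n * np.sin(angle))


def _circular_gaussian(rng: np.random.Generator, shape, variance: float) -> np.ndarray:
    # circular complex Gaussian: real/imag parts each N(0, variance/2)
    scale = np.sqrt(variance / 2.0)
    return scale * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))


def simulate_snapshots(
    geometry: ArrayGeometry,
    sources: SourceSet,
    signal_power: float | np.ndarray = 1.0,
    noise_variance: float = 0.0,
    num_snapshots: int = 64,
    seed: int = 0,
    coherent: bool = False,
) -> SnapshotFrame:
    """Draw T snapshots of ``x(t) = A s(t) + n(t)``.

    ``signal_power`` is the per-source variance of s(t) (scalar or one
    value per source); the stored complex amplitude of each source
    multiplies its draw, so fully coherent echoes can be produced by
    passing ``coherent=True``, which reuses one Gaussian draw for all
    sources (they then differ only by their fixed complex amplitudes —
    the rank-1 covariance case spatial smoothing exists to repair).

    K = 0 sources with zero noise returns an all-zero frame.
    """
    if num_snapshots < 1:
        raise ValueError("num_snapshots must be >= 1")
    if noise_variance < 0:
        raise ValueError("noise_variance must be >= 0")
    power = np.broadcast_to(
        np.atleast_1d(np.asarray(signal_power, dtype=float)), (sources.num_sources,)
    )
    if np.any(power < 0):
        raise ValueError("signal_power must be >= 0")

    rng = np.random.default_rng(seed)
    m, t = geometry.num_elements, int(num_snapshots)
    data = np.zeros((m, t), dtype=complex)
    if sources.num_sources:
        a_mat = np.column_stack(
            [steering_vector(geometry, th) for th in sources.angles]
        )
        if coherent:
            base = _circular_gaussian(rng, (1, t), 1.0)
            s = np.sqrt(power)[:, None] * base
        else:
            s = np.vstack(
                [_circular_gaussian(rng, (t,), p) for p in power]
            )
        s = sources.amplitudes[:, None] * s
        data += a_mat @ s
    if noise_variance > 0:
        data += _circular_gaussian(rng, (m, t), noise_variance)
    return SnapshotFrame(data=data, noise_variance=float(noise_variance))


def _place_points(
    rng: np.random.Generator, shape: tuple[int, int], num_points: int
) -> list[tuple[int, int, float]]:
    # keep scatterers separated by at least 3 px so they stay isolated
    placed: list[tuple[int, int, float]] = []
    attempts = 0
    while len(placed) < num_points and attempts < 10_000:
        attempts += 1
        r = int(rng.integers(1, shape[0] - 1))
        c = int(rng.integers(1, shape[1] - 1))
        if all(abs(r - pr) + abs(c - pc) > 3 for pr, pc, _ in placed):
            placed.append((r, c, 1.0))
    if len(placed) < num_points:
        raise ValueError("could not place the requested number of isolated points")
    return placed


def make_phantom(
    kind: str,
    size: tuple[int, int] = (64, 64),
    seed: int = 0,
    num_points: int = 2,
    cyst_radius: float | None = None,
) -> Phantom:
    """Build a deterministic test phantom.

    kinds
        ``points``        -- ``num_points`` isolated unit scatterers on black.
        ``cyst``          -- anechoic disc (zero) inside exponential speckle.
        ``pleura_blines`` -- bright horizontal pleural line plus vertical
        comet-tail streaks with depth-decaying brightness, the lung
        B-line artifact pattern.
    """
    rows, cols = int(size[0]), int(size[1])
    if rows < 8 or cols < 8:
        raise ValueError("phantom size must be at least 8x8")
    rng = np.random.default_rng(seed)
    img = np.zeros((rows, cols), dtype=float)

    if kind == "points":
        scatterers = _place_points(rng, (rows, cols), num_points)
        for r, c, amp in scatterers:
            img[r, c] = amp
        return Phantom(truth_image=img, scatterers=scatterers)

    if kind == "cyst":
        radius = cyst_radius if cyst_radius is not None else min(rows, cols) / 5.0
        img = rng.exponential(scale=1.0, size=(rows, cols))
        rr, cc = np.ogrid[:rows, :cols]
        inside = (rr - rows / 2.0) ** 2 + (cc - cols / 2.0) ** 2 <= radius**2
        img[inside] = 0.0
        return Phantom(truth_image=img, scatterers=[])

    if kind == "pleura_blines":
        pleura_row = rows // 4
        img[pleura_row, :] = 1.0
        n_lines = max(2, cols // 16)
        cols_chosen = rng.choice(np.arange(2, cols - 2), size=n_lines, replace=False)
        depth = np.arange(pleura_row + 1, rows)
        decay = np.exp(-(depth - pleura_row) / (0.5 * rows))
        for c in cols_chosen:
            img[pleura_row + 1 :, c] = np.maximum(img[pleura_row + 1 :, c], 0.8 * decay)
        return Phantom(truth_image=img, scatterers=[])

    raise ValueError(f"unknown phantom kind {kind!r}")
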