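"""Simulation of tomographic volumes from atomic models.

The simulator reproduces single-axis tomography on noise-free synthetic
data: an atomic model is rasterized into a cubic density grid (isotropic
Gaussian splats), optionally tumbled by a uniform random rotation,
projected into a tilt series about a fixed axis, and reconstructed by
(ramp-filtered) back projection. Restricting the tilt range below +/-90
degrees produces the classic missing-wedge elongation along the beam axis.

Grid convention: axis 0 = x, axis 1 = y (the tilt axis), axis 2 = z (the
beam axis). A tilt image is indexed (x, y).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .structures import AtomCloud

DEFAULT_VOXEL_SIZE = 1.0  # A/pixel; makes pixel cutoffs numerically equal to A cutoffs
DEFAULT_SIGMA = 1.0  # A; std dev of the Gaussian deposited per atom
BOX_PAD = 10.0  # A of padding on each side of the centered structure


@dataclass
class DensityVolume:
    """Cubic grid of nonnegative intensities with a physical voxel size."""

    grid: np.ndarray
    voxel_size: float = DEFAULT_VOXEL_SIZE
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3 or len(set(self.grid.shape)) != 1:
            raise ValueError("volume grid must be cubic (n, n, n)")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("intensities must be finite")
        if self.grid.size and self.grid.min() < 0:
            raise ValueError("intensities must be nonnegative")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]


@dataclass
class TiltScheme:
    """Inclusive range of tilt angles in degrees with a fixed increment."""

    angle_min: float
    angle_max: float
    increment: float

    def __post_init__(self) -> None:
        if not self.angle_min < self.angle_max:
            raise ValueError("angle_min must be below angle_max")
        if not self.increment > 0:
            raise ValueError("increment must be positive")

    def angles(self) -> np.ndarray:
        n = int(round((self.angle_max - self.angle_min) / self.increment)) + 1
        return self.angle_min + self.increment * np.arange(n)


#: Full single-axis coverage: -90..+90 deg in 0.5 deg steps (361 images).
FULL_SCHEME = TiltScheme(-90.0, 90.0, 0.5)
#: Typical cryo-ET acquisition: -60..+60 deg in 0.5 deg steps (241 images),
#: leaving a 60 deg missing wedge unsampled.
MISSING_WEDGE_SCHEME = TiltScheme(-60.0, 60.0, 0.5)

REGIMES = ("full", "tumbled", "tumbled_missing_wedge")


def default_box_size(atoms: AtomCloud, voxel_size: float = DEFAULT_VOXEL_SIZE,
                     pad: float = BOX_PAD) -> int:
    """Smallest multiple of 16 that holds the centered structure plus padding."""
    centered = atoms.positions - atoms.centroid
    extent = 2.0 * np.abs(centered).max() if len(centered) else 0.0
    need = (extent + 2.0 * pad) / voxel_size
    return int(np.ceil(need / 16.0)) * 16


def rasterize(
    atoms: AtomCloud,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
    box_size: int | None = None,
    sigma: float = DEFAULT_SIGMA,
) -> DensityVolume:
    """Deposit one isotropic Gaussian per atom onto a cubic grid.

    The structure is centered in the box. Each atom contributes a separable
    3-D Gaussian of standard deviation ``sigma`` (in angstroms), normalized
    so its integrated mass equals the atom's weight; the grid total is
    therefore ~ the sum of weights, up to tail truncation at 4 sigma.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if box_size is None:
        box_size = default_box_size(atoms, voxel_size)
    n = int(box_size)
    centered = atoms.positions - atoms.centroid
    vox = centered / voxel_size + (n - 1) / 2.0
    if vox.min() < 0 or vox.max() > n - 1:
        raise ValueError("box too small: an atom falls outside the grid after centering")

    sig_px = sigma / voxel_size
    halfw = max(1, int(np.ceil(4.0 * sig_px)))
    grid = np.zeros((n, n, n), dtype=np.float64)
    norm1d = voxel_size / (sigma * np.sqrt(2.0 * np.pi))
    for (cx, cy, cz), w in zip(vox, atoms.weights):
        ix0, ix1 = max(0, int(cx) - halfw), min(n, int(cx) + halfw + 2)
        iy0, iy1 = max(0, int(cy) - halfw), min(n, int(cy) + halfw + 2)
        iz0, iz1 = max(0, int(cz) - halfw), min(n, int(cz) + halfw + 2)
        gx = norm1d * np.exp(-0.5 * ((np.arange(ix0, ix1) - cx) / sig_px) ** 2)
        gy = norm1d * np.exp(-0.5 * ((np.arange(iy0, iy1) - cy) / sig_px) ** 2)
        gz = norm1d * np.exp(-0.5 * ((np.arange(iz0, iz1) - cz) / sig_px) ** 2)
        # each 1-D factor already carries a voxel_size, so this is mass per voxel
        grid[ix0:ix1, iy0:iy1, iz0:iz1] += w * (
            gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
        )
    return DensityVolume(grid=grid.astype(np.float32), voxel_size=voxel_size)


def random_rotation(seed: int) -> np.ndarray:
    """Uniform random rotation matrix (Haar measure on SO(3)), seeded."""
    rot = Rotation.random(rng=np.random.default_rng(seed))
    return rot.as_matrix()


def apply_rotation(atoms: AtomCloud, R: np.ndarray) -> AtomCloud:
    """Rotate the cloud about its centroid (pairwise distances preserved)."""
    R = np.asarray(R, dtype=float)
    c = atoms.centroid
    return AtomCloud(positions=(atoms.positions - c) @ R.T + c,
                     weights=atoms.weights.copy())


@dataclass
class TiltSeries:
    """Stack of 2-D projections, one per tilt angle (degrees, increasing)."""

    images: np.ndarray  # (n_angles, n, n), image indexed (x, y)
    angles: np.ndarray
    tilt_axis: str = "y"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n_angles, n, n) stack")
        if len(self.images) != len(self.angles):
            raise ValueError("one image per angle required")
        if len(self.angles) > 1 and not np.all(np.diff(self.angles) > 0):
            raise ValueError("angles must be strictly increasing")

    def __len__(self) -> int:
        return len(self.images)


def _tilt_matrix(theta_deg: float) -> np.ndarray:
    """Rotation about the y (tilt) axis mixing grid axes x and z."""
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


def _rotate_volume(grid: np.ndarray, theta_deg: float) -> np.ndarray:
    """Trilinear rotation of the grid about the tilt (y) axis, centered."""
    n = grid.shape[0]
    center = (n - 1) / 2.0
    m = _tilt_matrix(theta_deg)  # output coords -> input coords
    offset = center - m @ np.full(3, center)
    return ndimage.affine_transform(grid, m, offset=offset, order=1,
                                    mode="constant", cval=0.0, prefilter=False)


def project_tilt_series(volume: DensityVolume, scheme: TiltScheme) -> TiltSeries:
    """Single-axis projection: rotate about y by each angle, sum along z."""
    grid = np.asarray(volume.grid, dtype=np.float32)
    angles = scheme.angles()
    images = np.empty((len(angles), grid.shape[0], grid.shape[1]), dtype=np.float32)
    for k, theta in enumerate(angles):
        images[k] = _rotate_volume(grid, theta).sum(axis=2)
    return TiltSeries(images=images, angles=angles)


def project_atoms_tilt_series(
    atoms: AtomCloud,
    scheme: TiltScheme,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
    box_size: int | None = None,
    sigma: float = DEFAULT_SIGMA,
) -> TiltSeries:
    """Render tilt images directly from the atomic model.

    The projection along the beam of a field of isotropic 3-D Gaussians is
    exactly a sum of 2-D Gaussians at the rotated atom positions, so each
    tilt image can be rendered analytically instead of rotating the
    rasterized grid; the result matches :func:`project_tilt_series` of the
    rasterized volume up to its trilinear interpolation error, and is much
    faster for sparse atomic models.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if box_size is None:
        box_size = default_box_size(atoms, voxel_size)
    n = int(box_size)
    centered = atoms.positions - atoms.centroid
    vox = centered / voxel_size + (n - 1) / 2.0
    center = (n - 1) / 2.0
    sig_px = sigma / voxel_size
    halfw = max(1, int(np.ceil(4.0 * sig_px)))
    offs = np.arange(-halfw, halfw + 2)
    norm1d = voxel_size / (sigma * np.sqrt(2.0 * np.pi))
    w = atoms.weights

    cy = vox[:, 1]
    iy = np.floor(cy).astype(int)[:, None] + offs[None, :]
    gy = norm1d * np.exp(-0.5 * ((iy - cy[:, None]) / sig_px) ** 2)
    valid_y = (iy >= 0) & (iy < n)
    iy_c = np.clip(iy, 0, n - 1)
    gy = np.where(valid_y, gy, 0.0)

    px, pz = vox[:, 0] - center, vox[:, 2] - center
    angles = scheme.angles()
    images = np.zeros((len(angles), n, n), dtype=np.float32)
    for k, theta in enumerate(angles):
        t = np.deg2rad(theta)
        # active counter-rotation of atom x-coords, matching _rotate_volume
        cx = center + np.cos(t) * px + np.sin(t) * pz
        ix = np.floor(cx).astype(int)[:, None] + offs[None, :]
        gx = norm1d * np.exp(-0.5 * ((ix - cx[:, None]) / sig_px) ** 2)
        valid_x = (ix >= 0) & (ix < n)
        ix_c = np.clip(ix, 0, n - 1)
        gx = np.where(valid_x, gx, 0.0)
        vals = w[:, None, None] * gx[:, :, None] * gy[:, None, :]
        img = np.zeros((n, n), dtype=np.float64)
        np.add.at(img, (ix_c[:, :, None], iy_c[:, None, :]), vals)
        images[k] = img
    return TiltSeries(images=images, angles=angles)


def back_project(series: TiltSeries, filter: str = "ramp") -> DensityVolume:
    """Reconstruct a volume from a tilt series by (filtered) back projection.

    With ``filter="ramp"`` each image is convolved along x with the ramp
    kernel |omega| before smearing, the standard weighting that undoes the
    1/|omega| oversampling of low frequencies; negative intensities in the
    result are clamped to zero. ``filter="none"`` gives plain back
    projection (blurry but strictly nonnegative).
    """
    if filter not in ("ramp", "none"):
        raise ValueError(f"unknown filter {filter!r}")
    if len(series) == 0:
        raise ValueError("empty tilt series")
    n = series.images.shape[1]
    center = (n - 1) / 2.0
    recon = np.zeros((n, n, n), dtype=np.float32)
    dtheta = np.deg2rad(np.median(np.diff(series.angles))) if len(series) > 1 else 1.0
    ramp = np.abs(np.fft.rfftfreq(n))[:, None]

    # smearing a tilt image back through the volume reduces to a 1-D linear
    # interpolation along the image x-axis at t = c + cos(th) (x-c) + sin(th) (z-c)
    x = np.arange(n, dtype=np.float64) - center
    xx, zz = np.meshgrid(x, x, indexing="ij")  # (x, z)
    for img, theta in zip(series.images, series.angles):
        img64 = img.astype(np.float64)
        if filter == "ramp":
            img64 = np.fft.irfft(np.fft.rfft(img64, axis=0) * ramp, n=n, axis=0)
        t = np.deg2rad(theta)
        pos = center + np.cos(t) * xx + np.sin(t) * zz
        i0 = np.floor(pos).astype(np.int64)
        frac = (pos - i0).astype(np.float32)
        v0 = (i0 >= 0) & (i0 <= n - 1)
        v1 = (i0 + 1 >= 0) & (i0 + 1 <= n - 1)
        i0c = np.clip(i0, 0, n - 1)
        i1c = np.clip(i0 + 1, 0, n - 1)
        f32 = img64.astype(np.float32)
        lo = np.where(v0[:, None, :], f32[i0c].transpose(0, 2, 1), 0.0)
        hi = np.where(v1[:, None, :], f32[i1c].transpose(0, 2, 1), 0.0)
        recon += lo * (1.0 - frac)[:, None, :] + hi * frac[:, None, :]
    recon *= dtheta
    np.maximum(recon, 0.0, out=recon)
    return DensityVolume(grid=recon, voxel_size=1.0)


def simulate_tomogram(
    atoms: AtomCloud,
    regime: str = "full",
    seed: int = 0,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
    sigma: float = DEFAULT_SIGMA,
    box_size: int | None = None,
    filter: str = "ramp",
) -> DensityVolume:
    """Rasterize, optionally tumble, project and reconstruct in one call.

    Regimes: ``full`` = no rotation, -90..90 deg tilt range; ``tumbled`` =
    uniform random rotation (from ``seed``) then the full range;
    ``tumbled_missing_wedge`` = random rotation then the truncated
    -60..60 deg range.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    if regime != "full":
        atoms = apply_rotation(atoms, random_rotation(seed))
    scheme = MISSING_WEDGE_SCHEME if regime == "tumbled_missing_wedge" else FULL_SCHEME
    series = project_atoms_tilt_series(atoms, scheme, voxel_size=voxel_size,
                                       box_size=box_size, sigma=sigma)
    recon = back_project(series, filter=filter)
    recon.voxel_size = voxel_size
    return recon
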