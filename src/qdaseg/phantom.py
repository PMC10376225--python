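"""Seeded synthetic brain-slice phantom with ground-truth labels.

A concentric-ellipsoid head model — skull shell enclosing CSF, grey matter
and a white-matter core — with one or more star-convex tumor lumps placed
inside the white matter, per-tissue Gaussian texture, a smooth
multiplicative bias field emulating intensity inhomogeneity, and additive
Gaussian noise.  Every pipeline stage and the end-to-end system are
testable against the label volume without any external dataset.

Label indices: 0 background, 1 CSF, 2 grey, 3 white, 4 skull, 5 tumor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mri_io import Volume

__all__ = ["PhantomSpec", "TISSUES", "generate", "tumor_truth"]

TISSUES = ("background", "csf", "grey", "white", "skull", "tumor")
TUMOR_LABEL = 5

#: normalized-radius shells of the head model (fractions of the head
#: semi-axes): white core, grey ring, CSF ring, skull shell
_RHO_WHITE = 0.62
_RHO_GREY = 0.80
_RHO_CSF = 0.92
_RHO_SKULL = 1.00


@dataclass
class PhantomSpec:
    """Geometry, intensity and noise parameters of the phantom.

    Tissue means are on an 8-bit scale; the tumor is hyperintense
    (contrast-enhanced appearance) so the brightest-cluster rule applies,
    but all means are configurable so the outlier rule can be exercised
    too.  The separability invariant — tumor mean outside +/- 2 sd of
    every other tissue mean — is validated at construction and underpins
    the recovery tests.
    """

    shape: tuple[int, int, int] = (240, 240, 155)
    tissue_means: tuple[float, ...] = (0.0, 40.0, 100.0, 150.0, 230.0, 210.0)
    tissue_sds: tuple[float, ...] = (2.0, 5.0, 6.0, 6.0, 7.0, 8.0)
    n_tumors: int = 1
    tumor_radius_range: tuple[float, float] = (12.0, 18.0)
    tumor_irregularity: float = 0.3
    bias_amplitude: float = 0.1
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if len(self.tissue_means) != 6 or len(self.tissue_sds) != 6:
            raise ValueError("six tissue means and sds required")
        if len(set(self.tissue_means)) != 6:
            raise ValueError("tissue means must be distinct")
        if self.n_tumors < 0:
            raise ValueError("n_tumors must be >= 0")
        lo, hi = self.tumor_radius_range
        if not (0 < lo <= hi):
            raise ValueError("tumor radius range must satisfy 0 < lo <= hi")
        tumor = self.tissue_means[TUMOR_LABEL]
        for i, (m, s) in enumerate(zip(self.tissue_means, self.tissue_sds)):
            if i == TUMOR_LABEL:
                continue
            if abs(tumor - m) <= 2.0 * s:
                raise ValueError(
                    f"tumor mean {tumor} within 2 sd of {TISSUES[i]} "
                    f"({m} +/- {2 * s}): separability violated"
                )


class PlacementError(RuntimeError):
    """Tumors could not be placed without overlap after bounded retries."""


def _head_geometry(shape: tuple[int, int, int]):
    nx, ny, nz = shape
    center = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2])
    semi = np.array([0.42 * nx, 0.42 * ny, 0.46 * nz])
    return center, semi


def _rho(shape: tuple[int, int, int]) -> np.ndarray:
    center, semi = _head_geometry(shape)
    gx, gy, gz = np.ogrid[: shape[0], : shape[1], : shape[2]]
    acc = (
        ((gx - center[0]) / semi[0]) ** 2
        + ((gy - center[1]) / semi[1]) ** 2
        + ((gz - center[2]) / semi[2]) ** 2
    )
    return np.sqrt(acc)


def _star_radius_field(
    offsets: tuple[np.ndarray, np.ndarray, np.ndarray],
    rng: np.random.Generator,
    irregularity: float,
) -> np.ndarray:
    """Smooth random modulation in [1-irr, 1+irr] over directions.

    Low-order polynomials of the unit direction (a truncated spherical
    harmonic basis) keep the lump star-convex and free of
    self-intersection.
    """
    dx, dy, dz = offsets
    dist = np.sqrt(dx**2 + dy**2 + dz**2)
    dist = np.where(dist == 0, 1.0, dist)
    ux, uy, uz = dx / dist, dy / dist, dz / dist
    basis = [ux, uy, uz, ux * uy, uy * uz, ux * uz, ux**2 - uy**2]
    coef = rng.normal(size=len(basis))
    bound = np.sum(np.abs(coef))
    if bound > 0:
        coef /= bound  # |P| <= 1 since each basis function is bounded by 1
    perturb = sum(c * b for c, b in zip(coef, basis))
    return 1.0 + irregularity * perturb


def _place_tumors(
    spec: PhantomSpec, labels: np.ndarray, rng: np.random.Generator
) -> None:
    center, semi = _head_geometry(spec.shape)
    z_scale = semi[2] / semi[0]  # tumors share the head's z anisotropy
    placed: list[tuple[np.ndarray, float]] = []
    max_tries = 200
    for _ in range(spec.n_tumors):
        for attempt in range(max_tries):
            R = rng.uniform(*spec.tumor_radius_range)
            r_norm = R * (1 + spec.tumor_irregularity) / semi[0]
            if r_norm >= _RHO_WHITE:
                continue
            # rejection-sample a center deep enough inside white matter
            u = rng.uniform(-1.0, 1.0, size=3)
            rho_c = np.linalg.norm(u)
            if rho_c > _RHO_WHITE - r_norm - 0.02:
                continue
            c = center + u * semi
            margin = 2.0
            ok = True
            for (c2, R2) in placed:
                d = (c - c2) / np.array([1.0, 1.0, z_scale])
                if np.linalg.norm(d) <= (R + R2) * (1 + spec.tumor_irregularity) + margin:
                    ok = False
                    break
            if not ok:
                continue
            _carve_tumor(labels, c, R, z_scale, spec, rng)
            placed.append((c, R))
            break
        else:
            raise PlacementError(
                f"could not place {spec.n_tumors} non-overlapping tumors "
                f"after {max_tries} retries"
            )


def _carve_tumor(
    labels: np.ndarray,
    c: np.ndarray,
    R: float,
    z_scale: float,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> None:
    r_max = R * (1 + spec.tumor_irregularity) + 1
    lo = np.maximum(np.floor(c - r_max * np.array([1, 1, z_scale])).astype(int), 0)
    hi = np.minimum(
        np.ceil(c + r_max * np.array([1, 1, z_scale])).astype(int) + 1,
        np.array(labels.shape),
    )
    gx, gy, gz = np.meshgrid(
        *(np.arange(lo[i], hi[i]) for i in range(3)), indexing="ij"
    )
    dx = gx - c[0]
    dy = gy - c[1]
    dz = (gz - c[2]) / max(z_scale, 1e-6)  # isotropic in normalized space
    mod = _star_radius_field((dx, dy, dz), rng, spec.tumor_irregularity)
    inside = np.sqrt(dx**2 + dy**2 + dz**2) <= R * mod
    region = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    region[inside & (region == 3)] = TUMOR_LABEL


def _bias_field(
    shape: tuple[int, int, int], rng: np.random.Generator
) -> np.ndarray:
    """Separable low-frequency cosine field in [-1, 1]."""
    axes = []
    for n in shape:
        phase = rng.uniform(0, 2 * np.pi)
        axes.append(np.cos(np.pi * np.arange(n) / n + phase))
    bx, by, bz = axes
    return bx[:, None, None] * by[None, :, None] * bz[None, None, :]


def generate(spec: PhantomSpec | None = None) -> tuple[Volume, Volume]:
    """Build the phantom; returns (intensity volume, label volume).

    Fully deterministic given ``spec.seed``.  With zero tissue sds, zero
    bias amplitude and zero noise every voxel equals its tissue mean
    exactly.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    rho = _rho(spec.shape)
    labels = np.zeros(spec.shape, dtype=np.int64)
    labels[rho <= _RHO_SKULL] = 4
    labels[rho <= _RHO_CSF] = 1
    labels[rho <= _RHO_GREY] = 2
    labels[rho <= _RHO_WHITE] = 3
    if spec.n_tumors:
        _place_tumors(spec, labels, rng)

    means = np.asarray(spec.tissue_means)[labels]
    sds = np.asarray(spec.tissue_sds)[labels]
    data = means + sds * rng.standard_normal(spec.shape)
    if spec.bias_amplitude:
        data *= 1.0 + spec.bias_amplitude * _bias_field(spec.shape, rng)
    if spec.noise_sd:
        data += spec.noise_sd * rng.standard_normal(spec.shape)
    vol = Volume(data=data, spacing=(1.0, 1.0, 1.0))
    lab = Volume(data=labels.astype(np.float64), spacing=(1.0, 1.0, 1.0))
    return vol, lab


def tumor_truth(labels: Volume | np.ndarray) -> np.ndarray:
    """Boolean mask of tumor-labeled voxels."""
    data = labels.data if isinstance(labels, Volume) else np.asarray(labels)
    return data == TUMOR_LABEL
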