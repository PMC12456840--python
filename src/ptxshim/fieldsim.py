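"""Synthetic multi-channel transmit-field (B1+) data generator.

Emulates the geometry of a single-row loop-coil transmit array around a
head-like elliptical phantom: each channel's field is computed from a
quasi-static circular current loop (exact Biot–Savart field of a loop,
evaluated with complete elliptic integrals) and given a smooth phase ramp
proportional to the distance from the coil, mimicking the wave-propagation
phase at ultrahigh field that creates the constructive/destructive
interference RF shimming has to fix.  The loop rotated to azimuth θ also
contributes a geometric phase e^{iθ} to its transmit field, which is what
makes the circularly-polarized (quadrature) drive — channel phases stepping
by −45° for 8 coils — the natural baseline.

The generator produces 2-D slices (shimming here is slice-wise): a stack of
n-channel complex field maps, a mass-density surrogate and a binary
region-of-interest mask per slice, with per-slice variation through the
axial offset of the slice plane, per-volume variation through phantom
jitter, and rotation augmentation.  Fields are normalized per slice so the
quadrature-mode in-mask mean magnitude is 1.0, which makes the
percent-of-target-flip-angle error metric comparable across slices.

It also injects smooth multiplicative "voids" (local field dropouts) into
shimmed magnitude maps, the synthetic surrogate for the artifact cases used
to train the non-uniformity detector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, rotate as _ndrotate
from scipy.special import ellipe, ellipk

logger = logging.getLogger(__name__)

__all__ = [
    "CoilArraySpec",
    "PhantomSpec",
    "ChannelFieldSlice",
    "RegionMask",
    "FieldVolume",
    "VoidSpec",
    "GeneratorConfig",
    "loop_field",
    "simulate_channel_fields",
    "build_mask",
    "augment_rotations",
    "inject_nonuniformity",
    "simulate_dataset",
    "make_dataset",
]


class InvalidSpecError(ValueError):
    """Raised for geometrically impossible coil or phantom specifications."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoilArraySpec:
    """Transmit array geometry.

    ``element_angles`` are the azimuthal coil positions in degrees (default
    k·(360/n): 45° increments for 8 coils).  ``quadrature_phases`` is the
    drive-phase convention of the circularly-polarized mode, −k·(360/n)
    degrees by default; it is used for baseline combination and per-slice
    normalization, not burned into the stored fields.  ``radius`` (coil
    center distance from the phantom axis) and ``loop_radius`` (effective
    loop element radius) are in voxel units.
    """

    n_channels: int = 8
    radius: float = 58.0
    loop_radius: float = 16.0
    element_angles: tuple[float, ...] | None = None
    quadrature_phases: tuple[float, ...] | None = None
    wavelength: float = 55.0  # in-tissue RF wavelength surrogate, voxels

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise InvalidSpecError("n_channels must be >= 1")
        if self.radius < 0 or self.loop_radius <= 0:
            raise InvalidSpecError("coil radius must be >= 0 and loop_radius > 0")
        if self.wavelength <= 0:
            raise InvalidSpecError("wavelength must be positive")
        if self.element_angles is None:
            object.__setattr__(
                self,
                "element_angles",
                tuple(360.0 * k / self.n_channels for k in range(self.n_channels)),
            )
        if self.quadrature_phases is None:
            object.__setattr__(
                self,
                "quadrature_phases",
                tuple(-360.0 * k / self.n_channels for k in range(self.n_channels)),
            )
        if len(self.element_angles) != self.n_channels:
            raise InvalidSpecError("element_angles must have n_channels entries")
        if len(self.quadrature_phases) != self.n_channels:
            raise InvalidSpecError("quadrature_phases must have n_channels entries")

    @classmethod
    def for_grid(cls, grid_shape: tuple[int, int], n_channels: int = 8) -> "CoilArraySpec":
        """Array geometry scaled proportionally to the grid extent."""
        g = float(min(grid_shape))
        return cls(
            n_channels=n_channels,
            radius=0.58 * g,
            loop_radius=0.16 * g,
            wavelength=0.55 * g,
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Elliptical head-like phantom on a 2-D grid.

    ``semi_axes`` are the in-plane ellipse semi-axes in voxels;
    ``axial_semi_axis`` controls how the cross-section shrinks with the
    axial slice offset (ellipsoid-like).  ``noise_level`` adds smooth
    multiplicative texture to the interior mass-density surrogate.
    """

    grid_shape: tuple[int, int] = (101, 101)
    semi_axes: tuple[float, float] = (40.0, 32.0)
    axial_semi_axis: float = 45.0
    density_inside: float = 1.0
    density_outside: float = 0.0
    noise_level: float = 0.05
    center_offset: tuple[float, float] = (0.0, 0.0)
    tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 3:
            raise InvalidSpecError("grid_shape must be at least 3x3")
        if min(self.semi_axes) <= 0 or self.axial_semi_axis <= 0:
            raise InvalidSpecError("phantom semi-axes must be positive")
        if max(self.semi_axes) > max(self.grid_shape):
            raise InvalidSpecError("phantom does not fit in the grid")
        if self.density_inside <= self.density_outside:
            raise InvalidSpecError("density_inside must exceed density_outside")
        if self.noise_level < 0:
            raise InvalidSpecError("noise_level must be non-negative")

    @classmethod
    def for_grid(cls, grid_shape: tuple[int, int], **kw) -> "PhantomSpec":
        g = float(min(grid_shape))
        kw.setdefault("semi_axes", (0.40 * g, 0.32 * g))
        kw.setdefault("axial_semi_axis", 0.45 * g)
        return cls(grid_shape=grid_shape, **kw)


@dataclass(frozen=True)
class ChannelFieldSlice:
    """Complex per-channel transmit field on a 2-D grid; the rows of the
    shimming system matrix A."""

    values: np.ndarray  # complex, shape (n_channels, rows, cols)

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(self.values, dtype=np.complex128)
        if v.ndim != 3:
            raise ValueError("values must have shape (channels, rows, cols)")
        if not (np.all(np.isfinite(v.real)) and np.all(np.isfinite(v.imag))):
            raise ValueError("field values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def channel_count(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1:]


@dataclass(frozen=True)
class RegionMask:
    """Boolean region-of-interest grid (the w of the MLS objective)."""

    inside: np.ndarray  # bool, shape (rows, cols)

    def __post_init__(self) -> None:
        ins = np.asarray(self.inside, dtype=bool)
        if ins.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "inside", ins)

    @property
    def is_empty(self) -> bool:
        return not bool(self.inside.any())

    @property
    def n_voxels(self) -> int:
        return int(self.inside.sum())


@dataclass
class FieldVolume:
    """Ordered stack of field slices with matching masks and densities."""

    slices: list[ChannelFieldSlice]
    masks: list[RegionMask]
    densities: list[np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.slices) == len(self.masks) == len(self.densities)):
            raise ValueError("slices, masks and densities must have equal length")
        for s, m in zip(self.slices, self.masks):
            if s.grid_shape != m.inside.shape:
                raise ValueError("slice and mask shapes differ")

    @property
    def n_slices(self) -> int:
        return len(self.slices)


@dataclass(frozen=True)
class VoidSpec:
    """A smooth multiplicative field void: Gaussian suppression of the
    magnitude toward zero, depth 1 meaning complete dropout at the center."""

    radius: float
    depth: float
    center: tuple[int, int] | None = None  # None: drawn uniformly inside the mask
    n_voids: int = 1

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidSpecError("void radius must be positive")
        if not 0.0 <= self.depth <= 1.0:
            raise InvalidSpecError("void depth must be in [0, 1]")
        if self.n_voids < 1:
            raise InvalidSpecError("n_voids must be >= 1")


# ---------------------------------------------------------------------------
# loop-coil physics
# ---------------------------------------------------------------------------

def loop_field(rho, z, a: float):
    """Magnetostatic field of a circular current loop of radius ``a``.

    Returns ``(B_rho, B_z)`` in loop-centered cylindrical coordinates for
    unit current (mu0*I = 1), via the standard complete-elliptic-integral
    closed form.  On the axis (rho = 0) this reduces to
    ``B_z = a^2 / (2 (a^2 + z^2)^{3/2})``.
    """
    rho = np.asarray(rho, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    rho, z = np.broadcast_arrays(rho, z)
    denom_far = (a + rho) ** 2 + z**2
    denom_near = (a - rho) ** 2 + z**2
    # soften only the singular ring rho=a, z=0; elsewhere exact
    denom_near = np.maximum(denom_near, 1e-9)
    m = np.clip(4.0 * a * rho / denom_far, 0.0, 1.0 - 1e-12)
    K = ellipk(m)
    E = ellipe(m)
    pref = 1.0 / (2.0 * np.pi * np.sqrt(denom_far))
    Bz = pref * (K + E * (a**2 - rho**2 - z**2) / denom_near)
    with np.errstate(invalid="ignore", divide="ignore"):
        Brho = pref * (z / np.maximum(rho, 1e-12)) * (
            -K + E * (a**2 + rho**2 + z**2) / denom_near
        )
    Brho = np.where(rho < 1e-12, 0.0, Brho)
    return Brho, Bz


def _grid_coords(grid_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = grid_shape
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    yy, xx = np.mgrid[0:rows, 0:cols]
    return yy - cy, xx - cx  # (dy, dx) from grid center


def _single_coil_field(
    coils: CoilArraySpec, k: int, grid_shape: tuple[int, int], slice_dz: float
) -> np.ndarray:
    """Complex field of coil ``k`` on a slice offset ``slice_dz`` voxels
    axially from the coil plane."""
    theta = np.deg2rad(coils.element_angles[k])
    cy_rel, cx_rel = _grid_coords(grid_shape)
    # coil center in grid coordinates; loop axis points at the phantom axis
    px = coils.radius * np.cos(theta)
    py = coils.radius * np.sin(theta)
    ux, uy = -np.cos(theta), -np.sin(theta)  # axis direction
    tx, ty = -np.sin(theta), np.cos(theta)  # in-plane transverse direction
    dx = cx_rel - px
    dy = cy_rel - py
    axial = dx * ux + dy * uy
    trans = dx * tx + dy * ty
    rho = np.hypot(trans, slice_dz)
    Brho, Bz = loop_field(rho, axial, coils.loop_radius)
    mag = np.hypot(Brho, Bz)
    dist = np.sqrt(dx**2 + dy**2 + slice_dz**2)
    phase = theta - 2.0 * np.pi * dist / coils.wavelength
    return mag * np.exp(1j * phase)


def _phantom_density(
    phantom: PhantomSpec, slice_scale: float, rng: np.random.Generator
) -> np.ndarray:
    dy, dx = _grid_coords(phantom.grid_shape)
    oy, ox = phantom.center_offset
    dy = dy - oy
    dx = dx - ox
    t = np.deg2rad(phantom.tilt_deg)
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    a, b = phantom.semi_axes
    a, b = a * slice_scale, b * slice_scale
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    density = np.where(inside, phantom.density_inside, phantom.density_outside)
    if phantom.noise_level > 0:
        texture = gaussian_filter(rng.standard_normal(phantom.grid_shape), sigma=4.0)
        scale = np.std(texture)
        if scale > 0:
            texture = texture / scale
        density = np.where(
            inside,
            density * np.clip(1.0 + phantom.noise_level * texture, 0.6, 1.4),
            density,
        )
    return density


def build_mask(density: np.ndarray, threshold: float) -> RegionMask:
    """Binary region-of-interest mask from a mass-density surrogate:
    ``inside = density > threshold`` (surrounding air, density 0, excluded)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    mask = RegionMask(np.asarray(density) > threshold)
    if mask.is_empty:
        logger.warning("mask is empty (no voxel above threshold %.3g)", threshold)
    return mask


def quadrature_combined(fields: np.ndarray, quadrature_phases: Sequence[float]) -> np.ndarray:
    """Combine channel fields with the unit-magnitude quadrature drive."""
    drive = np.exp(1j * np.deg2rad(np.asarray(quadrature_phases)))
    return np.tensordot(drive, fields, axes=1)


def simulate_channel_fields(
    coils: CoilArraySpec,
    phantom: PhantomSpec,
    n_slices: int,
    seed: int,
    slice_spacing: float = 2.0,
    normalize: bool = True,
) -> FieldVolume:
    """Simulate one volume of n-channel complex field slices.

    Slices are axial offsets of the loop plane spaced ``slice_spacing``
    voxels apart, symmetric about the coil plane; the phantom cross-section
    shrinks ellipsoidally with the offset.  With ``normalize`` the fields of
    each slice are scaled so the quadrature-mode in-mask mean magnitude is
    exactly 1.0.  Deterministic given (specs, seed).
    """
    if n_slices < 1:
        raise InvalidSpecError("n_slices must be >= 1")
    if coils.radius <= 0:
        raise InvalidSpecError("coil radius must be positive for a volume simulation")
    rng = np.random.default_rng(seed)
    threshold = 0.5 * phantom.density_inside
    slices: list[ChannelFieldSlice] = []
    masks: list[RegionMask] = []
    densities: list[np.ndarray] = []
    meta_slices = []
    for j in range(n_slices):
        dz = slice_spacing * (j - (n_slices - 1) / 2.0)
        scale = np.sqrt(max(0.15, 1.0 - (dz / phantom.axial_semi_axis) ** 2))
        density = _phantom_density(phantom, scale, rng)
        mask = build_mask(density, threshold)
        if mask.is_empty:
            raise InvalidSpecError(
                f"slice {j}: degenerate phantom produced an empty mask"
            )
        vals = np.stack(
            [
                _single_coil_field(coils, k, phantom.grid_shape, dz)
                for k in range(coils.n_channels)
            ]
        )
        if normalize:
            cp = quadrature_combined(vals, coils.quadrature_phases)
            level = float(np.mean(np.abs(cp)[mask.inside]))
            if level <= 0:
                raise InvalidSpecError(f"slice {j}: zero quadrature field in mask")
            vals = vals / level
        slices.append(ChannelFieldSlice(vals))
        masks.append(mask)
        densities.append(density)
        meta_slices.append({"axial_offset": dz, "source_slice": j, "rotation_deg": 0.0})
    return FieldVolume(
        slices,
        masks,
        densities,
        metadata={
            "seed": int(seed),
            "coils": coils,
            "phantom": phantom,
            "slice_spacing": float(slice_spacing),
            "slices": meta_slices,
        },
    )


# ---------------------------------------------------------------------------
# augmentation and artifact injection
# ---------------------------------------------------------------------------

def _rotate_real(arr: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    return _ndrotate(
        arr, angle_deg, axes=(-2, -1), reshape=False, order=order,
        mode="constant", cval=0.0, prefilter=False,
    )


def rotate_slice(
    fields: ChannelFieldSlice, mask: RegionMask, density: np.ndarray, angle_deg: float
) -> tuple[ChannelFieldSlice, RegionMask, np.ndarray]:
    """Jointly rotate fields, mask and density about the grid center.

    Complex fields are rotated by bilinear interpolation of the real and
    imaginary parts separately; the mask with nearest-neighbor and
    re-binarized.
    """
    if angle_deg % 360.0 == 0.0:
        return fields, mask, density.copy()
    re = _rotate_real(fields.values.real, angle_deg, order=1)
    im = _rotate_real(fields.values.imag, angle_deg, order=1)
    rmask = _rotate_real(mask.inside.astype(np.float64), angle_deg, order=0) > 0.5
    rdensity = _rotate_real(density, angle_deg, order=1)
    return ChannelFieldSlice(re + 1j * im), RegionMask(rmask), rdensity


def augment_rotations(volume: FieldVolume, n_rotations: int) -> FieldVolume:
    """Expand a volume with rotated copies of each slice.

    Each source slice appears ``n_rotations`` times, rotated by
    k·(360/n_rotations) degrees, k = 0..n_rotations−1; fields, mask and
    density rotate jointly and the metadata records the angle and the
    source slice (the unit later used for leakage-free dataset splits).
    """
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    if n_rotations == 1:
        return volume
    slices, masks, densities, meta_slices = [], [], [], []
    src_meta = volume.metadata.get("slices", [{} for _ in volume.slices])
    for s, (f, m, d) in enumerate(zip(volume.slices, volume.masks, volume.densities)):
        for k in range(n_rotations):
            ang = 360.0 * k / n_rotations
            rf, rm, rd = rotate_slice(f, m, d, ang)
            if rm.is_empty:  # pragma: no cover - rotation preserves the phantom
                logger.warning("rotation %g of slice %d emptied the mask; skipped", ang, s)
                continue
            slices.append(rf)
            masks.append(rm)
            densities.append(rd)
            entry = dict(src_meta[s]) if s < len(src_meta) else {}
            entry.update({"source_slice": s, "rotation_deg": ang})
            meta_slices.append(entry)
    meta = dict(volume.metadata)
    meta["slices"] = meta_slices
    meta["n_rotations"] = int(n_rotations)
    return FieldVolume(slices, masks, densities, metadata=meta)


def inject_nonuniformity(
    magnitude_map: np.ndarray,
    mask: RegionMask,
    void_spec: VoidSpec,
    seed: int = 0,
) -> np.ndarray:
    """Inject smooth multiplicative voids into a shimmed magnitude map.

    Each void multiplies the map by ``1 - depth * exp(-r^2 / (2 sigma^2))``
    with ``sigma = radius / 2`` about its center, so a depth-1 void drives
    the center voxel's magnitude exactly to zero.  Void centers are the
    given one (required to lie inside the mask) or drawn uniformly from the
    in-mask voxels.
    """
    out = np.array(magnitude_map, dtype=np.float64, copy=True)
    if void_spec.depth == 0.0:
        return out
    rng = np.random.default_rng(seed)
    inside_idx = np.argwhere(mask.inside)
    if inside_idx.size == 0:
        raise ValueError("cannot inject a void into an empty mask")
    yy, xx = np.mgrid[0 : out.shape[0], 0 : out.shape[1]]
    sigma = void_spec.radius / 2.0
    for _ in range(void_spec.n_voids):
        if void_spec.center is not None:
            ci, cj = void_spec.center
            if not mask.inside[ci, cj]:
                raise ValueError("void center must lie inside the mask")
        else:
            ci, cj = inside_idx[rng.integers(len(inside_idx))]
        r2 = (yy - ci) ** 2 + (xx - cj) ** 2
        out *= 1.0 - void_spec.depth * np.exp(-r2 / (2.0 * sigma**2))
    return out


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for a full synthetic dataset.

    Per-volume diversity comes from jitter of the phantom ellipse (semi-axis
    scale, center offset, tilt); per-slice diversity from the axial offset;
    ``n_rotations`` rotation-augments every slice.  All geometric defaults
    scale with the grid so the 101×101 reference layout and the faster
    64×64 option produce comparable interference structure.
    """

    n_volumes: int = 4
    n_slices: int = 8
    n_rotations: int = 4
    grid_shape: tuple[int, int] = (101, 101)
    n_channels: int = 8
    slice_spacing: float | None = None
    noise_level: float = 0.05
    axis_jitter: float = 0.15
    center_jitter: float = 0.05  # fraction of grid extent
    tilt_jitter_deg: float = 30.0

    def __post_init__(self) -> None:
        if min(self.n_volumes, self.n_slices, self.n_rotations) < 1:
            raise InvalidSpecError("n_volumes, n_slices, n_rotations must be >= 1")


def simulate_dataset(config: GeneratorConfig, seed: int) -> list[FieldVolume]:
    """Generate ``n_volumes`` jittered, rotation-augmented field volumes.

    Fully reproducible from (config, seed): per-volume seeds are spawned
    from a single seed sequence.
    """
    root = np.random.SeedSequence(seed)
    vol_seeds = root.generate_state(2 * config.n_volumes) % (2**31)
    g = float(min(config.grid_shape))
    spacing = (
        config.slice_spacing
        if config.slice_spacing is not None
        else 0.02 * g
    )
    coils = CoilArraySpec.for_grid(config.grid_shape, config.n_channels)
    volumes = []
    for v in range(config.n_volumes):
        jrng = np.random.default_rng(vol_seeds[2 * v])
        sa = 0.40 * g * jrng.uniform(1 - config.axis_jitter, 1 + config.axis_jitter)
        sb = 0.32 * g * jrng.uniform(1 - config.axis_jitter, 1 + config.axis_jitter)
        off = jrng.uniform(-config.center_jitter * g, config.center_jitter * g, 2)
        tilt = jrng.uniform(-config.tilt_jitter_deg, config.tilt_jitter_deg)
        phantom = PhantomSpec(
            grid_shape=config.grid_shape,
            semi_axes=(sa, sb),
            axial_semi_axis=0.45 * g,
            noise_level=config.noise_level,
            center_offset=(float(off[0]), float(off[1])),
            tilt_deg=float(tilt),
        )
        vol = simulate_channel_fields(
            coils, phantom, config.n_slices, seed=int(vol_seeds[2 * v + 1]),
            slice_spacing=spacing,
        )
        vol = augment_rotations(vol, config.n_rotations)
        vol.metadata["volume_index"] = v
        volumes.append(vol)
    return volumes


def make_dataset(config: GeneratorConfig, seed: int, path=None) -> list[FieldVolume]:
    """Generate a dataset and, if ``path`` is given, write it to the HDF5
    container (see :mod:`ptxshim.io`)."""
    volumes = simulate_dataset(config, seed)
    if path is not None:
        from . import io as _io

        _io.write_dataset(volumes, path, config=config, seed=seed)
    return volumes
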