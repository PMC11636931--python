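"""Synthetic head phantoms and image-intensity-to-acoustic-property mapping.

CT-like volumes carry Hounsfield units (HU) clamped to ``[0, 2400]``: 0 is
water (and everything softer), 2400 is dense cortical bone.  A UTE-style
pseudo-CT of the same head is emulated by resampling the CT volume to a
coarser grid and round-tripping it through the log-linear UTE/CT regression
``log(UTE) = 7.3170e-4 * HU + 5.0211`` with spatially correlated model error
added in the log domain.

Acoustic property volumes follow the standard porosity mapping: with
porosity ``phi = 1 - HU/2400``, speed of sound and density interpolate
linearly between water and cortical-bone endpoints in ``(1 - phi)``, and the
attenuation coefficient rises with porosity inside bone (scattering by
trabecular pores) while pure-water voxels keep the water value.

The phantom generator produces an ellipsoidal two-layer skull shell (a rind
with seeded trabecular HU texture) immersed in water.  It is a geometric
stand-in for an anatomical skull: it reproduces the thickness, HU range and
spatial-correlation scales that drive phase aberration, nothing more.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "UTE_FIT_SLOPE",
    "UTE_FIT_INTERCEPT",
    "HeadVolume",
    "AcousticHeadModel",
    "PhantomSpec",
    "PropertyMap",
    "clamp_hu",
    "fit_line_forward",
    "fit_line_inverse",
    "ute_to_pseudo_ct",
    "hu_to_acoustic",
    "generate_synthetic_head",
    "degrade_to_ute_model",
]

HU_MIN = 0.0
HU_MAX = 2400.0

#: log-linear regression between UTE signal intensity and CT Hounsfield units
UTE_FIT_SLOPE = 7.3170e-4
UTE_FIT_INTERCEPT = 5.0211

_MODALITIES = ("CT", "UTE", "pseudoCT")


@dataclass
class HeadVolume:
    """A scalar voxel volume with grid metadata.

    Parameters
    ----------
    values : ndarray
        Voxel values; HU for ``CT``/``pseudoCT``, signal intensity for ``UTE``.
    spacing : sequence of 3 floats
        Voxel size in millimetres per axis (strictly positive).
    origin : sequence of 3 floats
        World position of voxel ``(0, 0, 0)`` centre, in metres.
    modality : {"CT", "UTE", "pseudoCT"}
    """

    values: np.ndarray
    spacing: tuple
    origin: tuple
    modality: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        self.spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (3,)))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in np.broadcast_to(self.origin, (3,)))
        if self.modality not in _MODALITIES:
            raise ValueError(f"modality must be one of {_MODALITIES}, got {self.modality!r}")

    @property
    def shape(self):
        return self.values.shape

    def axis_coords_m(self) -> list[np.ndarray]:
        """World coordinates (metres) of voxel centres along each axis."""
        return [
            self.origin[i] + np.arange(self.shape[i]) * self.spacing[i] / 1000.0
            for i in range(3)
        ]

    def extent_m(self) -> list[tuple[float, float]]:
        ax = self.axis_coords_m()
        return [(float(a[0]), float(a[-1])) for a in ax]

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        affine[:3, 3] = np.asarray(self.origin) * 1000.0  # NIfTI convention: mm
        img = nib.Nifti1Image(self.values, affine)
        img.header["descrip"] = self.modality.encode()
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, modality: str | None = None) -> "HeadVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(np.asarray(img.affine[:3, 3], dtype=float) / 1000.0)
        if modality is None:
            descrip = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode()
            modality = descrip if descrip in _MODALITIES else "CT"
        return cls(np.asarray(img.dataobj, dtype=float), spacing, origin, modality)


@dataclass(frozen=True)
class PropertyMap:
    """Endpoint constants of the porosity-based HU -> acoustic property mapping.

    Speed and density are linear in bone fraction ``1 - phi`` between the
    water and cortical-bone endpoints; attenuation inside bone follows
    ``alpha_bone_min + (alpha_bone_max - alpha_bone_min) * phi**attenuation_exponent``
    so that zero-porosity (cortical) bone takes the minimum bone value.
    The bone attenuation law applies only above ``bone_threshold_hu``:
    voxels below it (water, soft tissue, background noise) keep the water
    attenuation, since an absorption law extrapolated to near-zero HU would
    assign strong trabecular absorption to plain water.
    Units: m/s, kg/m^3, Np/m at the operating frequency.
    """

    c_water: float = 1500.0
    rho_water: float = 1000.0
    alpha_water: float = 0.03
    c_bone: float = 3100.0
    rho_bone: float = 1900.0
    alpha_bone_min: float = 10.0
    alpha_bone_max: float = 40.0
    attenuation_exponent: float = 0.5
    bone_threshold_hu: float = 150.0

    def __post_init__(self):
        if self.c_bone < self.c_water or self.rho_bone < self.rho_water:
            raise ValueError("bone endpoint below water endpoint")
        if self.alpha_bone_min < 0 or self.alpha_bone_max < self.alpha_bone_min:
            raise ValueError("attenuation endpoints must satisfy 0 <= min <= max")


@dataclass
class AcousticHeadModel:
    """Speed / density / attenuation voxel volumes on one common grid."""

    speed: np.ndarray
    density: np.ndarray
    attenuation: np.ndarray
    spacing: tuple
    origin: tuple

    def __post_init__(self):
        self.speed = np.asarray(self.speed, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        self.attenuation = np.asarray(self.attenuation, dtype=float)
        if not (self.speed.shape == self.density.shape == self.attenuation.shape):
            raise ValueError("speed, density and attenuation must share one grid")
        self.spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (3,)))
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        self.origin = tuple(float(o) for o in np.broadcast_to(self.origin, (3,)))
        if np.any(self.attenuation < 0):
            raise ValueError("attenuation must be nonnegative")

    @property
    def shape(self):
        return self.speed.shape

    def axis_coords_m(self) -> list[np.ndarray]:
        return [
            self.origin[i] + np.arange(self.shape[i]) * self.spacing[i] / 1000.0
            for i in range(3)
        ]

    @classmethod
    def uniform_water(cls, shape, spacing, origin=(0.0, 0.0, 0.0),
                      props: PropertyMap = PropertyMap()) -> "AcousticHeadModel":
        shape = tuple(int(s) for s in shape)
        return cls(
            np.full(shape, props.c_water),
            np.full(shape, props.rho_water),
            np.full(shape, props.alpha_water),
            spacing,
            origin,
        )


@dataclass
class PhantomSpec:
    """Parameters of the ellipsoidal skull-shell phantom.

    Lengths in millimetres; ``center_m`` in metres (world frame).
    """

    radii_mm: tuple = (80.0, 95.0, 75.0)
    thickness_mm: float = 7.0
    thickness_variation: float = 0.6  # fractional, peak amplitude
    thickness_correlation_mm: float = 30.0  # cm-scale thickness undulation
    texture_amplitude_hu: float = 800.0
    texture_correlation_mm: float = 20.0
    base_hu: float = 1700.0
    center_m: tuple = (0.11, 0.11, 0.09)
    seed: int = 0

    def __post_init__(self):
        self.center_m = tuple(float(c) for c in np.broadcast_to(self.center_m, (3,)))
        self.radii_mm = tuple(float(r) for r in np.broadcast_to(self.radii_mm, (3,)))
        if self.thickness_mm <= 0:
            raise ValueError("thickness must be positive")
        if min(self.radii_mm) <= self.thickness_mm:
            raise ValueError("radii must exceed shell thickness")
        if not 0 <= self.thickness_variation < 1:
            raise ValueError("thickness_variation must be in [0, 1)")


# --------------------------------------------------------------------------
# HU clamping and the UTE/CT fit line
# --------------------------------------------------------------------------

def clamp_hu(volume: HeadVolume) -> HeadVolume:
    """Clamp a CT/pseudo-CT volume into ``[HU_MIN, HU_MAX]``.

    Idempotent; values already in range pass through unchanged.  Non-finite
    voxels are an error (they indicate a broken upstream pipeline, not data).
    """
    if volume.modality not in ("CT", "pseudoCT"):
        raise ValueError(f"clamp_hu expects CT or pseudoCT, got {volume.modality}")
    bad = ~np.isfinite(volume.values)
    if np.any(bad):
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(f"non-finite HU at voxel index {idx}")
    return HeadVolume(
        np.clip(volume.values, HU_MIN, HU_MAX),
        volume.spacing,
        volume.origin,
        volume.modality,
    )


def fit_line_forward(hu: np.ndarray) -> np.ndarray:
    """HU -> UTE signal intensity through the log-linear regression."""
    return np.exp(UTE_FIT_SLOPE * np.asarray(hu, dtype=float) + UTE_FIT_INTERCEPT)


def fit_line_inverse(ute: np.ndarray) -> np.ndarray:
    """UTE signal intensity -> HU (no clamping); requires positive intensity."""
    return (np.log(np.asarray(ute, dtype=float)) - UTE_FIT_INTERCEPT) / UTE_FIT_SLOPE


def ute_to_pseudo_ct(volume: HeadVolume) -> HeadVolume:
    """Map a UTE intensity volume to a clamped pseudo-CT volume.

    Nonpositive intensities (background air / pure noise voxels) map to
    ``HU_MIN`` with a warning rather than erroring.
    """
    if volume.modality != "UTE":
        raise ValueError(f"ute_to_pseudo_ct expects a UTE volume, got {volume.modality}")
    vals = np.asarray(volume.values, dtype=float)
    nonpos = vals <= 0
    if np.any(nonpos):
        warnings.warn(
            f"{int(nonpos.sum())} nonpositive UTE voxels mapped to HU_MIN",
            RuntimeWarning,
            stacklevel=2,
        )
    hu = np.full(vals.shape, HU_MIN)
    with np.errstate(invalid="ignore"):
        hu[~nonpos] = fit_line_inverse(vals[~nonpos])
    out = HeadVolume(hu, volume.spacing, volume.origin, "pseudoCT")
    return clamp_hu(out)


# --------------------------------------------------------------------------
# HU -> acoustic properties
# --------------------------------------------------------------------------

def hu_to_acoustic(volume: HeadVolume, props: PropertyMap = PropertyMap()) -> AcousticHeadModel:
    """Map a clamped CT/pseudo-CT volume to speed/density/attenuation volumes.

    Porosity ``phi = 1 - HU/HU_MAX``.  Speed and density are linear in
    ``1 - phi``; attenuation follows the bone law above the bone-mask
    threshold and keeps the water value below it.
    """
    if volume.modality not in ("CT", "pseudoCT"):
        raise ValueError("hu_to_acoustic expects CT or pseudoCT")
    hu = volume.values
    if np.any(hu < HU_MIN) or np.any(hu > HU_MAX):
        raise ValueError("input must be clamped to [0, 2400]; run clamp_hu first")
    phi = 1.0 - hu / HU_MAX
    bone_frac = 1.0 - phi
    speed = props.c_water + (props.c_bone - props.c_water) * bone_frac
    density = props.rho_water + (props.rho_bone - props.rho_water) * bone_frac
    alpha = np.where(
        hu >= props.bone_threshold_hu,
        props.alpha_bone_min
        + (props.alpha_bone_max - props.alpha_bone_min) * phi**props.attenuation_exponent,
        props.alpha_water,
    )
    return AcousticHeadModel(speed, density, alpha, volume.spacing, volume.origin)


# --------------------------------------------------------------------------
# Phantom generation and UTE-model degradation
# --------------------------------------------------------------------------

def _correlated_field(rng: np.random.Generator, shape, sigma_vox: float) -> np.ndarray:
    """Unit-std Gaussian random field with Gaussian correlation kernel."""
    g = rng.standard_normal(shape)
    if sigma_vox > 0:
        g = ndimage.gaussian_filter(g, sigma=sigma_vox, mode="reflect")
    s = g.std()
    if s > 0:
        g = g / s
    return g


def generate_synthetic_head(
    spec: PhantomSpec,
    shape=(110, 110, 96),
    spacing_mm: float = 2.0,
    origin_m=(0.0, 0.0, 0.0),
) -> HeadVolume:
    """Generate a CT-like ellipsoidal skull-shell phantom.

    Water (0 HU) outside and inside the shell; shell voxels carry
    ``base_hu`` plus seeded trabecular texture, clipped to ``(0, HU_MAX]``.
    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in shape)
    spacing = tuple(float(s) for s in np.broadcast_to(spacing_mm, (3,)))
    origin = tuple(float(o) for o in np.broadcast_to(origin_m, (3,)))

    radii_m = np.asarray(spec.radii_mm) / 1000.0
    centre = np.asarray(spec.center_m)
    lo = [origin[i] for i in range(3)]
    hi = [origin[i] + (shape[i] - 1) * spacing[i] / 1000.0 for i in range(3)]
    for i in range(3):
        if centre[i] - radii_m[i] < lo[i] or centre[i] + radii_m[i] > hi[i]:
            raise ValueError(
                f"grid too small to contain shell along axis {i}: "
                f"needs [{centre[i] - radii_m[i]:.4f}, {centre[i] + radii_m[i]:.4f}] m, "
                f"grid spans [{lo[i]:.4f}, {hi[i]:.4f}] m"
            )

    # normalized ellipsoidal radius, built by broadcasting 1-D axes
    axes = [origin[i] + np.arange(shape[i]) * spacing[i] / 1000.0 for i in range(3)]
    u2 = (
        ((axes[0] - centre[0]) / radii_m[0])[:, None, None] ** 2
        + ((axes[1] - centre[1]) / radii_m[1])[None, :, None] ** 2
        + ((axes[2] - centre[2]) / radii_m[2])[None, None, :] ** 2
    )
    u = np.sqrt(u2)

    # thickness field: mean thickness modulated by a smooth seeded field
    r_ref = float(np.cbrt(np.prod(radii_m)))  # geometric-mean radius (m)
    corr_vox = spec.texture_correlation_mm / float(np.mean(spacing))
    if spec.thickness_variation > 0:
        g1 = _correlated_field(rng, shape, spec.thickness_correlation_mm / float(np.mean(spacing)))
        peak = np.max(np.abs(g1))
        if peak > 0:
            g1 = g1 / peak
        t_field = spec.thickness_mm / 1000.0 * (1.0 + spec.thickness_variation * g1)
    else:
        rng.standard_normal(shape)  # keep the stream layout stable across specs
        t_field = np.full(shape, spec.thickness_mm / 1000.0)
    u_inner = 1.0 - t_field / r_ref
    shell = (u <= 1.0) & (u >= u_inner)

    hu = np.zeros(shape)
    if spec.texture_amplitude_hu > 0:
        g2 = _correlated_field(rng, shape, corr_vox)
        shell_hu = spec.base_hu + spec.texture_amplitude_hu * g2
    else:
        rng.standard_normal(shape)
        shell_hu = np.full(shape, spec.base_hu)
    hu[shell] = np.clip(shell_hu[shell], 1.0, HU_MAX)
    return HeadVolume(hu, spacing, origin, "CT")


def degrade_to_ute_model(
    ct: HeadVolume,
    blur_mm: float = 0.0,
    model_error_std: float = 0.0,
    seed: int = 0,
    coarse_factor: float = 2.0,
    error_correlation_mm: float = 25.0,
    error_fine_fraction: float = 0.4,
) -> HeadVolume:
    """Emulate the UTE-derived pseudo-CT of a CT head volume.

    The CT volume is resampled to a coarser UTE-like grid (linear
    interpolation), optionally blurred, pushed through the UTE/CT fit line,
    perturbed by Gaussian model error of the given std in the log-intensity
    domain, mapped back to HU, clamped, and upsampled to the original grid
    with nearest-neighbour interpolation.

    The model error is two-scale: a smooth anatomical-bias field with
    ``error_correlation_mm`` correlation carrying ``1 - error_fine_fraction``
    of the variance, plus voxel-scale regression scatter carrying the rest
    (the UTE/CT fit line is a weak regression, so per-voxel scatter is a
    real feature of pseudo-CT synthesis).

    ``blur_mm == 0``, ``model_error_std == 0`` and ``coarse_factor == 1``
    reproduce the input exactly (up to clamping).
    """
    if blur_mm < 0 or model_error_std < 0:
        raise ValueError("blur_mm and model_error_std must be nonnegative")
    if coarse_factor < 1:
        raise ValueError("coarse_factor must be >= 1")
    if ct.modality != "CT":
        raise ValueError(f"degrade_to_ute_model expects a CT volume, got {ct.modality}")
    rng = np.random.default_rng(seed)

    vals = ct.values
    if coarse_factor > 1:
        vals = ndimage.zoom(vals, 1.0 / coarse_factor, order=1, mode="nearest")
    coarse_spacing = np.asarray(ct.spacing) * coarse_factor
    if blur_mm > 0:
        vals = ndimage.gaussian_filter(vals, sigma=blur_mm / coarse_spacing, mode="nearest")

    if not 0 <= error_fine_fraction <= 1:
        raise ValueError("error_fine_fraction must lie in [0, 1]")
    log_ute = UTE_FIT_SLOPE * vals + UTE_FIT_INTERCEPT
    if model_error_std > 0:
        sigma_vox = error_correlation_mm / float(np.mean(coarse_spacing))
        err = np.sqrt(1.0 - error_fine_fraction) * _correlated_field(rng, vals.shape, sigma_vox)
        if error_fine_fraction > 0:
            err = err + np.sqrt(error_fine_fraction) * rng.standard_normal(vals.shape)
        log_ute = log_ute + model_error_std * err
    hu = np.clip((log_ute - UTE_FIT_INTERCEPT) / UTE_FIT_SLOPE, HU_MIN, HU_MAX)

    if coarse_factor > 1:
        factors = [t / c for t, c in zip(ct.shape, hu.shape)]
        hu = ndimage.zoom(hu, factors, order=0, mode="nearest")
        # zoom may land one voxel short/long; pad with edge values then crop
        pad = [(0, max(0, t - s)) for t, s in zip(ct.shape, hu.shape)]
        hu = np.pad(hu, pad, mode="edge")[tuple(slice(0, t) for t in ct.shape)]
    return HeadVolume(hu, ct.spacing, ct.origin, "pseudoCT")
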