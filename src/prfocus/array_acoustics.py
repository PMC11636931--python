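"""Hemispherical phased array, transfer-matrix forward model, time reversal.

The single-frequency response between array element *n* and control point
*l* is computed with a straight-ray phase-screen model:

    h_ln = (A / r_ln) * exp(-int alpha ds) * exp(-i 2 pi f int ds / c(x))

with both line integrals taken along the straight element-to-target ray
through the voxelized acoustic model.  In uniform water this reduces exactly
to the free-space Green's-function amplitude/phase.  The model captures the
skull-induced amplitude and phase aberration that the calibration algorithm
consumes; it deliberately ignores refraction, multiple scattering and shear
conversion (see the methods note).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np

from .skull_model import AcousticHeadModel

__all__ = [
    "ArrayGeometry",
    "SourceSignal",
    "TransferMatrix",
    "FieldMap",
    "make_hemisphere_array",
    "compute_tm",
    "time_reversal",
    "field_map",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class ArrayGeometry:
    """Element positions (metres) on a sphere of given radius about a centre."""

    element_positions: np.ndarray
    radius: float
    centre: tuple

    def __post_init__(self):
        self.element_positions = np.atleast_2d(np.asarray(self.element_positions, dtype=float))
        if self.element_positions.shape[1] != 3:
            raise ValueError("element_positions must be (N, 3)")
        if self.element_positions.shape[0] < 1:
            raise ValueError("need at least one element")
        self.centre = tuple(float(c) for c in np.broadcast_to(self.centre, (3,)))
        d = np.linalg.norm(self.element_positions - np.asarray(self.centre), axis=1)
        if not np.allclose(d, self.radius, atol=1e-9):
            raise ValueError("all elements must lie at distance `radius` from the centre")

    @property
    def n_elements(self) -> int:
        return self.element_positions.shape[0]

    def to_json(self, path) -> None:
        payload = {
            "element_positions": self.element_positions.tolist(),
            "radius": self.radius,
            "centre": list(self.centre),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ArrayGeometry":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(np.asarray(payload["element_positions"]), payload["radius"], tuple(payload["centre"]))


@dataclass(frozen=True)
class SourceSignal:
    """Operating point of the array: single-frequency continuous-wave drive.

    ``burst_length`` is carried for provenance only; the forward model is
    frequency-domain.
    """

    frequency: float = 250e3  # Hz
    burst_length: float = 40e-6  # s
    amplitude: float = 1.0  # nominal per-element source strength (relative)

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")


@dataclass
class TransferMatrix:
    """Complex M x N single-frequency responses (rows: targets, cols: elements)."""

    values: np.ndarray
    targets: np.ndarray
    provenance: str  # true_model | degraded_model | estimate
    frequency: float = 250e3

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=complex))
        self.targets = np.atleast_2d(np.asarray(self.targets, dtype=float))
        if not np.all(np.isfinite(self.values.view(float))):
            raise ValueError("transfer matrix must be finite")
        if self.targets.shape != (self.values.shape[0], 3):
            raise ValueError("targets must be (M, 3) matching the row count")

    @property
    def n_targets(self) -> int:
        return self.values.shape[0]

    @property
    def n_elements(self) -> int:
        return self.values.shape[1]

    def row(self, l: int) -> np.ndarray:
        return self.values[l]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=self.values)
            fh.create_dataset("targets", data=self.targets)
            fh.attrs["provenance"] = self.provenance
            fh.attrs["frequency"] = self.frequency

    @classmethod
    def from_hdf5(cls, path) -> "TransferMatrix":
        with h5py.File(path, "r") as fh:
            return cls(
                fh["values"][()],
                fh["targets"][()],
                str(fh.attrs["provenance"]),
                float(fh.attrs["frequency"]),
            )


@dataclass
class FieldMap:
    """Nonnegative pressure-magnitude map on a voxel grid (relative units)."""

    pressure: np.ndarray
    spacing_mm: tuple
    origin_m: tuple

    def __post_init__(self):
        self.pressure = np.asarray(self.pressure, dtype=float)
        if np.any(self.pressure < 0) or not np.all(np.isfinite(self.pressure)):
            raise ValueError("pressure map must be finite and nonnegative")
        self.spacing_mm = tuple(float(s) for s in np.broadcast_to(self.spacing_mm, (3,)))
        self.origin_m = tuple(float(o) for o in np.broadcast_to(self.origin_m, (3,)))

    def argmax_index(self) -> tuple:
        # np.argmax breaks ties by lowest linear index
        return tuple(int(i) for i in np.unravel_index(np.argmax(self.pressure), self.pressure.shape))

    def argmax_position_m(self) -> np.ndarray:
        idx = np.asarray(self.argmax_index(), dtype=float)
        return np.asarray(self.origin_m) + idx * np.asarray(self.spacing_mm) / 1000.0


# --------------------------------------------------------------------------
# Array construction
# --------------------------------------------------------------------------

def make_hemisphere_array(
    n: int = 128,
    radius: float = 0.1,
    centre=(0.11, 0.11, 0.08),
    seed: int | None = None,
) -> ArrayGeometry:
    """Quasi-uniform element placement on the upper half-sphere.

    Uses a Fibonacci spiral lattice over the hemisphere; ``seed`` only
    rotates the lattice about the polar axis (placement stays quasi-uniform
    and deterministic per seed).  ``n == 1`` degenerates to a single element
    at the apex.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    centre = np.broadcast_to(np.asarray(centre, dtype=float), (3,))
    offset = 0.0
    if seed is not None:
        offset = float(np.random.default_rng(seed).uniform(0, 2 * np.pi))
    if n == 1:
        pos = centre + radius * np.array([[0.0, 0.0, 1.0]])
        return ArrayGeometry(pos, radius, tuple(centre))
    k = np.arange(n)
    z = (k + 0.5) / n  # quasi-uniform in area over the upper hemisphere
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    theta = _GOLDEN_ANGLE * k + offset
    unit = np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)
    return ArrayGeometry(centre + radius * unit, radius, tuple(centre))


def aperture_permutation(array: ArrayGeometry, layout: tuple) -> tuple:
    """Element ordering that makes a rows x cols image spatially coherent.

    Elements are sorted into ``rows`` elevation bands and by azimuth within
    each band, so neighbouring image pixels are neighbouring aperture
    positions; denoisers acting on transfer-matrix rows then see the smooth
    aperture structure of skull aberration.
    """
    rows, cols = layout
    if rows * cols != array.n_elements:
        raise ValueError(f"layout {layout} does not tile {array.n_elements} elements")
    rel = array.element_positions - np.asarray(array.centre)
    by_z = np.argsort(rel[:, 2], kind="stable")
    perm = np.empty(array.n_elements, dtype=int)
    for r in range(rows):
        band = by_z[r * cols:(r + 1) * cols]
        azimuth = np.arctan2(rel[band, 1], rel[band, 0])
        perm[r * cols:(r + 1) * cols] = band[np.argsort(azimuth, kind="stable")]
    return tuple(int(i) for i in perm)


# --------------------------------------------------------------------------
# Ray integration
# --------------------------------------------------------------------------

def _ray_integrals(model: AcousticHeadModel, start: np.ndarray, ends: np.ndarray,
                   step_mm: float, label: str):
    """Midpoint-rule line integrals of slowness and attenuation.

    ``start`` is a single point (metres); ``ends`` is (M, 3).  Returns
    (distances, travel_times, attenuation_integrals), each length M.
    """
    ends = np.atleast_2d(ends)
    d = np.linalg.norm(ends - start, axis=1)
    if np.any(d <= 0):
        m = int(np.argmin(d))
        raise ValueError(f"{label}: target {m} coincides with the element")
    n_steps = max(2, int(np.ceil(d.max() * 1000.0 / step_mm)))
    ts = (np.arange(n_steps) + 0.5) / n_steps
    # points: (M, S, 3)
    pts = start + ts[None, :, None] * (ends[:, None, :] - start)
    spacing_m = np.asarray(model.spacing) / 1000.0
    idx = np.rint((pts - np.asarray(model.origin)) / spacing_m).astype(np.intp)
    shape = np.asarray(model.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        bad = np.argwhere(np.any((idx < 0) | (idx >= shape), axis=(1, 2)))[0, 0]
        raise ValueError(f"{label}: ray to target {int(bad)} exits the model grid")
    ii, jj, kk = idx[..., 0], idx[..., 1], idx[..., 2]
    ds = d / n_steps  # (M,)
    slowness = 1.0 / model.speed[ii, jj, kk]
    alpha = model.attenuation[ii, jj, kk]
    travel = slowness.sum(axis=1) * ds
    att = alpha.sum(axis=1) * ds
    return d, travel, att


def compute_tm(
    model: AcousticHeadModel,
    array: ArrayGeometry,
    targets,
    signal: SourceSignal = SourceSignal(),
    step_mm: float | None = None,
    provenance: str = "true_model",
) -> TransferMatrix:
    """Compute the complex transfer matrix through a head model.

    ``targets`` is (M, 3) in metres and must lie inside the model grid.  The
    default ray sampling step is half the smallest voxel spacing.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if step_mm is None:
        step_mm = 0.5 * min(model.spacing)
    f = signal.frequency
    h = np.empty((targets.shape[0], array.n_elements), dtype=complex)
    for n_el, pos in enumerate(array.element_positions):
        d, travel, att = _ray_integrals(model, pos, targets, step_mm, f"element {n_el}")
        h[:, n_el] = (signal.amplitude / d) * np.exp(-att) * np.exp(-2j * np.pi * f * travel)
    return TransferMatrix(h, targets, provenance, f)


# --------------------------------------------------------------------------
# Time reversal and field evaluation
# --------------------------------------------------------------------------

def time_reversal(tm: TransferMatrix, l: int = 0, normalize: bool = True) -> np.ndarray:
    """Time-reversal drive vector for target ``l``: the conjugated TM row.

    With ``normalize=True`` (the package-wide convention) the drive is scaled
    to unit L2 norm, which makes it the Cauchy-Schwarz-optimal unit-norm
    input and bounds the recovery ratio by 100%.
    """
    if not 0 <= l < tm.n_targets:
        raise IndexError(f"target index {l} out of range [0, {tm.n_targets})")
    row = tm.row(l)
    nrm = np.linalg.norm(row)
    if nrm == 0:
        raise ValueError("all-zero transfer-matrix row: no focusing possible")
    e0 = np.conj(row)
    return e0 / nrm if normalize else e0


def field_map(
    model: AcousticHeadModel,
    array: ArrayGeometry,
    e_input,
    center_m,
    shape=(13, 13, 13),
    spacing_mm: float = 2.0,
    signal: SourceSignal = SourceSignal(),
    step_mm: float | None = None,
) -> FieldMap:
    """Coherent pressure-magnitude map of an array drive on a voxel region.

    The region is a ``shape`` grid of ``spacing_mm`` voxels centred on
    ``center_m``.  Each voxel value is ``|sum_n h(voxel, n) e_n|`` under the
    same ray model as :func:`compute_tm`, so the map at any target point
    equals the transfer-matrix prediction exactly.
    """
    e_input = np.asarray(e_input, dtype=complex).ravel()
    if e_input.size != array.n_elements:
        raise ValueError("drive vector length must equal the element count")
    shape = tuple(int(s) for s in np.broadcast_to(shape, (3,)))
    if min(shape) < 1:
        raise ValueError("empty field region")
    spacing = tuple(float(s) for s in np.broadcast_to(spacing_mm, (3,)))
    center = np.broadcast_to(np.asarray(center_m, dtype=float), (3,))
    origin = center - (np.asarray(shape) - 1) / 2.0 * np.asarray(spacing) / 1000.0
    axes = [origin[i] + np.arange(shape[i]) * spacing[i] / 1000.0 for i in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    tm = compute_tm(model, array, pts, signal, step_mm, provenance="true_model")
    pressure = np.abs(tm.values @ e_input).reshape(shape)
    return FieldMap(pressure, spacing, tuple(origin))
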