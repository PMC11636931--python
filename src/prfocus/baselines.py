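"""Comparison probe encodings feeding a common phase-retrieval backend.

The adaptive-focusing literature calibrates array transfer matrices with
structured drive patterns — Hadamard rows, Zernike phase modes, or random
drives.  To compare them against the RED-regularized Bernoulli protocol on
equal footing, every encoding here shares the measurement path, metrics and
the same solver with the RED weight set to zero, so any performance gap
isolates the value of the encoding plus the denoiser regularization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import factorial

import numpy as np
from scipy.linalg import hadamard

from .array_acoustics import ArrayGeometry
from .phase_retrieval import (
    ProbeSet,
    SolverConfig,
    TMEstimate,
    TransferMatrixCalibration,
    bernoulli_probes,
)

__all__ = [
    "EncodingSpec",
    "hadamard_probes",
    "zernike_probes",
    "random_uniform_probes",
    "baseline_estimate",
    "make_probes",
]


@dataclass
class EncodingSpec:
    """Which probe family to draw, how many, and its mode parameters."""

    scheme: str  # hadamard | zernike | random_uniform | bernoulli
    m: int
    n_elements: int
    max_radial_order: int | None = None  # zernike only
    seed: int | None = None

    def __post_init__(self):
        if self.scheme not in ("hadamard", "zernike", "random_uniform", "bernoulli"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.m < 1 or self.n_elements < 1:
            raise ValueError("m and n_elements must be >= 1")


# --------------------------------------------------------------------------
# Hadamard
# --------------------------------------------------------------------------

def hadamard_probes(spec: EncodingSpec) -> ProbeSet:
    """Rows of a Sylvester +-1 Hadamard matrix, truncated to N columns.

    The construction order is the next power of two covering both the
    element count and the probe count; requesting more probes than the order
    provides rows is an error.
    """
    order = 1
    while order < max(spec.m, spec.n_elements):
        order *= 2
    H = hadamard(order).astype(float)
    if spec.m > order:
        raise ValueError(f"only {order} Hadamard rows available, requested {spec.m}")
    if spec.seed is None:
        rows = np.arange(spec.m)
    else:
        rows = np.sort(np.random.default_rng(spec.seed).choice(order, spec.m, replace=False))
    return ProbeSet(H[rows, : spec.n_elements], "hadamard", spec.seed)


# --------------------------------------------------------------------------
# Zernike (Noll ordering)
# --------------------------------------------------------------------------

def _noll_to_nm(j: int) -> tuple:
    """Noll index (1-based) -> (radial order n, azimuthal frequency m)."""
    if j < 1:
        raise ValueError("Noll index starts at 1")
    n = 0
    j1 = j - 1
    while j1 > n:
        n += 1
        j1 -= n
    m = (-1) ** j * ((n % 2) + 2 * int((j1 + ((n + 1) % 2)) / 2.0))
    return n, m


def _zernike_radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for k in range((n - abs(m)) // 2 + 1):
        coef = (
            (-1) ** k
            * factorial(n - k)
            / (factorial(k) * factorial((n + abs(m)) // 2 - k) * factorial((n - abs(m)) // 2 - k))
        )
        out = out + coef * rho ** (n - 2 * k)
    return out


def zernike_polynomial(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Noll-normalized Zernike polynomial Z_j on the unit disk."""
    n, m = _noll_to_nm(j)
    R = _zernike_radial(n, m, rho)
    norm = np.sqrt(2.0 * (n + 1)) if m != 0 else np.sqrt(n + 1.0)
    if m > 0:
        return norm * R * np.cos(m * theta)
    if m < 0:
        return norm * R * np.sin(-m * theta)
    return norm * R


def zernike_probes(spec: EncodingSpec, array: ArrayGeometry) -> ProbeSet:
    """Pure-phase probes ``exp(i pi Z_j)`` sampled at projected elements.

    Elements are projected along the array axis onto the unit aperture disk
    (lateral offset divided by the array radius).
    """
    rel = array.element_positions - np.asarray(array.centre)
    rho = np.linalg.norm(rel[:, :2], axis=1) / array.radius
    if np.any(rho > 1 + 1e-9):
        bad = int(np.argmax(rho))
        raise ValueError(f"element {bad} projects outside the unit aperture disk")
    rho = np.clip(rho, 0.0, 1.0)
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    if spec.n_elements != array.n_elements:
        raise ValueError("encoding spec and array disagree on the element count")
    rows = np.empty((spec.m, array.n_elements), dtype=complex)
    for k in range(spec.m):
        j = k + 1  # Noll indices start at piston
        n_rad, _ = _noll_to_nm(j)
        if spec.max_radial_order is not None and n_rad > spec.max_radial_order:
            raise ValueError(
                f"probe {k} needs radial order {n_rad} > cap {spec.max_radial_order}"
            )
        rows[k] = np.exp(1j * np.pi * zernike_polynomial(j, rho, theta))
    return ProbeSet(rows, "zernike", spec.seed)


def random_uniform_probes(spec: EncodingSpec) -> ProbeSet:
    """Random drives: i.i.d. uniform phases at unit magnitude."""
    rng = np.random.default_rng(spec.seed)
    phases = rng.uniform(0, 2 * np.pi, size=(spec.m, spec.n_elements))
    return ProbeSet(np.exp(1j * phases), "random_uniform", spec.seed)


def make_probes(spec: EncodingSpec, array: ArrayGeometry | None = None) -> ProbeSet:
    if spec.scheme == "hadamard":
        return hadamard_probes(spec)
    if spec.scheme == "zernike":
        if array is None:
            raise ValueError("zernike probes need the array geometry")
        return zernike_probes(spec, array)
    if spec.scheme == "random_uniform":
        return random_uniform_probes(spec)
    return bernoulli_probes(spec.m, spec.n_elements, spec.seed)


# --------------------------------------------------------------------------
# Baseline reconstruction
# --------------------------------------------------------------------------

def baseline_estimate(probes, measurements, config: SolverConfig | None = None,
                      init=None) -> TMEstimate:
    """Same solver as the RED protocol, with the RED penalty switched off.

    lambda = 0 and the identity denoiser make this plain amplitude-flow
    reconstruction, so encoding quality and denoiser regularization are the
    only differences between a baseline and the full protocol.
    """
    config = config if config is not None else SolverConfig()
    config = replace(config, lam=0.0, denoiser="identity")
    model = TransferMatrixCalibration(probes, measurements, config)
    return model.fit(init).estimate
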