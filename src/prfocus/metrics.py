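"""Evaluation metrics for transfer-matrix calibration and focusing.

Four quantities summarize an experiment: the normalized mean-square error
between observed and predicted measurement magnitudes, the Pearson
correlation between estimated and reference transfer-matrix rows (after
global-phase alignment), the recovery ratio ``R%NS`` of gold-standard
maximum pressure, and the focal shift ``delta r`` between two field maxima.
A seeded Gaussian noise injector on the normalized measurement scale is
shared by every experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._utils import align_phase, as_complex_vector
from .array_acoustics import FieldMap

__all__ = [
    "EvaluationReport",
    "mse",
    "corr",
    "recovery_ratio",
    "focus_shift",
    "add_gaussian_noise",
]


@dataclass
class EvaluationReport:
    """A bundle of the four evaluation quantities plus run metadata."""

    mse: float
    corr: float
    r_ns_pct: float
    delta_r_mm: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mse < 0:
            raise ValueError("mse must be nonnegative")
        if not -1.0 - 1e-12 <= self.corr <= 1.0 + 1e-12:
            raise ValueError("corr must lie in [-1, 1]")
        if self.delta_r_mm < 0:
            raise ValueError("delta_r must be nonnegative")

    def to_json(self, path=None) -> str:
        payload = {
            "mse": self.mse,
            "corr": self.corr,
            "r_ns_pct": self.r_ns_pct,
            "delta_r_mm": self.delta_r_mm,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def mse(y, h_est, probes) -> float:
    """Normalized prediction error ``||y - |E h||^2 / ||y||^2``."""
    y = np.asarray(y, dtype=float).ravel()
    if np.linalg.norm(y) == 0:
        raise ValueError("observed magnitudes are all zero")
    E = np.atleast_2d(np.asarray(getattr(probes, "matrix", probes)))
    h = as_complex_vector(h_est, E.shape[1])
    pred = np.abs(E @ h)
    return float(np.linalg.norm(y - pred) ** 2 / np.linalg.norm(y) ** 2)


def corr(h_est, h_stand, moduli_only: bool = False) -> float:
    """Pearson correlation between two complex rows, global-phase aligned.

    Default: align ``h_est`` to ``h_stand`` by the optimal global phase, then
    correlate the concatenated real and imaginary parts.  With
    ``moduli_only=True`` the correlation is taken between the magnitude
    vectors instead (no alignment needed).
    """
    a = as_complex_vector(h_est)
    b = as_complex_vector(h_stand, a.size)
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("correlation undefined for a constant vector")
    if moduli_only:
        x, y = np.abs(a), np.abs(b)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("correlation undefined for constant moduli")
    else:
        a = align_phase(a, b)
        x = np.concatenate([a.real, a.imag])
        y = np.concatenate([b.real, b.imag])
    return float(np.corrcoef(x, y)[0, 1])


def recovery_ratio(p_sim: float, gs_pressure: float) -> float:
    """Percent of gold-standard maximum pressure restored: ``100 * p / GS``.

    Both pressures must come from unit-L2-norm array drives; under that
    convention the gold standard is the Cauchy-Schwarz maximizer and the
    ratio cannot exceed 100.
    """
    if gs_pressure <= 0:
        raise ValueError("gold-standard pressure must be positive")
    if p_sim < 0:
        raise ValueError("pressure magnitude must be nonnegative")
    return float(100.0 * p_sim / gs_pressure)


def focus_shift(field_sim: FieldMap, field_gs: FieldMap) -> float:
    """Euclidean distance (mm) between the argmax voxel centres of two maps."""
    if (
        field_sim.pressure.shape != field_gs.pressure.shape
        or not np.allclose(field_sim.spacing_mm, field_gs.spacing_mm)
        or not np.allclose(field_sim.origin_m, field_gs.origin_m)
    ):
        raise ValueError("field maps must share one grid")
    a = np.asarray(field_sim.argmax_index(), dtype=float) * np.asarray(field_sim.spacing_mm)
    b = np.asarray(field_gs.argmax_index(), dtype=float) * np.asarray(field_gs.spacing_mm)
    return float(np.linalg.norm(a - b))


def add_gaussian_noise(P, std_normalized: float, seed=None) -> np.ndarray:
    """Add Gaussian noise of the given std on the unit-RMS normalized scale.

    The magnitudes are scaled to unit root-mean-square, perturbed by
    ``N(0, std)`` noise, clamped at zero (magnitudes are nonnegative), and
    rescaled.  ``std == 0`` is the identity.  ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    if std_normalized < 0:
        raise ValueError("noise std must be nonnegative")
    P = np.asarray(P, dtype=float).copy()
    if std_normalized == 0:
        return P
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rms = np.sqrt(np.mean(P**2))
    if rms == 0:
        rms = 1.0
    noisy = P / rms + std_normalized * rng.standard_normal(P.shape)
    return np.clip(noisy, 0.0, None) * rms
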