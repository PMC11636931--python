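"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["align_phase", "as_complex_vector", "derive_seed"]


def align_phase(h_est: np.ndarray, h_ref: np.ndarray) -> np.ndarray:
    """Rotate ``h_est`` by the global phase that best matches ``h_ref``.

    Returns ``exp(i * theta) * h_est`` with ``theta`` minimizing
    ``|| exp(i*theta) h_est - h_ref ||_2``.  A zero reference (or zero
    overlap) leaves ``h_est`` unchanged.
    """
    a = np.asarray(h_est, dtype=complex)
    b = np.asarray(h_ref, dtype=complex)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    s = np.vdot(b, a)  # sum a * conj(b)
    if s == 0:
        return a.copy()
    return a * np.exp(-1j * np.angle(s))


def as_complex_vector(h, n: int | None = None) -> np.ndarray:
    h = np.asarray(h, dtype=complex).ravel()
    if n is not None and h.size != n:
        raise ValueError(f"expected length {n}, got {h.size}")
    return h


def derive_seed(master: int, *salt: int) -> int:
    """Deterministic child seed below 2**31 from a master seed and salt ints."""
    ss = np.random.SeedSequence([int(master), *[int(s) for s in salt]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
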