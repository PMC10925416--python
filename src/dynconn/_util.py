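"""Shared helpers: seeded RNG derivation and small validation utilities."""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from one master seed.

    Uses CRC32 of ``"<master>:<stage>"`` so that every stage of a pipeline
    gets an independent, reproducible stream and adding a stage never
    perturbs the others.  Result is always in ``[0, 2**31)``.
    """
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


def check_symmetric(a: np.ndarray, tol: float = 1e-12, name: str = "matrix") -> None:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square, got shape {a.shape}")
    # NaN marks missing rows/columns; compare with NaN==NaN allowed
    at = a.T
    both_nan = np.isnan(a) & np.isnan(at)
    close = np.isclose(a, at, atol=tol, equal_nan=False) | both_nan
    if not close.all():
        raise ValueError(f"{name} is not symmetric")
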