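"""Small numerical helpers shared by the benchmark forward models."""

from __future__ import annotations

import numpy as np

__all__ = ["expm_small"]

# [7/7] Pade coefficients for exp; accurate to double precision for
# matrices scaled to infinity norm <= ~0.95.
_B = (17297280.0, 8648640.0, 1995840.0, 277200.0, 25200.0, 1512.0, 56.0, 1.0)
_EYE: dict[int, np.ndarray] = {}


def expm_small(a: np.ndarray) -> np.ndarray:
    """Matrix exponential of a small dense matrix via scaling-and-squaring
    with a [7/7] Pade approximant.

    Tuned for the tiny (4x4, 10x10) rate generators evaluated millions
    of times inside the fitting loops; agrees with ``scipy.linalg.expm``
    to machine precision at these sizes but avoids its dispatch
    overhead.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    eye = _EYE.get(n)
    if eye is None:
        eye = _EYE.setdefault(n, np.eye(n))
    nrm = float(np.abs(a).sum(axis=1).max())  # infinity norm
    s = 0 if nrm <= 0.9 else int(np.ceil(np.log2(nrm / 0.9)))
    if s:
        a = a / (1 << s)
    a2 = a @ a
    a4 = a2 @ a2
    a6 = a4 @ a2
    u = a @ (_B[7] * a6 + _B[5] * a4 + _B[3] * a2 + _B[1] * eye)
    v = _B[6] * a6 + _B[4] * a4 + _B[2] * a2 + _B[0] * eye
    out = np.linalg.solve(v - u, v + u)
    for _ in range(s):
        out = out @ out
    return out
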