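"""Vectorised matrix exponential for stacked small generator matrices.

The panel likelihood needs ``expm`` of hundreds of thousands of 4x4
matrices per gradient evaluation.  This module implements the standard
scaling-and-squaring algorithm with a degree-13 Pade approximant,
vectorised over an arbitrary batch shape with batched ``matmul`` and
``solve`` so the per-matrix Python overhead disappears.  The squaring
count is chosen from the largest 1-norm in the batch (a conservative but
cheap choice for same-scale generators).  Accuracy matches scipy's
``expm`` to near machine precision on valid generators; tests verify the
agreement.
"""

from __future__ import annotations

import numpy as np

# Pade-13 coefficients (Higham 2005)
_B13 = np.array([
    64764752532480000.0, 32382376266240000.0, 7771770303897600.0,
    1187353796428800.0, 129060195264000.0, 10559470521600.0,
    670442572800.0, 33522128640.0, 1323241920.0, 40840800.0,
    960960.0, 16380.0, 182.0, 1.0,
])
_THETA13 = 5.371920351148152


def expm_batch(A: np.ndarray) -> np.ndarray:
    """``expm`` over the last two axes of a stacked array of square matrices."""
    A = np.asarray(A, dtype=float)
    n = A.shape[-1]
    if A.shape[-2] != n:
        raise ValueError("matrices must be square")
    norm = np.max(np.abs(A).sum(axis=-1)) if A.size else 0.0
    s = max(0, int(np.ceil(np.log2(norm / _THETA13)))) if norm > _THETA13 else 0
    As = A / (2.0 ** s)

    eye = np.broadcast_to(np.eye(n), A.shape)
    A2 = As @ As
    A4 = A2 @ A2
    A6 = A4 @ A2
    b = _B13
    U = As @ (A6 @ (b[13] * A6 + b[11] * A4 + b[9] * A2)
              + b[7] * A6 + b[5] * A4 + b[3] * A2 + b[1] * eye)
    V = (A6 @ (b[12] * A6 + b[10] * A4 + b[8] * A2)
         + b[6] * A6 + b[4] * A4 + b[2] * A2 + b[0] * eye)
    P = np.linalg.solve(V - U, V + U)
    for _ in range(s):
        P = P @ P
    return P
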