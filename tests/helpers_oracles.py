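"""Independent oracles used by the tests.

These deliberately take a different computational route from the package:
the quaternion (Horn) eigenvalue method for optimal superposition instead
of SVD, and brute-force prefix intersection for consensus selection.
"""

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal-superposition RMSD via the largest eigenvalue of Horn's
    4x4 key matrix (proper rotations only)."""
    X = mobile - mobile.mean(0)
    Y = reference - reference.mean(0)
    S = X.T @ Y
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    n = len(X)
    msd = max(((X**2).sum() + (Y**2).sum() - 2.0 * lam) / n, 0.0)
    return float(np.sqrt(msd))


def brute_force_consensus(ids_a: list, ids_b: list, schedule) -> dict:
    """Expected consensus: for each id, the smallest scheduled depth whose
    prefixes of both lists contain it (None if never)."""
    depths = {}
    for d in schedule:
        common = set(ids_a[:d]) & set(ids_b[:d])
        for c in common:
            depths.setdefault(c, d)
    return depths
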