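"""Independent numerical oracles used by the tests.

These deliberately avoid the code paths they check: the quaternion RMSD is
the Horn/Kearsley eigenvalue method, independent of the SVD-based Kabsch
fit in the package.
"""

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD between paired point sets via the quaternion
    (Kearsley) 4×4 eigenvalue formulation."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    m = mc.T @ rc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    e0 = float((mc ** 2).sum() + (rc ** 2).sum())
    return float(np.sqrt(max(e0 - 2.0 * lam, 0.0) / len(mobile)))


def random_proper_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
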