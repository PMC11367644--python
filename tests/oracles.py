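"""Independent references used only to check the package's implementations."""

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal superposition RMSD via the Horn quaternion eigenvalue method.

    Builds the 4x4 key matrix from the coordinate cross-covariance; the
    largest eigenvalue lambda_max gives the minimal residual
    E = sum(|m|^2 + |r|^2) - 2*lambda_max. Entirely independent of the
    SVD-based Kabsch route.
    """
    m = np.asarray(mobile, float) - np.mean(mobile, axis=0)
    r = np.asarray(reference, float) - np.mean(reference, axis=0)
    sxx, sxy, sxz = (m[:, 0] @ r[:, 0]), (m[:, 0] @ r[:, 1]), (m[:, 0] @ r[:, 2])
    syx, syy, syz = (m[:, 1] @ r[:, 0]), (m[:, 1] @ r[:, 1]), (m[:, 1] @ r[:, 2])
    szx, szy, szz = (m[:, 2] @ r[:, 0]), (m[:, 2] @ r[:, 1]), (m[:, 2] @ r[:, 2])
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    e = (m**2).sum() + (r**2).sum() - 2.0 * lam
    return float(np.sqrt(max(e, 0.0) / m.shape[0]))
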