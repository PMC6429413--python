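"""Independent oracles used to cross-check implementations.

The superposition oracle searches rotation space directly (coarse random
quaternion sampling followed by simplex refinement of the rotation vector)
and never uses the SVD-based solution it is checking.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def rmsd_of_rotation(rotvec, x, y):
    r = Rotation.from_rotvec(rotvec).as_matrix()
    d = x @ r.T - y
    return float(np.sqrt(np.mean(np.sum(d**2, axis=1))))


def quaternion_search_rmsd(mobile, reference, n_samples=4000, seed=0):
    """Minimal RMSD over proper rotations by brute-force search + refinement.

    Translations are removed by centering (optimal for least squares);
    rotations are sampled uniformly from the quaternion sphere, and the best
    candidate is polished by Nelder-Mead on the rotation vector.
    """
    x = np.asarray(mobile, float) - np.mean(mobile, axis=0)
    y = np.asarray(reference, float) - np.mean(reference, axis=0)
    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_samples, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    best_val, best_vec = np.inf, np.zeros(3)
    for q in quats:
        vec = Rotation.from_quat(q).as_rotvec()
        val = rmsd_of_rotation(vec, x, y)
        if val < best_val:
            best_val, best_vec = val, vec
    res = minimize(
        rmsd_of_rotation,
        best_vec,
        args=(x, y),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
    )
    return min(best_val, float(res.fun))


def chain_1d_eigenvalues(k, masses):
    """Eigenvalues of a 1-D nearest-neighbour spring chain (pen-and-paper Hessian).

    Builds the tridiagonal force-constant matrix for a linear chain with
    springs k between neighbours, mass-weights it and diagonalizes the tiny
    matrix directly.  Independent of the 3-D elastic-network code path.
    """
    masses = np.asarray(masses, float)
    n = len(masses)
    h = np.zeros((n, n))
    for i in range(n - 1):
        h[i, i] += k
        h[i + 1, i + 1] += k
        h[i, i + 1] -= k
        h[i + 1, i] -= k
    inv = 1.0 / np.sqrt(masses)
    return np.sort(np.linalg.eigvalsh(h * np.outer(inv, inv)))
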