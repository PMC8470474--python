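"""Independent numeric oracle for rigid superposition.

Minimises RMSD over rotations parameterised by unit quaternions with a
general-purpose optimiser and multiple random restarts.  Shares no code
with the package's closed-form solver, so agreement between the two is a
genuine cross-check.
"""

import numpy as np
from scipy.optimize import minimize


def quaternion_to_matrix(q):
    q = np.asarray(q, float)
    q = q / np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def min_rmsd_quaternion(P, Q, seed=0, restarts=8):
    """Best achievable RMSD superposing P onto Q, by numeric minimisation
    over the quaternion rotation manifold (translation eliminated by
    centring)."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    n = len(P0)

    def objective(q):
        R = quaternion_to_matrix(q)
        d = P0 @ R.T - Q0
        return (d * d).sum() / n

    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [np.array([1.0, 0, 0, 0])] + \
        [rng.normal(size=4) for _ in range(restarts - 1)]
    for q0 in starts:
        res = minimize(objective, q0 / np.linalg.norm(q0),
                       method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-16,
                                "maxiter": 20000, "maxfev": 20000})
        if res.fun < best:
            best = res.fun
    return float(np.sqrt(best))
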