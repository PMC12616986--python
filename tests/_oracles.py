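"""Independent dense oracles shared by the unit and acceptance tests."""

import numpy as np
import pandas as pd

from lactsel.breedsim import blup_evaluate, kinship_matrix


def dense_gls_check(atol=1e-6):
    """Sparse MME solution vs the dense multivariate GLS projection
    u_hat = Cov(u, y) V^-1 y on a five-animal, two-trait pedigree with
    missing records.  Raises AssertionError on disagreement."""
    ped = pd.DataFrame({"animal_id": [1, 2, 3, 4, 5],
                        "sire_id": [0, 0, 0, 1, 1],
                        "dam_id": [0, 0, 0, 2, 3]})
    G = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"],
                     columns=["a", "b"])
    R = pd.DataFrame([[2.0, 0.3], [0.3, 1.5]], index=["a", "b"],
                     columns=["a", "b"])
    y = pd.DataFrame({"a": [1.2, np.nan, 0.3, -0.5, 2.0],
                      "b": [0.4, 1.1, np.nan, 0.7, np.nan]},
                     index=[1, 2, 3, 4, 5])
    ebv = blup_evaluate(ped, y, G, R,
                        known_means=pd.Series({"a": 0.0, "b": 0.0}))

    sire = np.array([-1, -1, -1, 0, 0])
    dam = np.array([-1, -1, -1, 1, 2])
    A = kinship_matrix(sire, dam)
    gm, rm = G.to_numpy(), R.to_numpy()
    yn = y.to_numpy()
    obs = [(i, t) for i in range(5) for t in range(2)
           if np.isfinite(yn[i, t])]
    V = np.array([[A[i, j] * gm[t, s] + (i == j) * rm[t, s]
                   for (j, s) in obs] for (i, t) in obs])
    yv = np.array([yn[i, t] for i, t in obs])
    cov_uy = np.array([[A[k, j] * gm[t, s] for (j, s) in obs]
                       for k in range(5) for t in range(2)])
    dense = (cov_uy @ np.linalg.solve(V, yv)).reshape(5, 2)
    np.testing.assert_allclose(ebv.to_numpy(), dense, atol=atol)
    return ebv, dense
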