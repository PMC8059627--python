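"""Independent brute-force oracles used by the test suite only."""

import numpy as np


def brute_force_adj_r2(x, y):
    """Simple-regression fit and adjusted R² from raw normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    X = np.stack([np.ones(n), x], axis=1)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - ss_res / ss_tot
    return beta, r2, 1 - (1 - r2) * (n - 1) / (n - 2)
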