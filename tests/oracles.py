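"""Independent reference computations used by the test suite.

These deliberately avoid the package's own code paths: partial correlation via
regression residuals, the Cox partial likelihood written out directly, and the
log-rank test accumulated term by term from the hypergeometric moments.
"""

import numpy as np


def residual_partial_correlation(x, y, z):
    """Pearson correlation of least-squares residuals of x on z and y on z."""
    Z = np.column_stack([np.ones_like(z), z])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def cox_partial_loglik(beta, times, events, x):
    """Hand-written Cox partial log-likelihood (valid without tied event times)."""
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def logrank_by_hand(times_a, events_a, times_b, events_b):
    """Term-by-term hypergeometric log-rank chi-square for two arms."""
    all_t = np.concatenate([times_a, times_b])
    all_e = np.concatenate([events_a, events_b])
    arm_a = np.concatenate([np.ones(len(times_a), bool), np.zeros(len(times_b), bool)])
    num = 0.0
    var = 0.0
    for t in sorted(set(all_t[all_e == 1])):
        at_risk = all_t >= t
        n = at_risk.sum()
        n1 = (at_risk & arm_a).sum()
        d = ((all_t == t) & (all_e == 1)).sum()
        d1 = ((all_t == t) & (all_e == 1) & arm_a).sum()
        num += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return num**2 / var
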