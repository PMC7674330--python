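"""Independent brute-force oracles the test suite checks the package against.

Everything here is deliberately naive and structurally different from the
implementation paths it verifies: the DEA oracle solves the *multiplier*
(dual) form instead of the envelopment form, FDH is a pure-Python loop over
dominating sets, UrS/UrD expand counts into individual case observations,
the HHI oracle enumerates every share term, and the truncated-regression
oracle is a two-stage dense grid search over the likelihood surface.
"""

import itertools
import math

import numpy as np
from scipy.optimize import linprog
from scipy.stats import norm


def dea_vrs_dual(X, Y, o):
    """Input-oriented VRS efficiency of DMU o via the multiplier form.

    max u'y_o + w  s.t.  v'x_o = 1,  u'y_j - v'x_j + w <= 0 for all j,
    u, v >= 0, w free. Optimal value equals the envelopment theta.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n, p = X.shape
    q = Y.shape[1]
    # variables [v(p), u(q), w]
    c = np.concatenate([np.zeros(p), -Y[o], [-1.0]])
    A_ub = np.column_stack([-X, Y, np.ones(n)])
    b_ub = np.zeros(n)
    A_eq = np.concatenate([X[o], np.zeros(q), [0.0]])[None, :]
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=[1.0],
        bounds=[(0, None)] * (p + q) + [(None, None)],
        method="highs",
    )
    assert res.status == 0
    return -res.fun


def dea_crs_dual(X, Y, o):
    """CRS variant of the multiplier form (no free intercept)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n, p = X.shape
    q = Y.shape[1]
    c = np.concatenate([np.zeros(p), -Y[o]])
    A_ub = np.column_stack([-X, Y])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=np.zeros(n),
        A_eq=np.concatenate([X[o], np.zeros(q)])[None, :],
        b_eq=[1.0],
        bounds=[(0, None)] * (p + q),
        method="highs",
    )
    assert res.status == 0
    return -res.fun


def fdh_enumerate(X, Y, o):
    """FDH input efficiency by explicit loops over dominating DMUs."""
    best = math.inf
    for j in range(len(X)):
        if all(Y[j][r] >= Y[o][r] for r in range(len(Y[o]))):
            ratio = max(X[j][i] / X[o][i] for i in range(len(X[o])))
            best = min(best, ratio)
    return min(best, 1.0)


def urs_urd_by_expansion(codes_counts, u_map):
    """UrS and UrD by expanding each case into one observation.

    UrD uses the ordinary n-1 sample SD over the expanded list.
    """
    cases = []
    for code, cnt in codes_counts.items():
        u = u_map[code]
        if not np.isfinite(u):
            continue
        cases.extend([u] * int(cnt))
    cases = np.asarray(cases, float)
    urs = cases.mean()
    urd = cases.std(ddof=1) if len(cases) > 1 else float("nan")
    return urs, urd


def weighted_hhi_enumerate(hospitals, focal):
    """hospitals: {hid: {"xy": (lat, lon) ignored, "chapters": {c: count}}}.

    Assumes the catchment is everyone passed in; enumerates every share.
    """
    focal_ch = hospitals[focal]["chapters"]
    total_focal = sum(focal_ch.values())
    hhi = 0.0
    for c, cnt in focal_ch.items():
        if cnt == 0:
            continue
        w = cnt / total_focal
        denom = sum(h["chapters"].get(c, 0) for h in hospitals.values())
        hhi_c = sum(
            (h["chapters"].get(c, 0) / denom) ** 2
            for h in hospitals.values()
            if h["chapters"].get(c, 0) > 0
        )
        hhi += w * hhi_c
    return hhi


def truncreg_grid_search(delta, Z, b0_range, b1_range, s_range, step=1e-3):
    """Two-stage dense grid search of the truncated-normal likelihood.

    Coarse pass over the supplied ranges, then a fine pass at ``step``
    resolution around the coarse optimum. Returns (b0, b1, sigma, loglik).
    """
    delta = np.asarray(delta, float)
    Z = np.asarray(Z, float)

    def ll(b0, b1, s):
        mu = b0 + b1 * Z[:, 1]
        r = (delta - mu) / s
        a = (mu - 1.0) / s
        return np.sum(
            -np.log(s) + norm.logpdf(r) - norm.logcdf(a)
        )

    def search(b0s, b1s, ss):
        best = (-math.inf, None)
        for b0, b1, s in itertools.product(b0s, b1s, ss):
            v = ll(b0, b1, s)
            if v > best[0]:
                best = (v, (b0, b1, s))
        return best

    coarse = search(
        np.arange(*b0_range, 20 * step),
        np.arange(*b1_range, 20 * step),
        np.arange(*s_range, 20 * step),
    )
    (b0c, b1c, sc) = coarse[1]
    span = 25 * step
    fine = search(
        np.arange(b0c - span, b0c + span, step),
        np.arange(b1c - span, b1c + span, step),
        np.arange(max(step, sc - span), sc + span, step),
    )
    v, (b0, b1, s) = fine
    return b0, b1, s, v
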