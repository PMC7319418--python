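"""Independent brute-force oracles, kept deliberately separate from the
implementation code paths they check."""

import numpy as np


def trap_membership(x, abcd):
    """Piecewise-linear trapezoid via np.interp (different construction from
    the implementation's branch arithmetic)."""
    a, b, c, d = abcd
    xs, ys = [], []
    if a == b:
        xs += [a - 1.0, a]
        ys += [1.0, 1.0]
    else:
        xs += [a, b]
        ys += [0.0, 1.0]
    if c == d:
        xs += [d, d + 1.0]
        ys += [1.0, 1.0]
    else:
        xs += [c, d]
        ys += [1.0, 0.0]
    return np.interp(x, xs, ys)


def brute_force_mamdani(config, inputs, n_points=6001):
    """Reference Mamdani evaluation: explicit rule loop, dense consequent
    discretisation and trapezoidal-quadrature centroid."""
    lo, hi = config.consequent.universe
    grid = np.linspace(lo, hi, n_points)
    agg = np.zeros(n_points)
    clipped = {
        var.name: float(np.clip(inputs[var.name], *var.universe))
        for var in config.antecedents
    }
    fired = False
    for terms, cterm in config.rules:
        strength = 1.0
        for var, term in zip(config.antecedents, terms):
            strength = min(strength, float(trap_membership(clipped[var.name], var.terms[term])))
        if strength > 0:
            fired = True
        cmf = trap_membership(grid, config.consequent.terms[cterm])
        agg = np.maximum(agg, np.minimum(strength, cmf))
    if not fired:
        raise ValueError("no rule fired")
    num = np.trapezoid(agg * grid, grid)
    den = np.trapezoid(agg, grid)
    return num / den


def exceedance_sort_and_count(flows, percent_exceeded):
    """Order-statistic oracle for flow exceedance: explicit sorted-position
    interpolation of the (100-p)th percentile."""
    v = np.sort(np.asarray(flows, dtype=float))
    q = (100.0 - percent_exceeded) / 100.0
    pos = q * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def beta_ci_quadrature(k, n, lo_mass=0.025, hi_mass=0.975, n_grid=200001):
    """Equal-tailed credible interval of the Beta(k+1, n-k+1) posterior by
    direct numerical integration of the unnormalised density."""
    from math import lgamma

    p = np.linspace(1e-12, 1 - 1e-12, n_grid)
    logpdf = k * np.log(p) + (n - k) * np.log1p(-p)
    logpdf -= logpdf.max()
    pdf = np.exp(logpdf)
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]
    return float(np.interp(lo_mass, cdf, p)), float(np.interp(hi_mass, cdf, p))


def top_half_mean_sort_slice(values):
    """Sort-and-slice oracle for the top-50% (ceil) mean."""
    v = sorted(values, reverse=True)
    k = len(v)
    if k == 0:
        return 0.0
    keep = (k + 1) // 2
    return sum(v[:keep]) / keep
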