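"""Bayesian evaluation of forage and dam-capacity categories.

For each category we observe k successes (active reaches, or dammed active
reaches) in n trials. With a uniform prior the posterior of the category
probability is the exact conjugate Beta(k+1, n-k+1); the MAP is k/n and the
95% credible interval comes from Beta quantiles (equal-tailed by default,
HPD available). Category contrasts are summarised by the posterior
distribution of the probability ratio p_i / p_j, sampled by Monte Carlo:
the reported "MAP Bayes factor" is the mode of a kernel density estimate of
the ratio (Silverman bandwidth on the log scale) with 95% percentile bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CategoryCounts:
    category: str
    successes: int
    trials: int

    def __post_init__(self):
        if not 0 <= self.successes <= self.trials:
            raise ValueError("need 0 <= k <= n")


@dataclass
class PosteriorSummary:
    category: str
    map: float
    ci_low: float
    ci_high: float
    alpha: float  # Beta posterior parameters
    beta: float


def fit_category_binomial(counts: CategoryCounts, interval: str = "equal-tailed") -> PosteriorSummary:
    """Exact conjugate posterior for one category under a uniform prior."""
    k, n = counts.successes, counts.trials
    if n < 1:
        raise ValueError("no trials in category")
    a, b = k + 1.0, n - k + 1.0
    map_ = k / n
    if interval == "equal-tailed":
        lo, hi = stats.beta.ppf([0.025, 0.975], a, b)
    elif interval == "hpd":
        lo, hi = _hpd_beta(a, b, 0.95)
    else:
        raise ValueError("interval must be 'equal-tailed' or 'hpd'")
    return PosteriorSummary(counts.category, float(map_), float(lo), float(hi), a, b)


def _hpd_beta(a: float, b: float, mass: float) -> tuple[float, float]:
    """Highest-posterior-density interval by scanning interval offsets."""
    def width(lo_q):
        lo = stats.beta.ppf(lo_q, a, b)
        hi = stats.beta.ppf(lo_q + mass, a, b)
        return hi - lo
    grid = np.linspace(0.0, 1.0 - mass, 512)
    best = grid[np.argmin([width(q) for q in grid])]
    return stats.beta.ppf(best, a, b), stats.beta.ppf(best + mass, a, b)


@dataclass
class RatioSummary:
    numerator: str
    denominator: str
    map: float
    ci_low: float
    ci_high: float
    unbounded_upper: bool


def _ratio_mode(draws: np.ndarray) -> float:
    """Modal Bayes factor: mode of the Silverman-bandwidth KDE of the
    log ratio, exponentiated.

    Working on the log scale makes the summary reciprocal-symmetric
    (BF(i,j) = 1/BF(j,i) exactly in distribution) and keeps the mode of the
    heavily right-skewed ratio away from the degenerate linear-scale peak.
    """
    logd = np.log(draws)
    kde = stats.gaussian_kde(logd, bw_method="silverman")
    grid = np.linspace(logd.min(), logd.max(), 1024)
    return float(np.exp(grid[np.argmax(kde(grid))]))


def bayes_factor_matrix(
    posteriors: list[PosteriorSummary], mc_draws: int = 100_000, seed: int = 0
) -> pd.DataFrame:
    """Pairwise posterior-ratio summaries between categories.

    Entry (i, j) summarises p_i / p_j from independent draws of the two Beta
    posteriors: KDE mode ('MAP Bayes factor') and 2.5/97.5 percentiles. A
    zero-success denominator flags the upper bound as unbounded. The diagonal
    is 1.
    """
    if len(posteriors) < 2:
        raise ValueError("need at least two categories")
    if mc_draws < 10_000:
        raise ValueError("too few Monte Carlo draws for stable summaries")
    rng = np.random.default_rng(seed)
    draws = {
        p.category: rng.beta(p.alpha, p.beta, size=mc_draws) for p in posteriors
    }
    rows = []
    for pi in posteriors:
        for pj in posteriors:
            if pi.category == pj.category:
                rows.append(
                    RatioSummary(pi.category, pj.category, 1.0, 1.0, 1.0, False)
                )
                continue
            r = draws[pi.category] / draws[pj.category]
            lo, hi = np.percentile(r, [2.5, 97.5])
            rows.append(
                RatioSummary(
                    pi.category,
                    pj.category,
                    _ratio_mode(r),
                    float(lo),
                    float(hi),
                    unbounded_upper=(pj.alpha <= 1.0),  # k = 0 in denominator
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def matrix_lower_triangle(matrix: pd.DataFrame, order: list[str]) -> pd.DataFrame:
    """Render the pairwise summaries as a lower-triangular table
    ('MAP [lo, hi]' strings) in the given category order."""
    out = pd.DataFrame(index=order[1:], columns=order[:-1], dtype=object)
    lut = {(r.numerator, r.denominator): r for r in matrix.itertuples()}
    for i, num in enumerate(order[1:], start=1):
        for den in order[:i]:
            r = lut[(num, den)]
            out.loc[num, den] = f"{r.map:.2f} [{r.ci_low:.2f}, {r.ci_high:.2f}]"
    return out


def metropolis_beta_sample(k: int, n: int, draws: int, seed: int = 0, step: float = 0.1) -> np.ndarray:
    """Simple seeded Metropolis sampler for the binomial posterior
    (uniform prior). Cross-checks the closed form in tests."""
    rng = np.random.default_rng(seed)
    p = max(min(k / max(n, 1), 0.99), 0.01)
    out = np.empty(draws)
    def logpost(q):
        if q <= 0 or q >= 1:
            return -np.inf
        return k * np.log(q) + (n - k) * np.log1p(-q)
    lp = logpost(p)
    for i in range(draws):
        cand = p + step * rng.standard_normal()
        lc = logpost(cand)
        if np.log(rng.random()) < lc - lp:
            p, lp = cand, lc
        out[i] = p
    return out
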