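"""Mamdani fuzzy inference for beaver dam capacity.

Two inference stages map reach attributes to a dam-capacity density in
dams/km on a [0, 30] universe:

1. a vegetation stage combining streamside (10 m) and riparian (40 m)
   forage-index summaries, and
2. a combined stage taking the vegetation capacity together with reach
   slope and stream power at low (Q80) and high (Q2) flow.

Inference is classic Mamdani: trapezoidal memberships, rule firing by the
minimum over antecedent memberships, per-consequent-term aggregation by
maximum, and centroid defuzzification of the aggregated, clipped consequent
over a discretised universe.

Membership breakpoints and rule lists ship as editable YAML
(``data/fis_vegetation.yaml`` and ``data/fis_combined.yaml``); the defaults
are adapted from the BRAT dam-capacity framework and can be replaced
wholesale by user-supplied rule sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml


def trapmf(x, abcd):
    """Trapezoidal membership: 0 at a rises to 1 on [b, c] falls to 0 at d.

    Degenerate edges (a == b or c == d) give crisp shoulders.
    """
    a, b, c, d = abcd
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x)
    if b > a:
        rising = (x > a) & (x < b)
        y[rising] = (x[rising] - a) / (b - a)
    flat = (x >= b) & (x <= c)
    y[flat] = 1.0
    if d > c:
        falling = (x > c) & (x < d)
        y[falling] = (d - x[falling]) / (d - c)
    return y if y.shape else float(y)


@dataclass
class FuzzyVariable:
    """A named variable with a universe and trapezoidal membership terms."""

    name: str
    universe: tuple[float, float]
    terms: dict[str, tuple[float, float, float, float]]

    def __post_init__(self):
        lo, hi = self.universe
        for term, (a, b, c, d) in self.terms.items():
            if not a <= b <= c <= d:
                raise ValueError(f"{self.name}.{term}: breakpoints must be ordered")
        # coverage: no point of the universe may have zero membership everywhere
        xs = np.linspace(lo, hi, 501)
        cover = np.zeros_like(xs)
        for abcd in self.terms.values():
            cover = np.maximum(cover, trapmf(xs, abcd))
        if np.any(cover <= 0):
            gap = xs[np.argmin(cover)]
            raise ValueError(f"{self.name}: membership functions leave a gap near {gap:g}")

    def membership(self, value):
        """Memberships of (clipped) values in every term -> dict of arrays."""
        lo, hi = self.universe
        v = np.clip(np.asarray(value, dtype=float), lo, hi)
        return {term: trapmf(v, abcd) for term, abcd in self.terms.items()}


@dataclass
class FISConfig:
    """Antecedents, consequent and the rule base of one Mamdani stage."""

    antecedents: list[FuzzyVariable]
    consequent: FuzzyVariable
    rules: list[tuple[tuple[str, ...], str]]
    resolution: float = 0.01

    def __post_init__(self):
        names = [a.name for a in self.antecedents]
        for terms, cterm in self.rules:
            if len(terms) != len(self.antecedents):
                raise ValueError("rule arity does not match antecedent count")
            for var, term in zip(self.antecedents, terms):
                if term not in var.terms:
                    raise ValueError(f"rule references unknown term {var.name}.{term}")
            if cterm not in self.consequent.terms:
                raise ValueError(f"rule references unknown consequent term {cterm}")
        self._names = names

    def consequent_grid(self):
        lo, hi = self.consequent.universe
        n = int(round((hi - lo) / self.resolution)) + 1
        return np.linspace(lo, hi, n)


def evaluate_fis(config: FISConfig, inputs: dict[str, float]) -> float:
    """Run Mamdani inference for one crisp input tuple.

    Inputs are clipped to their universes. Raises if no rule fires with
    positive strength (a rule-base coverage violation).
    """
    return float(evaluate_fis_batch(config, {k: np.asarray([v]) for k, v in inputs.items()})[0])


def evaluate_fis_batch(config: FISConfig, inputs: dict[str, np.ndarray]) -> np.ndarray:
    """Vectorised Mamdani inference over arrays of crisp inputs."""
    n = len(next(iter(inputs.values())))
    memb = {}  # (var, term) -> (n,) membership
    for var in config.antecedents:
        if var.name not in inputs:
            raise ValueError(f"missing input for antecedent '{var.name}'")
        for term, m in var.membership(inputs[var.name]).items():
            memb[(var.name, term)] = np.atleast_1d(m)

    cterms = list(config.consequent.terms)
    strength = {t: np.zeros(n) for t in cterms}
    for terms, cterm in config.rules:
        firing = np.ones(n)
        for var, term in zip(config.antecedents, terms):
            firing = np.minimum(firing, memb[(var.name, term)])
        strength[cterm] = np.maximum(strength[cterm], firing)

    total = np.zeros(n)
    for t in cterms:
        total = np.maximum(total, strength[t])
    if np.any(total <= 0):
        idx = int(np.argmin(total))
        vals = {k: float(np.asarray(v)[idx]) for k, v in inputs.items()}
        raise ValueError(f"no rule fires for input {vals}; rule base does not cover it")

    grid = config.consequent_grid()
    cmf = np.stack([trapmf(grid, config.consequent.terms[t]) for t in cterms])  # (T, G)
    s = np.stack([strength[t] for t in cterms])  # (T, n)
    # aggregated membership per input: max over terms of min(strength, term mf)
    agg = np.max(np.minimum(s[:, :, None], cmf[:, None, :]), axis=0)  # (n, G)
    return (agg * grid).sum(axis=1) / agg.sum(axis=1)


# --- default configurations -------------------------------------------------


def _load_yaml(name: str) -> dict:
    with resources.files("damcap.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def fis_from_dict(cfg: dict) -> FISConfig:
    antecedents = [
        FuzzyVariable(a["name"], tuple(a["universe"]), {t: tuple(v) for t, v in a["terms"].items()})
        for a in cfg["antecedents"]
    ]
    c = cfg["consequent"]
    consequent = FuzzyVariable(c["name"], tuple(c["universe"]), {t: tuple(v) for t, v in c["terms"].items()})
    rules = [(tuple(r[:-1]), r[-1]) for r in cfg["rules"]]
    return FISConfig(antecedents, consequent, rules, resolution=cfg.get("resolution", 0.01))


def default_vegetation_fis() -> FISConfig:
    return fis_from_dict(_load_yaml("fis_vegetation.yaml"))


def default_combined_fis() -> FISConfig:
    return fis_from_dict(_load_yaml("fis_combined.yaml"))


def vegetation_capacity(streamside_bfi, riparian_bfi, veg_config: FISConfig | None = None) -> np.ndarray:
    """Dam capacity (dams/km) supported by vegetation alone."""
    cfg = veg_config or default_vegetation_fis()
    s = np.atleast_1d(np.asarray(streamside_bfi, dtype=float))
    r = np.atleast_1d(np.asarray(riparian_bfi, dtype=float))
    return evaluate_fis_batch(cfg, {"streamside_bfi": s, "riparian_bfi": r})


def combined_capacity(veg_capacity, slope, power_q80, power_q2, comb_config: FISConfig | None = None) -> np.ndarray:
    """Dam capacity after accounting for slope and stream-power controls."""
    cfg = comb_config or default_combined_fis()
    arrs = {
        "veg_capacity": np.atleast_1d(np.asarray(veg_capacity, dtype=float)),
        "slope": np.atleast_1d(np.asarray(slope, dtype=float)),
        "power_q80": np.atleast_1d(np.asarray(power_q80, dtype=float)),
        "power_q2": np.atleast_1d(np.asarray(power_q2, dtype=float)),
    }
    return evaluate_fis_batch(cfg, arrs)


# --- constraints and categories ---------------------------------------------


@dataclass
class ConstraintConfig:
    """Physical limits beyond which reaches cannot hold dams.

    Wide channels (lakes/large rivers), large contributing areas and high
    stream orders are zeroed; 5th-order streams are capped at a low density.
    """

    max_width_m: float = 25.0
    max_area_km2: float = 250.0
    max_order: int = 5
    order5_cap_dpkm: float = 0.9


def apply_constraints(capacity, width_m, contrib_area_km2, order, cc: ConstraintConfig | None = None):
    cc = cc or ConstraintConfig()
    cap = np.atleast_1d(np.asarray(capacity, dtype=float)).copy()
    w = np.atleast_1d(np.asarray(width_m, dtype=float))
    a = np.atleast_1d(np.asarray(contrib_area_km2, dtype=float))
    o = np.atleast_1d(np.asarray(order))
    cap[(w > cc.max_width_m) | (a > cc.max_area_km2) | (o > cc.max_order)] = 0.0
    five = o == cc.max_order
    cap[five] = np.minimum(cap[five], cc.order5_cap_dpkm)
    return cap


CATEGORY_ORDER = ["None", "Rare", "Occasional", "Frequent", "Pervasive"]
_CATEGORY_UPPER = [0.0, 1.0, 4.0, 15.0, 30.0]


def categorize_capacity(capacity):
    """Dam-capacity class: None {0}, Rare (0,1], Occasional (1,4],
    Frequent (4,15], Pervasive (15,30]."""
    cap = np.atleast_1d(np.asarray(capacity, dtype=float))
    if np.any((cap < 0) | (cap > 30)):
        raise ValueError("capacity outside [0, 30] dams/km")
    idx = np.searchsorted(_CATEGORY_UPPER, cap, side="left")
    idx = np.clip(idx, 0, 4)
    out = np.array(CATEGORY_ORDER, dtype=object)[idx]
    return out


def max_dams(capacity, length_m):
    """Expected maximum dams a reach can hold: density x length."""
    return np.asarray(capacity, dtype=float) * np.asarray(length_m, dtype=float) / 1000.0
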