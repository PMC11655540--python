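"""Over-coverage estimation by year and subgroup.

Over-coverage in year y is OC_y = 1 - sum_{i in D_y} Zhat_iy / |D_y|, where
D_y is the set of individuals administratively registered in year y (arrived,
no recorded death, not de-registered without a later re-registration) and
Zhat_iy is the presence probability: exactly 1 for individuals detected in
at least one list that year, and the posterior smoothed probability
otherwise.  The register-trace alternative counts an individual as present
iff detected in at least one list, which can only over-state over-coverage
relative to the model (Zhat_iy >= 0 with equality to 1 on detected years).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ModelConfig
from .likelihood import PackedCohort
from .simulate import _administratively_registered

__all__ = [
    "registered_set",
    "oc_estimate",
    "register_trace_oc",
    "oc_table",
    "gap_summary",
    "plot_overcoverage",
    "plot_gap_summary",
]


def registered_set(
    individuals: pd.DataFrame,
    events: pd.DataFrame,
    year: int,
    subgroup: pd.Series | np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask (over individuals rows) of the denominator set D_y.

    Includes individuals with registration_year <= year, no recorded death
    up to year, and no unresolved de-registration (a de-registration at or
    before year with no re-registration in between).  ``subgroup`` is an
    optional extra boolean filter aligned with ``individuals``.
    """
    mask = _administratively_registered(individuals, events, year)
    if subgroup is not None:
        mask = mask & np.asarray(subgroup, dtype=bool)
    return mask


def _seen_in_year(individuals: pd.DataFrame, observations: pd.DataFrame,
                  year: int) -> np.ndarray:
    obs_y = observations[(observations["year"] == year)
                         & (observations["value"] == 1)]
    return individuals["id"].isin(obs_y["id"].unique()).to_numpy()


def register_trace_oc(
    individuals: pd.DataFrame,
    observations: pd.DataFrame,
    events: pd.DataFrame,
    year: int,
    subgroup=None,
) -> float | None:
    """Deterministic register-trace over-coverage: the fraction of D_y not
    seen in any list in ``year``.  Returns None for an empty D_y."""
    d = registered_set(individuals, events, year, subgroup)
    if not d.any():
        return None
    seen = _seen_in_year(individuals, observations, year)
    return float(1.0 - seen[d].mean())


def oc_estimate(
    individuals: pd.DataFrame,
    events: pd.DataFrame,
    zhat_mean: np.ndarray,
    year: int,
    config: ModelConfig,
    subgroup=None,
    zhat_draws: np.ndarray | None = None,
    ci_level: float = 0.95,
    seed: int = 0,
):
    """Model-based over-coverage for one year (and optional subgroup).

    ``zhat_mean`` is the (n, Y) posterior-mean presence array aligned with
    ``individuals`` sorted by id; ``zhat_draws`` (optional, (n_draws, n, Y))
    per-draw smoothed presence.  The credible interval is a posterior
    predictive interval for the realized over-coverage: for every retained
    coefficient draw the latent presence indicators of the unconstrained
    individual-years are sampled as Bernoulli(zhat) and the resulting OC
    fractions quantiled, so the interval reflects both coefficient
    uncertainty and the binomial realization of who is actually present.
    Returns (point, lower, upper, n) with lower/upper None when draws are
    absent, or None for an empty D_y.
    """
    ind = individuals.sort_values("id").reset_index(drop=True)
    d = registered_set(ind, events, year, subgroup)
    if not d.any():
        return None
    col = year - config.first_year
    z = zhat_mean[d, col]
    point = float(1.0 - np.nanmean(z))
    lo = hi = None
    if zhat_draws is not None:
        zd = zhat_draws[:, d, col].astype(float)
        rng = np.random.default_rng(seed + year)
        sampled = rng.random(zd.shape) < zd
        per_draw = 1.0 - sampled.mean(axis=1)
        a = (1.0 - ci_level) / 2.0
        lo, hi = (float(np.quantile(per_draw, a)),
                  float(np.quantile(per_draw, 1.0 - a)))
    return point, lo, hi, int(d.sum())


def _subgroup_iter(individuals: pd.DataFrame, by: list[str] | None, year: int):
    """Yield (label dict, boolean mask) for each subgroup cell."""
    if not by:
        yield {}, np.ones(len(individuals), dtype=bool)
        return
    cols = {}
    for b in by:
        if b == "tsm":
            cols[b] = year - individuals["registration_year"]
        elif b in individuals.columns:
            cols[b] = individuals[b]
        else:
            raise ValueError(f"unknown subgroup column {b!r}")
    frame = pd.DataFrame(cols)
    for key, idx in frame.groupby(by if len(by) > 1 else by[0]).groups.items():
        if not isinstance(key, tuple):
            key = (key,)
        mask = np.zeros(len(individuals), dtype=bool)
        mask[individuals.index.get_indexer(idx)] = True
        yield dict(zip(by, key)), mask


def oc_table(
    individuals: pd.DataFrame,
    observations: pd.DataFrame,
    events: pd.DataFrame,
    zhat_mean: np.ndarray,
    config: ModelConfig,
    years: list[int] | None = None,
    by: list[str] | None = None,
    zhat_draws: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tidy over-coverage table: one row per (year, subgroup, method).

    Methods are ``model`` (with 95% credible interval when per-draw
    presence is supplied) and ``register_trace`` (deterministic, no
    interval).  Over-coverage is estimated from the year after the window
    opens (no one can have silently left in the first year).
    """
    ind = individuals.sort_values("id").reset_index(drop=True)
    if years is None:
        years = list(range(config.first_year + 1, config.last_year + 1))
    rows = []
    for year in years:
        for label, sub in _subgroup_iter(ind, by, year):
            est = oc_estimate(ind, events, zhat_mean, year, config,
                              subgroup=sub, zhat_draws=zhat_draws)
            trace = register_trace_oc(ind, observations, events, year, sub)
            base = {"year": year, **label}
            if est is not None:
                point, lo, hi, nreg = est
                rows.append({**base, "method": "model", "estimate": point,
                             "lower": lo, "upper": hi, "n_registered": nreg})
            if trace is not None:
                d = registered_set(ind, events, year, sub)
                rows.append({**base, "method": "register_trace",
                             "estimate": trace, "lower": None, "upper": None,
                             "n_registered": int(d.sum())})
    return pd.DataFrame(rows)


def gap_summary(
    zhat_mean: np.ndarray,
    packed: PackedCohort,
    aggregate: bool = True,
    quantiles: tuple = (0.1, 0.25, 0.5, 0.75, 0.9),
) -> pd.DataFrame:
    """Presence probabilities of undetected individual-years by gap length.

    For every unconstrained (no detection, no recorded event) individual-year
    y before the final year, records the number of consecutive undetected
    years ending at y (the gap), time since first migration, whether the
    individual is detected in at least one list in y+1, and the posterior
    presence probability.  With ``aggregate=True`` returns per-cell
    quantiles; otherwise the row-level table.
    """
    cfg = packed.config
    n, Y = packed.obs_any.shape
    rows = []
    for i in range(n):
        y0 = packed.start[i]
        gap = 0
        for y in range(y0 + 1, Y):
            if packed.obs_any[i, y]:
                gap = 0
                continue
            gap += 1
            if packed.mask[i, y] != 0:  # event-pinned year: not a free gap
                continue
            if y == Y - 1:
                continue
            rows.append({
                "id": packed.ids[i],
                "year": cfg.first_year + y,
                "gap": gap,
                "tsm": int(y - y0),
                "seen_next": int(packed.obs_any[i, y + 1]),
                "zhat": float(zhat_mean[i, y]),
            })
    detail = pd.DataFrame(rows, columns=["id", "year", "gap", "tsm",
                                         "seen_next", "zhat"])
    if not aggregate:
        return detail
    if detail.empty:
        return pd.DataFrame(columns=["gap", "tsm", "seen_next", "n", "mean"]
                            + [f"q{int(100 * q)}" for q in quantiles])
    def agg(g):
        out = {"n": len(g), "mean": g["zhat"].mean()}
        for q in quantiles:
            out[f"q{int(100 * q)}"] = g["zhat"].quantile(q)
        return pd.Series(out)
    table = (detail.groupby(["gap", "tsm", "seen_next"])
             .apply(agg, include_groups=False).reset_index())
    table["n"] = table["n"].astype(int)
    return table


def plot_overcoverage(table: pd.DataFrame, ax=None):
    """Over-coverage by year: model estimate with credible band vs the
    register-trace curve.  Expects an un-grouped ``oc_table`` output."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    model = table[table["method"] == "model"].sort_values("year")
    trace = table[table["method"] == "register_trace"].sort_values("year")
    ax.plot(trace["year"], trace["estimate"], "k-", label="register trace")
    ax.plot(model["year"], model["estimate"], "b-", label="model")
    if model["lower"].notna().any():
        ax.plot(model["year"], model["lower"], "b--", lw=0.8)
        ax.plot(model["year"], model["upper"], "b--", lw=0.8)
    ax.set_xlabel("year")
    ax.set_ylabel("over-coverage")
    ax.legend()
    return ax


def plot_gap_summary(detail: pd.DataFrame, ax=None):
    """Histograms of presence probability by gap length (detail table)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for gap, g in detail.groupby("gap"):
        if gap > 4:
            continue
        ax.hist(g["zhat"], bins=20, range=(0, 1), alpha=0.5, density=True,
                label=f"gap {gap} (n={len(g)})")
    ax.set_xlabel("posterior presence probability")
    ax.set_ylabel("density")
    ax.legend()
    return ax
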