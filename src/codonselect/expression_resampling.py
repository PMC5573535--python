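"""Age-trajectory test for expression divergence from constancy.

For each species (and brain region) the observed expression values are
lowess-smoothed against log2-transformed age, and a null envelope is built
by permuting expression values across individuals within the series — the
null of constant expression over the lifespan — refitting the lowess on
each permutation, and taking pointwise 2.5%/97.5% percentiles. Grid points
where the observed curve leaves the envelope mark ages of significant
deviation; comparing envelopes across species localizes lineage-specific
expression dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

#: default offset (years) added before the log2 age transform; roughly a
#: human gestation so that age 0 maps to a finite coordinate.
AGE_OFFSET = 0.75

MIN_SERIES_SIZE = 8


@dataclass
class ExpressionSeries:
    """Expression measurements for one species x region series."""

    species: str
    region: str
    individuals: list
    ages: np.ndarray
    expression: np.ndarray
    age_offset: float = AGE_OFFSET

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.expression = np.asarray(self.expression, dtype=float)
        if np.any(self.ages < 0):
            raise ValueError("ages must be non-negative")
        if self.ages.shape != self.expression.shape:
            raise ValueError("ages and expression lengths differ")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individuals within a series")

    @property
    def n(self) -> int:
        return self.ages.size

    @property
    def x(self) -> np.ndarray:
        """log2 age coordinate used by every fit."""
        return np.log2(self.ages + self.age_offset)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, species: str = None,
                   region: str = None,
                   age_offset: float = AGE_OFFSET) -> "ExpressionSeries":
        """Build one series from a tidy table (individual, species, region,
        age_years, expression); with multiple species/regions present the
        wanted one must be named."""
        sub = df
        if species is not None:
            sub = sub[sub["species"] == species]
        if region is not None:
            sub = sub[sub["region"] == region]
        sp = sub["species"].unique()
        rg = sub["region"].unique()
        if len(sp) != 1 or len(rg) != 1:
            raise ValueError("frame holds multiple series; specify "
                             "species and region")
        return cls(species=sp[0], region=rg[0],
                   individuals=list(sub["individual"]),
                   ages=sub["age_years"].to_numpy(),
                   expression=sub["expression"].to_numpy(),
                   age_offset=age_offset)


def split_series(df: pd.DataFrame,
                 age_offset: float = AGE_OFFSET) -> list:
    """All species x region series present in a tidy expression table."""
    out = []
    for (sp, rg), sub in df.groupby(["species", "region"], sort=True):
        out.append(ExpressionSeries.from_frame(sub, sp, rg, age_offset))
    return out


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"individual", "species", "region", "age_years", "expression"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    return df


def lowess_curve(series: ExpressionSeries, span: float = 0.5,
                 robust_iters: int = 3, grid_points: int = 100,
                 grid: np.ndarray = None) -> tuple:
    """Locally weighted regression of expression on log2 age, evaluated on
    an even grid spanning the observed age range. Returns (grid, fitted)."""
    if series.n < 4:
        raise ValueError("need at least 4 points for a lowess fit")
    if span * series.n < 2:
        raise ValueError("span window holds fewer than 2 points")
    x = series.x
    if grid is None:
        grid = np.linspace(x.min(), x.max(), grid_points)
    fit = sm_lowess(series.expression, x, frac=span, it=robust_iters,
                    xvals=grid)
    return grid, fit


@dataclass
class Envelope:
    """Permutation null band for one series' lowess curve."""

    series: ExpressionSeries
    grid: np.ndarray
    observed: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    B: int
    seed: int
    percentiles: tuple = (2.5, 97.5)
    span: float = 0.5

    def __post_init__(self):
        if np.any(self.lower > self.upper + 1e-12):
            raise ValueError("lower envelope exceeds upper")

    @property
    def exceed_above(self) -> np.ndarray:
        return self.observed > self.upper

    @property
    def exceed_below(self) -> np.ndarray:
        return self.observed < self.lower

    @property
    def flags(self) -> np.ndarray:
        return self.exceed_above | self.exceed_below

    @property
    def exceed_fraction(self) -> float:
        return float(self.flags.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": self.series.species, "region": self.series.region,
            "log2_age": self.grid,
            "age_years": 2.0 ** self.grid - self.series.age_offset,
            "observed": self.observed, "lower": self.lower,
            "upper": self.upper, "exceeds": self.flags,
        })


def null_envelope(series: ExpressionSeries, B: int = 1000,
                  percentiles: tuple = (2.5, 97.5), seed: int = 0,
                  span: float = 0.5, robust_iters: int = 3,
                  grid_points: int = 100) -> Envelope:
    """Permutation envelope under the constant-expression null.

    Expression values are reshuffled across individuals within the series B
    times; each reshuffle is lowess-refit on the same age grid, and the
    pointwise percentile band is compared with the observed curve.
    """
    if B < 100:
        raise ValueError("B < 100 gives unstable tail percentiles")
    if series.n < MIN_SERIES_SIZE:
        raise ValueError(
            f"series '{series.species}/{series.region}' has {series.n} "
            f"individuals; need >= {MIN_SERIES_SIZE} for an envelope")
    rng = np.random.default_rng(seed)
    grid, observed = lowess_curve(series, span, robust_iters, grid_points)
    x = series.x
    y = series.expression
    sims = np.empty((B, grid.size))
    for b in range(B):
        perm = rng.permutation(y)
        sims[b] = sm_lowess(perm, x, frac=span, it=robust_iters, xvals=grid)
    lower, upper = np.percentile(sims, percentiles, axis=0)
    return Envelope(series=series, grid=grid, observed=observed,
                    lower=lower, upper=upper, B=B, seed=seed,
                    percentiles=percentiles, span=span)


def deviation_report(envelopes) -> pd.DataFrame:
    """Comparative table across species/regions: exceedance fraction,
    direction, and the age intervals where the observed curve leaves the
    null band."""
    rows = []
    for env in envelopes:
        above = env.exceed_above
        below = env.exceed_below
        intervals = []
        for mask, tag in ((above, "up"), (below, "down")):
            start = None
            for i, m in enumerate(list(mask) + [False]):
                if m and start is None:
                    start = i
                elif not m and start is not None:
                    a = 2.0 ** env.grid[start] - env.series.age_offset
                    bnd = 2.0 ** env.grid[i - 1] - env.series.age_offset
                    intervals.append(f"{tag}:{a:.1f}-{bnd:.1f}y")
                    start = None
        rows.append({
            "species": env.series.species, "region": env.series.region,
            "n_individuals": env.series.n,
            "exceed_fraction": env.exceed_fraction,
            "fraction_up": float(above.mean()),
            "fraction_down": float(below.mean()),
            "direction": ("up" if above.sum() > below.sum() else
                          "down" if below.any() else "none"),
            "intervals": ";".join(intervals) if intervals else "",
        })
    return pd.DataFrame(rows, columns=[
        "species", "region", "n_individuals", "exceed_fraction",
        "fraction_up", "fraction_down", "direction", "intervals"])


def plot_envelope(env: Envelope, ax=None):
    """Draw points, lowess curve, and null band in the usual layout."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(env.series.x, env.series.expression, s=18, alpha=0.8,
               label="individuals")
    ax.plot(env.grid, env.observed, lw=2, label="lowess")
    ax.plot(env.grid, env.lower, lw=1, ls="--", color="gray")
    ax.plot(env.grid, env.upper, lw=1, ls="--", color="gray",
            label=f"null {env.percentiles[0]}–{env.percentiles[1]}%")
    ax.set_xlabel("log2(age + offset)")
    ax.set_ylabel("expression (log)")
    ax.set_title(f"{env.series.species} {env.series.region}")
    ax.legend(fontsize=8)
    return ax
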