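"""Group-level statistics: ANOVA, Tukey HSD, correlation, and the omega histogram.

The one-way analysis of variance decomposes dN/dS variation into a
between-functional-group and a residual component and tests the F ratio.
Tukey's honestly-significant-difference procedure then compares all group
means simultaneously with studentized-range critical values (Tukey-Kramer for
unequal group sizes); group means are reported with simultaneous confidence
half-widths (q / sqrt(2)) * sqrt(MSE / n_i), so two means are declared
different exactly when their adjusted p falls below alpha.

Studentized-range tail probabilities are evaluated by direct two-dimensional
Gauss-Legendre quadrature of

    P(Q <= q) = int_0^inf f_S(s) * k int phi(z) [Phi(z) - Phi(z - q s)]^(k-1) dz ds

with S = sqrt(chi2_df / df); the quadrature is vectorized over q, which keeps
large simulation-based calibrations (thousands of Tukey calls) affordable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.special import gammaln, ndtr


class StatsError(ValueError):
    pass


# --------------------------------------------------------------------------
# studentized range distribution
# --------------------------------------------------------------------------

# grid sizes hold the absolute CDF error near 1e-5, ample for p-values while
# keeping simulation calibrations (thousands of Tukey calls) fast
_NZ, _NS = 64, 40


@lru_cache(maxsize=64)
def _z_grid():
    x, w = np.polynomial.legendre.leggauss(_NZ)
    lo, hi = -9.0, 9.0
    return lo + (hi - lo) * (x + 1) / 2, w * (hi - lo) / 2


@lru_cache(maxsize=256)
def _s_grid(df: int):
    x, w = np.polynomial.legendre.leggauss(_NS)
    spread = 9.0 / math.sqrt(df)
    lo, hi = max(0.0, 1.0 - spread), 1.0 + max(spread, 0.35)
    s = lo + (hi - lo) * (x + 1) / 2
    ws = w * (hi - lo) / 2
    # chi density of S = sqrt(chi2_df / df), in log space for large df
    log_dens = (
        math.log(2.0)
        + (df / 2.0) * math.log(df / 2.0)
        - gammaln(df / 2.0)
        + (df - 1) * np.log(s)
        - df * s**2 / 2.0
    )
    return s, ws * np.exp(log_dens)


def _range_cdf(r: np.ndarray, k: int) -> np.ndarray:
    """P(range of k standard normals <= r), vectorized over r (any shape)."""
    z, wz = _z_grid()
    shape = r.shape
    rr = r.reshape(-1, 1)
    inner = ndtr(z) - ndtr(z - rr)
    np.clip(inner, 0.0, None, out=inner)
    phi = np.exp(-z**2 / 2.0) / math.sqrt(2.0 * math.pi)
    vals = k * (inner ** (k - 1) * phi * wz).sum(axis=1)
    return vals.reshape(shape)


def studentized_range_cdf(q, k: int, df: int):
    """CDF of the studentized range with k groups and df error degrees of freedom."""
    q = np.asarray(q, dtype=float)
    s, ws = _s_grid(df)
    r = np.maximum(q[..., None], 0.0) * s  # (..., ns)
    out = (_range_cdf(r, k) * ws).sum(axis=-1)
    return np.clip(out, 0.0, 1.0)


def studentized_range_sf(q, k: int, df: int):
    return 1.0 - studentized_range_cdf(q, k, df)


def studentized_range_ppf(p: float, k: int, df: int) -> float:
    """Quantile: smallest q with CDF(q) >= p (p the coverage, e.g. 0.95)."""
    if not 0 < p < 1:
        raise StatsError("ppf probability must be in (0, 1)")
    return brentq(lambda q: float(studentized_range_cdf(q, k, df)) - p, 1e-6, 100.0)


# --------------------------------------------------------------------------
# ANOVA
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaRow:
    source: str
    ss: float
    df: int
    ms: float | None = None
    f: float | None = None
    p: float | None = None


@dataclass
class AnovaTable:
    rows: list[AnovaRow]

    def row(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    @property
    def p(self) -> float:
        return self.row("Groups").p

    @property
    def f(self) -> float:
        return self.row("Groups").f

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "Source": r.source,
                    "SS": r.ss,
                    "df": r.df,
                    "MS": r.ms,
                    "F": r.f,
                    "Prob>F": r.p,
                }
                for r in self.rows
            ]
        )


def _group_arrays(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise StatsError("values and labels must have equal length")
    uniq, inverse = np.unique(labels, return_inverse=True)
    return values, uniq, inverse


def one_way_anova(values, labels) -> AnovaTable:
    """Fixed-effects one-way ANOVA decomposition with the F-test p-value."""
    values, uniq, inverse = _group_arrays(values, labels)
    k, n = len(uniq), len(values)
    if k < 2:
        raise StatsError("one-way ANOVA requires at least 2 groups")
    counts = np.bincount(inverse)
    sums = np.bincount(inverse, weights=values)
    means = sums / counts
    grand = values.mean()
    ss_groups = float(np.sum(counts * (means - grand) ** 2))
    ss_total = float(np.sum((values - grand) ** 2))
    ss_error = ss_total - ss_groups
    df_groups, df_error = k - 1, n - k
    if df_error < 1:
        raise StatsError("no residual degrees of freedom")
    ms_groups = ss_groups / df_groups
    ms_error = ss_error / df_error
    if ms_error <= 0:
        f_stat = math.inf if ms_groups > 0 else 0.0
        p = 0.0 if ms_groups > 0 else 1.0
    else:
        f_stat = ms_groups / ms_error
        p = float(sps.f.sf(f_stat, df_groups, df_error))
    return AnovaTable(
        rows=[
            AnovaRow("Groups", ss_groups, df_groups, ms_groups, f_stat, p),
            AnovaRow("Error", ss_error, df_error, ms_error),
            AnovaRow("Total", ss_total, n - 1),
        ]
    )


def two_way_anova(values, group_labels, copy_labels) -> AnovaTable:
    """Main-effects two-factor ANOVA with Type II sums of squares.

    Suited to the highly unbalanced functional-group x copy-number design;
    empty factor levels are dropped, aliased (confounded) factors are an error.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "group": pd.Categorical(group_labels),
            "copy": pd.Categorical(copy_labels),
        }
    )
    df["group"] = df["group"].cat.remove_unused_categories()
    df["copy"] = df["copy"].cat.remove_unused_categories()
    for factor in ("group", "copy"):
        if df[factor].nunique() < 2:
            raise StatsError(f"factor {factor!r} has fewer than 2 levels")
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols("value ~ C(group) + C(copy)", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise StatsError("factors are aliased: design matrix is rank deficient")
    table = sm.stats.anova_lm(model, typ=2)
    rows = [
        AnovaRow(
            "Groups",
            float(table.loc["C(group)", "sum_sq"]),
            int(table.loc["C(group)", "df"]),
            float(table.loc["C(group)", "sum_sq"] / table.loc["C(group)", "df"]),
            float(table.loc["C(group)", "F"]),
            float(table.loc["C(group)", "PR(>F)"]),
        ),
        AnovaRow(
            "CopyNumber",
            float(table.loc["C(copy)", "sum_sq"]),
            int(table.loc["C(copy)", "df"]),
            float(table.loc["C(copy)", "sum_sq"] / table.loc["C(copy)", "df"]),
            float(table.loc["C(copy)", "F"]),
            float(table.loc["C(copy)", "PR(>F)"]),
        ),
        AnovaRow(
            "Error",
            float(table.loc["Residual", "sum_sq"]),
            int(table.loc["Residual", "df"]),
            float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"]),
        ),
    ]
    return AnovaTable(rows=rows)


# --------------------------------------------------------------------------
# Tukey HSD
# --------------------------------------------------------------------------


@dataclass
class TukeyResult:
    groups: list
    means: np.ndarray
    ns: np.ndarray
    halfwidths: np.ndarray  # simultaneous 95% CI half-widths for group means
    q_crit: float
    alpha: float
    diffs: dict = field(default_factory=dict)  # (g1, g2) -> (diff, p_adj, significant)

    def significant_pairs(self):
        return [pair for pair, (_, _, sig) in self.diffs.items() if sig]

    def extreme_groups(self):
        """Groups whose mean differs significantly from every other group."""
        out = []
        for i, g in enumerate(self.groups):
            others = [o for o in self.groups if o != g]
            if all(
                self.diffs[tuple(sorted((str(g), str(o)), key=str))][2] for o in others
            ):
                out.append(g)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.groups,
                "n": self.ns,
                "mean": self.means,
                "lo": self.means - self.halfwidths,
                "hi": self.means + self.halfwidths,
            }
        )


def tukey_hsd(values, labels, alpha: float = 0.05) -> TukeyResult:
    """Tukey-Kramer all-pairs comparison plus simultaneous group-mean intervals."""
    if not 0 < alpha < 1:
        raise StatsError("alpha must be in (0, 1)")
    values, uniq, inverse = _group_arrays(values, labels)
    k = len(uniq)
    if k < 2:
        raise StatsError("Tukey HSD requires at least 2 groups")
    anova = one_way_anova(values, np.asarray(labels))
    mse = anova.row("Error").ms
    dfe = anova.row("Error").df
    counts = np.bincount(inverse)
    means = np.bincount(inverse, weights=values) / counts
    q_crit = studentized_range_ppf(1 - alpha, k, dfe)
    halfwidths = (q_crit / math.sqrt(2.0)) * np.sqrt(mse / counts)

    pairs_i, pairs_j = np.triu_indices(k, 1)
    diffs = means[pairs_i] - means[pairs_j]
    se = np.sqrt((mse / 2.0) * (1.0 / counts[pairs_i] + 1.0 / counts[pairs_j]))
    with np.errstate(divide="ignore", invalid="ignore"):
        q_stat = np.where(se > 0, np.abs(diffs) / se, np.where(diffs == 0, 0.0, np.inf))
    p_adj = np.where(np.isfinite(q_stat), studentized_range_sf(np.where(np.isfinite(q_stat), q_stat, 0.0), k, dfe), 0.0)
    result: dict = {}
    for idx in range(len(pairs_i)):
        g1, g2 = str(uniq[pairs_i[idx]]), str(uniq[pairs_j[idx]])
        key = tuple(sorted((g1, g2)))
        result[key] = (
            float(diffs[idx]),
            float(p_adj[idx]),
            bool(p_adj[idx] < alpha),
        )
    return TukeyResult(
        groups=list(uniq),
        means=means,
        ns=counts,
        halfwidths=halfwidths,
        q_crit=float(q_crit),
        alpha=alpha,
        diffs=result,
    )


# --------------------------------------------------------------------------
# correlation & histogram
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson_correlation(x, y) -> CorrelationResult:
    """Sample Pearson correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise StatsError("correlation requires equal-length vectors of n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("zero variance in input vector")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(x))


@dataclass
class HistogramBins:
    edges: np.ndarray
    counts: np.ndarray
    bin_width: float
    values: np.ndarray

    def fraction_below(self, threshold: float) -> float:
        return float(np.mean(self.values < threshold))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lo": self.edges[:-1], "hi": self.edges[1:], "count": self.counts}
        )


def omega_histogram(values, bin_width: float = 0.1) -> HistogramBins:
    """Half-open bins [k*w, (k+1)*w) over nonnegative dN/dS values."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise StatsError("no values to bin")
    if bin_width <= 0:
        raise StatsError("bin width must be positive")
    if np.any(values < 0):
        raise StatsError("negative dN/dS value")
    idx = np.floor(values / bin_width).astype(int)
    counts = np.bincount(idx)
    edges = np.arange(len(counts) + 1) * bin_width
    return HistogramBins(edges=edges, counts=counts, bin_width=bin_width, values=values)


def plot_group_means(tukey: TukeyResult, path, title: str = "") -> None:
    """Means-with-simultaneous-intervals plot in the style of a Tukey chart."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = tukey.to_frame()
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(frame)), 4))
    xs = np.arange(len(frame))
    ax.errorbar(xs, frame["mean"], yerr=tukey.halfwidths, fmt="o", capsize=2)
    ax.set_xticks(xs)
    ax.set_xticklabels(frame["group"], rotation=90, fontsize=6)
    ax.set_ylabel("mean dN/dS")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
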