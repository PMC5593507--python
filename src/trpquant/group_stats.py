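"""Group-level aggregation, non-parametric testing and dose-response fits.

Averaged traces are reported as mean +/- SEM with single cells as the
biological replicates.  Two-group comparisons use the Mann-Whitney test
(unpaired) or the Wilcoxon signed-rank test (paired); multi-group
comparisons use the Kruskal-Wallis test (independent groups) or the
Friedman test (repeated measures), each followed by Dunn's multiple
comparison test with Bonferroni adjustment.  Dose-response curves are fit
with a Hill function with variable slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "MultiComparison",
    "DoseResponseFit",
    "average_trace",
    "percentage",
    "size_histogram",
    "compare_groups",
    "compare_multi",
    "fit_hill",
    "densitometry_normalize",
    "significance_stars",
]


@dataclass
class GroupSummary:
    """Pointwise mean +/- SEM over the cells of one category."""

    name: str
    n_cells: int
    time: np.ndarray
    mean: np.ndarray
    sem: np.ndarray  # NaN when n == 1


def average_trace(traces: list, name: str = "") -> GroupSummary:
    """Pointwise mean and SEM across cells sharing one time grid."""
    if not traces:
        raise ValueError("cannot average an empty group")
    time = traces[0].time
    for tr in traces[1:]:
        if len(tr.time) != len(time) or not np.allclose(tr.time, time):
            raise ValueError("traces must share one time grid")
    data = np.vstack([tr.ratio for tr in traces])
    n = len(traces)
    mean = np.nanmean(data, axis=0)
    if n > 1:
        sem = np.nanstd(data, axis=0, ddof=1) / math.sqrt(n)
    else:
        sem = np.full_like(mean, np.nan)
    return GroupSummary(name=name, n_cells=n, time=time.copy(), mean=mean, sem=sem)


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """100*count/total rounded half-away-from-zero at ``decimals`` places."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    x = 100.0 * count / total
    f = 10.0 ** decimals
    return math.floor(x * f + 0.5) / f


def size_histogram(
    diameters_um,
    bin_width_um: float = 2.0,
    cutoff_um: float = 31.0,
) -> tuple[pd.DataFrame, float]:
    """Cell-size histogram with half-open bins [k*w, (k+1)*w).

    Returns the binned counts and the fraction of cells with diameter
    strictly above ``cutoff_um``.
    """
    d = np.asarray(list(diameters_um), dtype=float)
    if len(d) == 0:
        raise ValueError("no diameters given")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    idx = np.floor(d / bin_width_um).astype(int)
    counts = np.bincount(idx)
    k = np.arange(len(counts))
    table = pd.DataFrame(
        {
            "bin_left_um": k * bin_width_um,
            "bin_right_um": (k + 1) * bin_width_um,
            "count": counts,
        }
    )
    frac_above = float(np.mean(d > cutoff_um))
    return table, frac_above


def significance_stars(p: float) -> str:
    """Star convention: * for 0.01 <= p < 0.05, ** for 0.001 <= p < 0.01,
    *** for p < 0.001, 'ns' otherwise."""
    if not np.isfinite(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    statistic: float
    pvalue: float
    test: str
    stars: str
    flags: list = field(default_factory=list)


EXACT_N_MAX = 25


def compare_groups(
    values_a, values_b, paired: bool = False
) -> GroupComparison:
    """Two-sided Mann-Whitney (unpaired) or Wilcoxon signed-rank (paired).

    Exact p-values are used when both sample sizes are <= 25 and the data
    permit it (no ties for Mann-Whitney, no ties or zero differences for
    Wilcoxon); otherwise the normal approximation with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    flags: list[str] = []
    if len(a) < 3 or len(b) < 3:
        flags.append("small-sample (n < 3)")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        flags.append("degenerate: all values tied")
        return GroupComparison(
            float("nan"), float("nan"), "degenerate", "ns", flags
        )
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal-length samples")
        diff = a - b
        exact = (
            len(a) <= EXACT_N_MAX
            and not np.any(diff == 0)
            and len(np.unique(np.abs(diff))) == len(diff)
        )
        if np.all(diff == 0):
            flags.append("degenerate: all differences zero")
            return GroupComparison(
                float("nan"), float("nan"), "wilcoxon", "ns", flags
            )
        res = stats.wilcoxon(
            a, b, alternative="two-sided",
            method="exact" if exact else "approx",
        )
        test = "wilcoxon"
    else:
        exact = (
            len(a) <= EXACT_N_MAX
            and len(b) <= EXACT_N_MAX
            and len(np.unique(pooled)) == len(pooled)
        )
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided",
            method="exact" if exact else "asymptotic",
        )
        test = "mann-whitney"
    p = float(res.pvalue)
    return GroupComparison(float(res.statistic), p, test, significance_stars(p), flags)


@dataclass
class MultiComparison:
    omnibus_statistic: float
    omnibus_pvalue: float
    test: str
    pairwise: pd.DataFrame  # group_i, group_j, z, pvalue, p_adjusted, stars


def _dunn_independent(groups: list[np.ndarray]) -> pd.DataFrame:
    """Dunn's post-hoc z tests on pooled ranks, Bonferroni-adjusted."""
    k = len(groups)
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(ranks[start : start + n].mean())
        start += n
    # tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            p_adj = min(1.0, p * m)
            rows.append(
                {
                    "group_i": i, "group_j": j, "z": z,
                    "pvalue": p, "p_adjusted": p_adj,
                    "stars": significance_stars(p_adj),
                }
            )
    return pd.DataFrame(rows)


def _dunn_repeated(data: np.ndarray) -> pd.DataFrame:
    """Dunn's post-hoc for Friedman designs on within-block ranks."""
    n_blocks, k = data.shape
    ranks = np.vstack([stats.rankdata(row) for row in data])
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n_blocks))
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            p_adj = min(1.0, p * m)
            rows.append(
                {
                    "group_i": i, "group_j": j, "z": z,
                    "pvalue": p, "p_adjusted": p_adj,
                    "stars": significance_stars(p_adj),
                }
            )
    return pd.DataFrame(rows)


def compare_multi(groups: list, repeated: bool = False) -> MultiComparison:
    """Kruskal-Wallis or Friedman omnibus test with Dunn's post-hoc.

    ``groups`` is a list of >= 3 samples; for repeated measures all groups
    must have equal length (one value per block and treatment).
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups (use compare_groups for 2)")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if repeated:
        lengths = {len(g) for g in arrays}
        if len(lengths) != 1:
            raise ValueError("repeated-measures groups must have equal length")
        stat, p = stats.friedmanchisquare(*arrays)
        pairwise = _dunn_repeated(np.column_stack(arrays))
        test = "friedman+dunn"
    else:
        stat, p = stats.kruskal(*arrays)
        pairwise = _dunn_independent(arrays)
        test = "kruskal-wallis+dunn"
    return MultiComparison(float(stat), float(p), test, pairwise)


@dataclass
class DoseResponseFit:
    """Hill-function fit R(d) = bottom + (top-bottom)/(1 + (IC50/d)^h)."""

    ic50: float
    hill_slope: float
    bottom: float
    top: float
    doses: np.ndarray
    responses: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    converged: bool
    ic50_in_dose_range: bool
    flags: list = field(default_factory=list)

    def predict(self, doses) -> np.ndarray:
        d = np.asarray(doses, dtype=float)
        return _hill(d, self.bottom, self.top, self.ic50, self.hill_slope)


def _hill(d, bottom, top, ic50, h):
    return bottom + (top - bottom) / (1.0 + (ic50 / d) ** h)


def fit_hill(
    doses,
    responses,
    *,
    direction: str = "increasing",
    bottom_bounds: tuple[float, float] = (0.0, 100.0),
    top_bounds: tuple[float, float] = (0.0, 100.0),
    slope_bounds: tuple[float, float] = (0.05, 10.0),
) -> DoseResponseFit:
    """Least-squares Hill fit with variable slope.

    ``direction`` states the expected monotonic trend of the response with
    dose ('increasing' for percent inhibition growing with inhibitor
    concentration); a contradicting trend in the data is flagged, not
    fitted away.  Initialization uses the data quartiles; bottom and top
    are bounded for percent-scale responses by default.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(d) != len(r):
        raise ValueError("doses and responses must have equal length")
    if len(np.unique(d)) < 4:
        raise ValueError("need at least 4 distinct doses for a Hill fit")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")

    flags: list[str] = []
    rho = stats.spearmanr(d, r).statistic
    if direction == "increasing" and rho < 0:
        flags.append("direction-mismatch: responses decrease with dose")
    elif direction == "decreasing" and rho > 0:
        flags.append("direction-mismatch: responses increase with dose")

    lo = max(bottom_bounds[0], min(r.min(), bottom_bounds[1]))
    hi = min(top_bounds[1], max(r.max(), top_bounds[0]))
    mid = 0.5 * (lo + hi)
    above = d[r >= mid]
    ic50_init = float(above.min()) if len(above) else float(np.median(d))
    ic50_init = float(np.clip(ic50_init, d.min(), d.max()))
    p0 = [lo, hi, ic50_init, 1.0]
    bounds = (
        [bottom_bounds[0], top_bounds[0], d.min() / 1e3, slope_bounds[0]],
        [bottom_bounds[1], top_bounds[1], d.max() * 1e3, slope_bounds[1]],
    )
    converged = True
    try:
        popt, _ = optimize.curve_fit(
            _hill, d, r, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError):
        converged = False
        flags.append("fit did not converge; reporting initial estimates")
        popt = p0
    bottom, top, ic50, h = (float(x) for x in popt)
    fitted = _hill(d, bottom, top, ic50, h)
    in_range = bool(d.min() <= ic50 <= d.max())
    if not in_range:
        flags.append("IC50 outside tested dose range")
    return DoseResponseFit(
        ic50=ic50, hill_slope=h, bottom=bottom, top=top,
        doses=d, responses=r, fitted=fitted, residuals=r - fitted,
        converged=converged, ic50_in_dose_range=in_range, flags=flags,
    )


def densitometry_normalize(ip_density: float, lysate_density: float) -> float:
    """Normalize an immunoprecipitate band density to the total-lysate band."""
    if lysate_density <= 0:
        raise ValueError("lysate density must be positive")
    return ip_density / lysate_density
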