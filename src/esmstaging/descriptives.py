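"""Distributional characterization of ESM mental-state data.

Everything here pools *measurements* within severity subgroups (the
subgroup tables of the motivating literature report N in measurements,
not persons): per-subgroup descriptives with floor/ceiling percentages,
Pearson/Spearman correlation tables, the floor-proportion-by-severity
profile, boxplot-style five-number summaries, and the exhaustive search
for severity cutpoints that would equalize subgroup variances (which
fails, by construction, on floor-inflated skewed states).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from esmstaging.synthetic_esm import STATES, EsmDataset

FLOOR_TOL = 1e-9
VARIABLES = ("scl", "na", "pa", "par")

__all__ = [
    "DescriptiveSummary",
    "SeverityGrouping",
    "CorrelationTable",
    "CutpointSearchResult",
    "GroupingError",
    "summarize",
    "assign_quartile_groups",
    "grouping_from_cutpoints",
    "correlation_table",
    "search_equal_variance_cutpoints",
    "floor_profile",
    "subgroup_table",
    "boxplot_summaries",
]


class GroupingError(ValueError):
    """Severity grouping could not produce the requested subgroups."""


@dataclass(frozen=True)
class DescriptiveSummary:
    n_measurements: int
    mean: float
    variance: float
    skewness: float  # NaN when n < 3
    floor_pct: float
    ceiling_pct: float


@dataclass(frozen=True)
class SeverityGrouping:
    """Ordered severity subgroups from cutpoints on the person-level score."""

    cutpoints: tuple[float, ...]
    group_of_person: pd.Series  # person_id -> 1..k
    group_sizes: tuple[int, ...]

    @property
    def n_groups(self) -> int:
        return len(self.cutpoints) + 1


@dataclass(frozen=True)
class CorrelationTable:
    variables: tuple[str, ...]
    pearson: pd.DataFrame
    spearman: pd.DataFrame
    n_pairs: pd.DataFrame


@dataclass(frozen=True)
class CutpointSearchResult:
    best_cutpoints: tuple[float, float, float]
    subgroup_variances: tuple[float, ...]
    variance_ratio: float
    achieved: bool
    tolerance: float


def summarize(scores, scale_min: float, scale_max: float) -> DescriptiveSummary:
    """Descriptive summary of pooled scores on a bounded scale.

    Variance uses the n-1 denominator; skewness is the adjusted
    Fisher-Pearson standardized third moment (undefined below n=3);
    floor/ceiling are the percentages exactly at the scale bounds
    (within a 1e-9 tolerance absorbing float representation of mean
    item scores).
    """
    x = np.asarray(pd.Series(scores).dropna(), dtype=float)
    if x.size == 0:
        raise ValueError("scores must be non-empty")
    if not scale_min < scale_max:
        raise ValueError("scale_min must be below scale_max")
    n = x.size
    skew = float(stats.skew(x, bias=False)) if n >= 3 and np.ptp(x) > 0 else (
        0.0 if n >= 3 else np.nan
    )
    if n < 3:
        skew = np.nan
    return DescriptiveSummary(
        n_measurements=n,
        mean=float(np.mean(x)),
        variance=float(np.var(x, ddof=1)) if n > 1 else 0.0,
        skewness=skew,
        floor_pct=float(np.mean(np.abs(x - scale_min) <= FLOOR_TOL) * 100.0),
        ceiling_pct=float(np.mean(np.abs(x - scale_max) <= FLOOR_TOL) * 100.0),
    )


def grouping_from_cutpoints(person_severity: pd.Series, cutpoints) -> SeverityGrouping:
    """Assign persons to ordered groups: group g iff score in (c_{g-1}, c_g].

    The upper boundary is inclusive, so ties at a cutpoint fall in the
    lower group.  Raises GroupingError if any group is empty.
    """
    cuts = tuple(float(c) for c in cutpoints)
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise GroupingError("cutpoints must be strictly increasing")
    edges = [-np.inf, *cuts, np.inf]
    groups = pd.cut(person_severity, edges, labels=False, right=True) + 1
    sizes = tuple(int((groups == g).sum()) for g in range(1, len(cuts) + 2))
    if any(s == 0 for s in sizes):
        raise GroupingError(f"empty severity subgroup for cutpoints {cuts}")
    return SeverityGrouping(
        cutpoints=cuts,
        group_of_person=groups.astype(int),
        group_sizes=sizes,
    )


def assign_quartile_groups(person_severity: pd.Series) -> SeverityGrouping:
    """Four severity subgroups at the 25th/50th/75th percentiles.

    Mirrors the quartile subgrouping of the person-level severity
    score.  Massive ties that leave a subgroup empty raise
    GroupingError.
    """
    sev = pd.Series(person_severity).dropna()
    if sev.size < 4:
        raise GroupingError("need at least 4 persons for quartile groups")
    cuts = sev.quantile([0.25, 0.5, 0.75]).to_numpy()
    if len(np.unique(cuts)) < 3:
        raise GroupingError("severity ties too heavy for 4 quartile groups")
    try:
        return grouping_from_cutpoints(sev, cuts)
    except GroupingError as err:
        raise GroupingError(f"quartile grouping degenerate: {err}") from err


def correlation_table(dataset: EsmDataset) -> CorrelationTable:
    """Measurement-level Pearson and Spearman correlations of SCL/NA/PA/PAR.

    Pairwise-complete; Spearman uses midranks for ties.  A constant
    variable's correlations come out NaN.
    """
    frame = dataset.frame[list(VARIABLES)]
    pearson = frame.corr(method="pearson", min_periods=3)
    spearman = frame.corr(method="spearman", min_periods=3)
    notna = frame.notna().astype(int)
    n_pairs = notna.T @ notna
    for tab in (pearson, spearman):
        np.fill_diagonal(tab.values, 1.0)
    const = [v for v in VARIABLES if frame[v].nunique(dropna=True) <= 1]
    for v in const:
        pearson.loc[v, :] = pearson.loc[:, v] = np.nan
        spearman.loc[v, :] = spearman.loc[:, v] = np.nan
    return CorrelationTable(
        variables=VARIABLES, pearson=pearson, spearman=spearman, n_pairs=n_pairs
    )


def _person_level_prefixes(frame: pd.DataFrame, state: str):
    """Per-person (n, sum, sumsq) of a state's scores, persons sorted by SCL."""
    per = (
        frame.dropna(subset=[state])
        .groupby("person_id")[state]
        .agg(n="count", s="sum", ss=lambda v: float(np.sum(np.square(v))))
    )
    sev = frame.groupby("person_id")["scl"].first()
    per = per.join(sev).sort_values("scl", kind="mergesort")
    return per


def search_equal_variance_cutpoints(
    dataset: EsmDataset,
    state: str,
    tolerance: float = 1.5,
    min_group_persons: int = 10,
    max_grid: int | None = 60,
) -> CutpointSearchResult:
    """Exhaustively search severity cutpoint triples for equal variances.

    Scans ordered triples of candidate cutpoints on the person-level
    severity score (all 4 groups at least ``min_group_persons`` persons)
    and returns the triple minimizing the max/min ratio of the
    measurement-level variance of ``state`` across subgroups.
    ``achieved`` reports whether the best ratio is within ``tolerance``.
    With ``max_grid`` set, the candidate set is the distinct person
    scores coarsened to that many quantile levels; ``None`` uses every
    distinct score.
    """
    if state not in STATES:
        raise ValueError(f"state must be one of {STATES}")
    per = _person_level_prefixes(dataset.frame, state)
    sev_vals = per["scl"].to_numpy()
    distinct = np.unique(sev_vals)
    if distinct.size < 4:
        raise GroupingError("fewer than 4 distinct severity values")
    if max_grid is not None and distinct.size > max_grid:
        qs = np.quantile(distinct, np.linspace(0, 1, max_grid + 2)[1:-1])
        candidates = np.unique(qs)
    else:
        candidates = distinct[:-1]  # a cutpoint at the max leaves group 4 empty

    # prefix sums over persons sorted by severity -> O(1) pooled variance
    # of any contiguous severity segment
    cn = np.concatenate([[0], np.cumsum(per["n"].to_numpy())])
    cs = np.concatenate([[0.0], np.cumsum(per["s"].to_numpy())])
    css = np.concatenate([[0.0], np.cumsum(per["ss"].to_numpy())])
    cp = np.concatenate([[0], np.cumsum(np.ones(len(per), dtype=int))])
    # index of first person with severity > c, for each candidate cutpoint
    splits = np.searchsorted(sev_vals, np.asarray(candidates), side="right")

    def segment_var(i, j):
        n = cn[j] - cn[i]
        if n < 2:
            return np.nan
        s = cs[j] - cs[i]
        ss = css[j] - css[i]
        return (ss - s * s / n) / (n - 1)

    best = None
    n_persons_total = len(per)
    for ia, ib, ic in combinations(range(len(splits)), 3):
        bounds = (0, splits[ia], splits[ib], splits[ic], n_persons_total)
        if any(cp[bounds[k + 1]] - cp[bounds[k]] < min_group_persons for k in range(4)):
            continue
        variances = [segment_var(bounds[k], bounds[k + 1]) for k in range(4)]
        if any(not np.isfinite(v) or v <= 0 for v in variances):
            continue
        ratio = max(variances) / min(variances)
        if best is None or ratio < best[0]:
            best = (ratio, (candidates[ia], candidates[ib], candidates[ic]), variances)
    if best is None:
        raise GroupingError("no admissible cutpoint triple under the constraints")
    ratio, cuts, variances = best
    return CutpointSearchResult(
        best_cutpoints=tuple(float(c) for c in cuts),
        subgroup_variances=tuple(float(v) for v in variances),
        variance_ratio=float(ratio),
        achieved=bool(ratio <= tolerance),
        tolerance=float(tolerance),
    )


def floor_profile(dataset: EsmDataset, state: str, bin_width: float = 0.1) -> pd.DataFrame:
    """Floor proportion of a state's scores by severity (SCL) bin.

    Returns a frame with bin_left, bin_right, n_measurements and
    floor_prop; counts over non-empty bins sum to the state's total
    non-missing measurement count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    frame = dataset.frame.dropna(subset=[state])
    if frame.empty:
        return pd.DataFrame(columns=["bin_left", "bin_right", "n_measurements", "floor_prop"])
    scl = frame["scl"].to_numpy()
    lo = np.floor(scl.min() / bin_width) * bin_width
    hi = scl.max()
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width + FLOOR_TOL)))
    idx = np.clip(((scl - lo) / bin_width).astype(int), 0, n_bins - 1)
    at_floor = np.abs(frame[state].to_numpy() - 1.0) <= FLOOR_TOL
    n = np.bincount(idx, minlength=n_bins)
    n_floor = np.bincount(idx, weights=at_floor.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        prop = np.where(n > 0, n_floor / np.maximum(n, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_left": lo + bin_width * np.arange(n_bins),
            "bin_right": lo + bin_width * (np.arange(n_bins) + 1),
            "n_measurements": n,
            "floor_prop": prop,
        }
    )


def subgroup_table(dataset: EsmDataset, grouping: SeverityGrouping | None = None) -> pd.DataFrame:
    """Subgroup descriptives of SCL/NA/PA/PAR (total plus per severity group).

    Rows are (block, parameter); columns the four variables.  SCL is on
    its ~1-5 scale, states on 1-7.
    """
    frame = dataset.frame
    if grouping is None:
        grouping = assign_quartile_groups(dataset.person_severity())
    scales = {"scl": (1.0, 5.0), "na": (1.0, 7.0), "pa": (1.0, 7.0), "par": (1.0, 7.0)}
    groups = frame["person_id"].map(grouping.group_of_person)
    blocks: dict[str, pd.DataFrame] = {}
    for label, mask in [("total", np.ones(len(frame), dtype=bool))] + [
        (f"severity_{g}", (groups == g).to_numpy()) for g in range(1, grouping.n_groups + 1)
    ]:
        cols = {}
        for var in VARIABLES:
            x = frame.loc[mask, var]
            if x.dropna().empty:
                cols[var] = dict.fromkeys(
                    ["n_measurements", "mean", "variance", "skewness", "floor_pct", "ceiling_pct"],
                    np.nan,
                )
                continue
            s = summarize(x, *scales[var])
            cols[var] = {
                "n_measurements": s.n_measurements,
                "mean": s.mean,
                "variance": s.variance,
                "skewness": s.skewness,
                "floor_pct": s.floor_pct,
                "ceiling_pct": s.ceiling_pct,
            }
        blocks[label] = pd.DataFrame(cols)
    out = pd.concat(blocks, names=["block", "parameter"])
    return out


def boxplot_summaries(dataset: EsmDataset, state: str, grouping: SeverityGrouping | None = None) -> pd.DataFrame:
    """Five-number summaries with 1.5*IQR whiskers per severity subgroup.

    A tabular stand-in for per-subgroup boxplots: median, quartiles, and
    whiskers extending to the most extreme observations within 1.5 IQR
    of the box.
    """
    if grouping is None:
        grouping = assign_quartile_groups(dataset.person_severity())
    frame = dataset.frame.dropna(subset=[state])
    groups = frame["person_id"].map(grouping.group_of_person)
    rows = []
    for g in range(1, grouping.n_groups + 1):
        x = frame.loc[groups == g, state].to_numpy()
        if x.size == 0:
            continue
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        lo_w = x[x >= q1 - 1.5 * iqr].min()
        hi_w = x[x <= q3 + 1.5 * iqr].max()
        rows.append(
            {
                "group": g,
                "n": x.size,
                "lower_whisker": lo_w,
                "q1": q1,
                "median": med,
                "q3": q3,
                "upper_whisker": hi_w,
                "n_outliers": int(np.sum((x < lo_w) | (x > hi_w))),
            }
        )
    return pd.DataFrame(rows)
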