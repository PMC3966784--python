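"""Statistical summaries of classified dive records.

Dive depths/durations, surfacing-bout durations and inter-deep-dive
intervals are right-skewed, so each individual is summarized by medians
with ranges, and the group is characterized by the unweighted mean and
SD of the per-individual values — individuals, never pooled events, are
the unit of replication.  The group SD uses the n denominator
(descriptive of the tagged sample itself): that convention reproduces
the published group SDs (e.g. 137.8 m for deep-dive depth) from the
printed per-individual medians, where the n-1 form does not (147.4 m).

Also provides the hypothesis tests used on these summaries: Mann-Whitney
U (sensor-mode comparison of bout durations), Kruskal-Wallis with
Dunn-style pairwise Z comparisons (bout-type comparison), and paired
t-tests on per-whale day/night values (diel contrasts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .behavior_log import BehaviorLog
from .diel_solar import DAY, NIGHT, DielAssignment
from .dive_classification import DEEP, SHALLOW, ClassifiedDive
from .sequence_analysis import DeepDiveInterval, TypedSurfacing, UNTYPED

#: Variables carried in an IndividualSummary.
SUMMARY_VARIABLES = (
    "deep_depth_m",
    "deep_duration_min",
    "shallow_depth_m",
    "shallow_duration_min",
    "surfacing_duration_min",
    "iddi_duration_min",
    "iddi_n_shallow",
)


@dataclass
class VariableSummary:
    median: float
    min: float
    max: float
    n: int


@dataclass
class IndividualSummary:
    whale_id: str
    variables: dict[str, VariableSummary] = field(default_factory=dict)
    deep_dive_rate: float = float("nan")


@dataclass
class GroupSummary:
    variable: str
    group_mean: float
    group_sd: float
    n_individuals: int
    pooled_n: int


@dataclass
class DielBudget:
    """Per-whale time budget split by diel class.

    ``fractions[diel][mode]`` is the share of classified time the whale
    spent in that behavior mode (deep dive / shallow dive / surfacing)
    within the diel class; shares sum to 1 per class.
    """

    whale_id: str
    fractions: dict[str, dict[str, float]]
    deep_dives_per_hour: dict[str, float]
    hours: dict[str, float]


def _summary(values: Sequence[float]) -> VariableSummary:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return VariableSummary(float("nan"), float("nan"), float("nan"), 0)
    return VariableSummary(
        float(np.median(arr)), float(arr.min()), float(arr.max()), int(arr.size)
    )


def individual_summary(
    whale_id: str,
    classified: Sequence[ClassifiedDive],
    typed: Sequence[TypedSurfacing],
    iddis: Sequence[DeepDiveInterval],
    total_bl_hours: float,
) -> IndividualSummary:
    """Medians/ranges/counts of the core dive-cycle variables for one
    whale, plus its deep-dive rate (deep dives / BL hours)."""
    deep = [c.event for c in classified if c.dive_class == DEEP]
    shallow = [c.event for c in classified if c.dive_class == SHALLOW]
    out = IndividualSummary(whale_id)
    out.variables["deep_depth_m"] = _summary([e.max_depth for e in deep])
    out.variables["deep_duration_min"] = _summary([e.duration_min for e in deep])
    out.variables["shallow_depth_m"] = _summary([e.max_depth for e in shallow])
    out.variables["shallow_duration_min"] = _summary([e.duration_min for e in shallow])
    out.variables["surfacing_duration_min"] = _summary(
        [t.event.duration_min for t in typed]
    )
    out.variables["iddi_duration_min"] = _summary([i.duration_min for i in iddis])
    out.variables["iddi_n_shallow"] = _summary([i.n_shallow for i in iddis])
    out.deep_dive_rate = len(deep) / total_bl_hours if total_bl_hours > 0 else float("nan")
    return out


def group_summary(
    summaries: Sequence[IndividualSummary], variable: str
) -> GroupSummary:
    """Unweighted mean and SD (n denominator) of per-individual medians
    (or of per-individual rates for ``deep_dive_rate``)."""
    if len(summaries) < 2:
        raise ValueError("group summary needs at least 2 individuals")
    if variable == "deep_dive_rate":
        vals = [s.deep_dive_rate for s in summaries]
        pooled = len(summaries)
    else:
        vals = [s.variables[variable].median for s in summaries]
        pooled = int(sum(s.variables[variable].n for s in summaries))
    return GroupSummary(
        variable=variable,
        group_mean=float(np.mean(vals)),
        group_sd=float(np.std(vals, ddof=0)),
        n_individuals=len(summaries),
        pooled_n=pooled,
    )


def group_mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Mean and SD (n denominator) of a set of per-individual values."""
    arr = np.asarray(list(values), dtype=float)
    return float(arr.mean()), float(arr.std(ddof=0))


# ---------------------------------------------------------------------------
# bout-type comparison (Kruskal-Wallis + Dunn pairwise Z)


@dataclass
class PairwiseZ:
    group_a: str
    group_b: str
    z: float
    p_adjusted: float
    significant: bool


@dataclass
class BoutTypeComparison:
    h_statistic: float
    p_value: float
    group_medians: dict[str, float]
    group_ranges: dict[str, tuple[float, float]]
    group_n: dict[str, int]
    pairwise: list[PairwiseZ]
    alpha: float


def _dunn_pairwise(
    groups: Mapping[str, np.ndarray], alpha: float
) -> list[PairwiseZ]:
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_ranks = {}
    start = 0
    for g in names:
        k = groups[g].size
        mean_ranks[g] = ranks[start : start + k].mean()
        start += k
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    m = len(names) * (len(names) - 1) // 2  # Bonferroni family
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = np.sqrt(max(var_base, 0.0) * (1.0 / groups[a].size + 1.0 / groups[b].size))
            # fully tied pooled sample -> no evidence of any difference
            z = abs(mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = min(1.0, 2.0 * sps.norm.sf(z) * m)
            out.append(PairwiseZ(a, b, float(z), float(p), bool(p < alpha)))
    return out


def bout_type_comparison(
    typed: Sequence[TypedSurfacing], alpha: float = 0.05
) -> BoutTypeComparison:
    """Compare surfacing-bout durations across FS/IS/TS/SS types.

    Intended for wet/dry-sensor individuals only (depth-threshold tags
    inflate bout durations); pools bouts across whales by type.  Types
    with no bouts are excluded with a warning.
    """
    groups: dict[str, np.ndarray] = {}
    for btype in ("FS", "IS", "TS", "SS"):
        vals = np.array(
            [t.event.duration_min for t in typed if t.bout_type == btype], dtype=float
        )
        if vals.size == 0:
            warnings.warn(f"bout type {btype} has no observations; excluded")
            continue
        groups[btype] = vals
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty bout types")
    samples = list(groups.values())
    if all(np.all(s == samples[0][0]) for s in samples):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples)
    return BoutTypeComparison(
        h_statistic=float(h),
        p_value=float(p),
        group_medians={g: float(np.median(v)) for g, v in groups.items()},
        group_ranges={g: (float(v.min()), float(v.max())) for g, v in groups.items()},
        group_n={g: int(v.size) for g, v in groups.items()},
        pairwise=_dunn_pairwise(groups, alpha),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# sensor-mode comparison (Mann-Whitney U)


@dataclass
class MannWhitneyReport:
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    method: str


def sensor_mode_comparison(
    durations_a: Sequence[float],
    durations_b: Sequence[float],
    method: str = "auto",
) -> MannWhitneyReport:
    """Two-sided Mann-Whitney U comparing bout durations between sensor
    modes.  ``method='auto'`` uses the exact null distribution at small
    n without ties, else the tie-corrected normal approximation."""
    a = np.asarray(list(durations_a), dtype=float)
    b = np.asarray(list(durations_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    used = method
    if method == "auto":
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        used = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    return MannWhitneyReport(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=int(a.size),
        n_b=int(b.size),
        method=used,
    )


# ---------------------------------------------------------------------------
# diel contrasts (paired t-tests on per-whale day/night values)

#: Alternative hypotheses per variable, following the reported diel
#: findings: deep dives are deeper at night, longer during the day;
#: time-budget proportions are tested two-sided.
DEFAULT_TAILS = {
    "deep_depth_m": "night_greater",
    "deep_duration_min": "day_greater",
}

_ALT_MAP = {  # alternative for ttest_rel on (day - night)
    "two-sided": "two-sided",
    "day_greater": "greater",
    "night_greater": "less",
}


@dataclass
class PairedTestResult:
    variable: str
    t_statistic: float
    df: int
    p_value: float
    day_mean: float
    night_mean: float
    alternative: str


def paired_diel_test(
    day: Sequence[float],
    night: Sequence[float],
    variable: str = "",
    alternative: str = "two-sided",
) -> PairedTestResult:
    """Paired t-test of per-whale day vs night values.

    ``alternative``: 'two-sided', 'day_greater' or 'night_greater',
    applied to the mean of (day - night) differences.
    """
    d = np.asarray(list(day), dtype=float)
    n = np.asarray(list(night), dtype=float)
    if d.size != n.size or d.size < 2:
        raise ValueError("need >= 2 paired day/night values")
    diffs = d - n
    if np.all(diffs == diffs[0]) and np.std(diffs) == 0 and diffs[0] != 0:
        raise ValueError("zero-variance differences")
    if alternative not in _ALT_MAP:
        raise ValueError(f"unknown alternative {alternative!r}")
    if np.all(diffs == 0):
        t, p = 0.0, 1.0 if _ALT_MAP[alternative] == "two-sided" else 0.5
    else:
        res = sps.ttest_rel(d, n, alternative=_ALT_MAP[alternative])
        t, p = float(res.statistic), float(res.pvalue)
    return PairedTestResult(
        variable=variable,
        t_statistic=t,
        df=int(d.size - 1),
        p_value=p,
        day_mean=float(d.mean()),
        night_mean=float(n.mean()),
        alternative=alternative,
    )


def diel_contrasts(
    per_whale: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    tails: Mapping[str, str] | None = None,
) -> dict[str, PairedTestResult]:
    """Run the paired day/night tests for a set of variables.

    ``per_whale`` maps variable name -> (day values, night values),
    aligned by whale.  Tails default to :data:`DEFAULT_TAILS` (one-tailed
    for deep-dive depth and duration, two-sided otherwise).
    """
    tails = dict(DEFAULT_TAILS, **(tails or {}))
    return {
        var: paired_diel_test(day, night, var, tails.get(var, "two-sided"))
        for var, (day, night) in per_whale.items()
    }


# ---------------------------------------------------------------------------
# diel time budgets


def compute_diel_budget(
    log: BehaviorLog,
    classified: Sequence[ClassifiedDive],
    assignments: Sequence[DielAssignment],
) -> DielBudget:
    """Split a whale's classified time between behavior modes by diel
    class.  Each event contributes its full duration to the diel class
    of its start time."""
    diel_of = {id(a.event): a.diel_class for a in assignments}
    class_of = {id(c.event): c.dive_class for c in classified}
    seconds = {d: {"deep": 0.0, "shallow": 0.0, "surfacing": 0.0} for d in (DAY, NIGHT)}
    deep_counts = {DAY: 0, NIGHT: 0}
    for e in log.events:
        diel = diel_of.get(id(e))
        if diel is None:
            continue
        if e.kind == "surfacing":
            mode = "surfacing"
        else:
            cls = class_of.get(id(e))
            if cls is None:
                continue
            mode = "deep" if cls == DEEP else "shallow"
            if cls == DEEP:
                deep_counts[diel] += 1
        seconds[diel][mode] += e.duration_s
    fractions: dict[str, dict[str, float]] = {}
    rates: dict[str, float] = {}
    hours: dict[str, float] = {}
    for diel in (DAY, NIGHT):
        total = sum(seconds[diel].values())
        hours[diel] = total / 3600.0
        if total > 0:
            fractions[diel] = {m: s / total for m, s in seconds[diel].items()}
            rates[diel] = deep_counts[diel] / (total / 3600.0)
        else:
            fractions[diel] = {m: float("nan") for m in seconds[diel]}
            rates[diel] = float("nan")
    return DielBudget(
        whale_id=log.whale_id,
        fractions=fractions,
        deep_dives_per_hour=rates,
        hours=hours,
    )
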