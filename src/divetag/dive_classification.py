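"""Deep/shallow dive classification by per-individual 2-means clustering.

Beaked-whale dive records beyond 50 m separate into two behavioral
classes: long, deep dives (presumed foraging) and shorter, shallower
intervening dives.  Each individual's dives are partitioned by K-means
(k = 2) on maximum depth and duration, z-standardized per individual so
neither feature dominates.  The cluster whose mean raw depth is greater
is labeled ``deep``.

Because a small fraction of dives is genuinely ambiguous, dives in the
tails of their assigned class (deep dives below the class 5th percentile
of depth or duration; shallow dives above the 95th) are flagged as
borderline, and a contextual rule — a surrogate for visual verification
against the surrounding dive trace — may reassign a flagged dive when
the local sequence makes its K-means label implausible (e.g. several
consecutive "deep" dives far shallower than their neighbors).  Flagged
dives adjacent to a record gap always keep their original label.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from datetime import timedelta
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.cluster import KMeans

from .behavior_log import BehaviorLog, BehaviorLogEvent

DEEP = "deep"
SHALLOW = "shallow"

#: Default tail probability for borderline flagging.
DEFAULT_FLAG_TAIL = 0.05
#: Default relative-depth factor for contextual reassignment.
DEFAULT_RHO = 0.6
#: Default context window (hours) for the local reference median.
DEFAULT_WINDOW_H = 24.0
#: Minimum run of consecutive same-labeled dives for reassignment.
MIN_DEEP_RUN = 3


@dataclass
class ClassifiedDive:
    event: BehaviorLogEvent
    dive_class: str
    borderline: bool = False
    reclassified: bool = False
    original_class: str = ""

    def __post_init__(self) -> None:
        if not self.original_class:
            self.original_class = self.dive_class


@dataclass
class ClassificationReport:
    whale_id: str
    n_deep: int
    n_shallow: int
    n_flagged: int
    n_reclassified: int
    #: (depth m, duration min) cluster centers in original units, deep first.
    cluster_centers: dict[str, tuple[float, float]]
    #: One-way ANOVA p-value for depth by assigned class.
    anova_p: float


class ClassificationError(ValueError):
    pass


def _feature_matrix(dives: Sequence[BehaviorLogEvent]) -> np.ndarray:
    return np.array([[d.max_depth, d.duration_min] for d in dives], dtype=float)


def kmeans_two_class(
    dives: Sequence[BehaviorLogEvent],
    seed: int = 0,
    n_init: int = 50,
) -> tuple[list[ClassifiedDive], ClassificationReport]:
    """Partition one individual's dives into deep and shallow classes.

    Features (max depth, duration) are z-standardized per individual
    before clustering; labels are assigned by mean raw depth so the
    arbitrary cluster indices never leak into the result.  Deterministic
    for a given seed.
    """
    dives = list(dives)
    if len(dives) < 4:
        raise ClassificationError("insufficient dives for clustering")
    X = _feature_matrix(dives)
    if not np.all(np.isfinite(X)):
        raise ClassificationError("non-finite depth or duration")
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ClassificationError("degenerate feature matrix")
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - X.mean(axis=0)) / sd

    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z)
    if len(set(labels)) < 2:
        raise ClassificationError("degenerate feature matrix")

    # depth-ordered relabeling: cluster with greater mean raw depth is deep
    mean_depth = [X[labels == k, 0].mean() for k in (0, 1)]
    deep_idx = int(np.argmax(mean_depth))
    classified = [
        ClassifiedDive(d, DEEP if lab == deep_idx else SHALLOW)
        for d, lab in zip(dives, labels)
    ]

    centers = {}
    for name, k in ((DEEP, deep_idx), (SHALLOW, 1 - deep_idx)):
        sub = X[labels == k]
        centers[name] = (float(sub[:, 0].mean()), float(sub[:, 1].mean()))

    deep_depths = X[labels == deep_idx, 0]
    shal_depths = X[labels != deep_idx, 0]
    if len(deep_depths) > 1 and len(shal_depths) > 1 and (
        deep_depths.std() > 0 or shal_depths.std() > 0
    ):
        anova_p = float(sps.f_oneway(deep_depths, shal_depths).pvalue)
    else:
        anova_p = 0.0  # complete separation with no within-class variance

    report = ClassificationReport(
        whale_id=dives[0].whale_id,
        n_deep=int(np.sum(labels == deep_idx)),
        n_shallow=int(np.sum(labels != deep_idx)),
        n_flagged=0,
        n_reclassified=0,
        cluster_centers=centers,
        anova_p=anova_p,
    )
    return classified, report


def brute_force_two_class(dives: Sequence[BehaviorLogEvent]) -> list[str]:
    """Exact 2-partition by exhaustive within-cluster sum-of-squares
    minimization on the z-scored features.  Exponential in n; intended
    as an oracle for small inputs (n <= ~15)."""
    dives = list(dives)
    n = len(dives)
    if n < 4:
        raise ClassificationError("insufficient dives for clustering")
    X = _feature_matrix(dives)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - X.mean(axis=0)) / sd
    best, best_mask = np.inf, None
    for mask in range(1, 2**n - 1):
        sel = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        a, b = Z[sel], Z[~sel]
        wcss = ((a - a.mean(axis=0)) ** 2).sum() + ((b - b.mean(axis=0)) ** 2).sum()
        if wcss < best - 1e-12:
            best, best_mask = wcss, sel
    deep_is_sel = X[best_mask, 0].mean() > X[~best_mask, 0].mean()
    return [
        DEEP if (s == deep_is_sel) else SHALLOW for s in best_mask
    ]


def flag_borderline(
    classified: Sequence[ClassifiedDive], tail: float = DEFAULT_FLAG_TAIL
) -> list[ClassifiedDive]:
    """Flag class-tail dives as borderline, in place.

    Deep dives strictly below the deep-class ``tail`` percentile of depth
    or duration, and shallow dives strictly above the shallow-class
    ``1 - tail`` percentile of depth or duration, are flagged.
    Percentiles use linear interpolation and are computed per class
    within the individual.
    """
    classified = list(classified)
    for cls, upper in ((DEEP, False), (SHALLOW, True)):
        members = [c for c in classified if c.dive_class == cls]
        if not members:
            continue
        depths = np.array([c.event.max_depth for c in members])
        durs = np.array([c.event.duration_min for c in members])
        q = 100 * (1 - tail) if upper else 100 * tail
        d_cut = np.percentile(depths, q)
        t_cut = np.percentile(durs, q)
        for c in members:
            if upper:
                c.borderline = c.event.max_depth > d_cut or c.event.duration_min > t_cut
            else:
                c.borderline = c.event.max_depth < d_cut or c.event.duration_min < t_cut
    return classified


def _gap_adjacent(event: BehaviorLogEvent, log: BehaviorLog) -> bool:
    """True when a message-loss gap (or the record edge) directly abuts
    the event, so the surrounding pattern cannot be judged."""
    if not log.events:
        return True
    if event.start == log.events[0].start or event.end == log.events[-1].end:
        return True
    for g0, g1 in log.gaps:
        if event.end == g0 or event.start == g1:
            return True
    return False


def _consecutive_dive_runs(log: BehaviorLog, class_of: dict[int, str]) -> list[list[int]]:
    """Runs of consecutive dives (ids) sharing a class label.

    Dives are consecutive when no gap falls between them; intervening
    surfacing bouts do not break a run.
    """
    dive_ids = [id(e) for e in log.events if e.kind == "dive" and id(e) in class_of]
    gap_bounds = set()
    # index dives by position; a gap between dive i and i+1 breaks the run
    dives = [e for e in log.events if e.kind == "dive" and id(e) in class_of]
    for i, (a, b) in enumerate(zip(dives, dives[1:])):
        for g0, g1 in log.gaps:
            if a.end <= g0 and g1 <= b.start:
                gap_bounds.add(i)
    runs: list[list[int]] = []
    current: list[int] = []
    for i, did in enumerate(dive_ids):
        if current and (
            class_of[did] != class_of[current[-1]] or (i - 1) in gap_bounds
        ):
            runs.append(current)
            current = []
        current.append(did)
    if current:
        runs.append(current)
    return runs


def contextual_reclassify(
    log: BehaviorLog,
    classified: Sequence[ClassifiedDive],
    rho: float = DEFAULT_RHO,
    window_h: float = DEFAULT_WINDOW_H,
) -> list[ClassifiedDive]:
    """Reassign borderline dives whose K-means label is contextually
    implausible.

    A flagged *deep* dive is reassigned to shallow iff (i) no gap or
    record edge abuts it, (ii) it sits in a run of >= 3 consecutive
    deep-labeled dives, and (iii) its depth is below ``rho`` times the
    median depth of unflagged deep dives within ``window_h`` hours.
    Symmetrically, a flagged *shallow* dive is reassigned to deep iff it
    is a lone shallow dive bracketed by deep dives across surfacing
    bouts only and its depth exceeds ``1/rho`` times the local unflagged
    shallow median.  Dives already carrying a reassignment are never
    touched again, so the operation is idempotent.
    """
    classified = list(classified)
    class_of = {id(c.event): c.dive_class for c in classified}
    by_event = {id(c.event): c for c in classified}

    def local_median(cls: str, around: BehaviorLogEvent) -> float | None:
        lo = around.start - timedelta(hours=window_h)
        hi = around.start + timedelta(hours=window_h)
        vals = [
            c.event.max_depth
            for c in classified
            if c.dive_class == cls
            and not c.borderline
            and lo <= c.event.start <= hi
        ]
        return statistics.median(vals) if vals else None

    runs = _consecutive_dive_runs(log, class_of)
    run_of = {did: run for run in runs for did in run}

    to_flip: list[ClassifiedDive] = []
    for c in classified:
        if not c.borderline or c.reclassified:
            continue
        if _gap_adjacent(c.event, log):
            continue
        if c.dive_class == DEEP:
            run = run_of.get(id(c.event), [])
            if len(run) < MIN_DEEP_RUN:
                continue
            ref = local_median(DEEP, c.event)
            if ref is not None and c.event.max_depth < rho * ref:
                to_flip.append(c)
        else:
            run = run_of.get(id(c.event), [])
            if len(run) != 1:
                continue  # not isolated
            # bracketing dives (across surfacing bouts) must both be deep
            dives = [e for e in log.events if e.kind == "dive" and id(e) in class_of]
            i = next(j for j, e in enumerate(dives) if e is c.event)
            if i == 0 or i == len(dives) - 1:
                continue
            if class_of[id(dives[i - 1])] != DEEP or class_of[id(dives[i + 1])] != DEEP:
                continue
            ref = local_median(SHALLOW, c.event)
            if ref is not None and c.event.max_depth > ref / rho:
                to_flip.append(c)

    for c in to_flip:
        c.original_class = c.dive_class
        c.dive_class = SHALLOW if c.dive_class == DEEP else DEEP
        c.reclassified = True
    return classified


def classify_dives(
    log: BehaviorLog,
    seed: int = 0,
    tail: float = DEFAULT_FLAG_TAIL,
    rho: float = DEFAULT_RHO,
    window_h: float = DEFAULT_WINDOW_H,
    n_init: int = 50,
) -> tuple[list[ClassifiedDive], ClassificationReport]:
    """Full classification chain: 2-means, tail flagging, contextual
    reclassification.  Returns dives in log order."""
    classified, report = kmeans_two_class(log.dives(), seed=seed, n_init=n_init)
    classified = flag_borderline(classified, tail=tail)
    classified = contextual_reclassify(log, classified, rho=rho, window_h=window_h)
    report.n_flagged = sum(c.borderline for c in classified)
    report.n_reclassified = sum(c.reclassified for c in classified)
    report.n_deep = sum(c.dive_class == DEEP for c in classified)
    report.n_shallow = sum(c.dive_class == SHALLOW for c in classified)
    return classified, report
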