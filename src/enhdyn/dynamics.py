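"""Binding time-courses conditioned on class transitions and proximity tests.

For a transition cohort (enhancers moving from one TF class to another over
one time interval) the module contrasts TF-binding fractions of changers
against stayers, and tests whether changers sit closer to pre-existing
enhancers of a reference class than stayers do (Welch t-test on log10
center-to-center base distances; reference membership is taken at the
interval start, i.e. pre-transition).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from enhdyn._constants import SCORE_CAP

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# binding fractions


def binding_fraction_timecourse(
    assignments: dict[float, np.ndarray],
    raw_scores: dict[float, np.ndarray],
    classes: list[str],
    threshold: float = SCORE_CAP,
) -> pd.DataFrame:
    """Fraction of enhancers bound (raw score >= threshold) per class, per time.

    ``assignments`` and ``raw_scores`` map each time point to per-enhancer
    class labels and raw capped scores for one TF.  Fractions are on [0, 1].
    """
    times = sorted(assignments)
    out = pd.DataFrame(index=classes, columns=times, dtype=float)
    for t in times:
        a = np.asarray(assignments[t], dtype=object)
        s = np.asarray(raw_scores[t], dtype=float)
        for c in classes:
            members = a == c
            out.loc[c, t] = (
                float((s[members] >= threshold).mean()) if members.any() else np.nan
            )
    return out


@dataclass
class TransitionCohort:
    """Enhancers changing from ``from_class`` to ``to_class`` in one interval.

    The complement holds the from-class members at the interval start that
    stayed in the from-class (did not transition).
    """

    from_class: str
    to_class: str
    interval: tuple[float, float]
    members: np.ndarray
    complement: np.ndarray

    def __post_init__(self):
        if np.intersect1d(self.members, self.complement).size:
            raise ValueError("cohort and complement must be disjoint")


def build_transition_cohort(
    assign_start,
    assign_end,
    from_class: str,
    to_class: str,
    interval: tuple[float, float] = (0.0, 0.5),
) -> TransitionCohort:
    a = np.asarray(assign_start, dtype=object)
    b = np.asarray(assign_end, dtype=object)
    if a.shape != b.shape:
        raise ValueError("assignments must cover the same enhancer universe")
    members = np.flatnonzero((a == from_class) & (b == to_class))
    complement = np.flatnonzero((a == from_class) & (b == from_class))
    return TransitionCohort(from_class, to_class, interval, members, complement)


def conditioned_binding_fraction(
    cohort: TransitionCohort,
    raw_scores: dict[float, np.ndarray],
    threshold: float = SCORE_CAP,
) -> pd.DataFrame:
    """Binding-fraction curves for changers vs stayers of one cohort.

    Returns a 2 x time table with rows ``changers`` and ``stayers``; an
    empty complement flags the stayer curve as NaN.
    """
    if len(cohort.members) == 0:
        raise ValueError("empty transition cohort")
    if len(cohort.complement) == 0:
        warnings.warn("empty complement; stayer curve undefined")
    times = sorted(raw_scores)
    rows = {}
    for name, idx in (("changers", cohort.members), ("stayers", cohort.complement)):
        rows[name] = [
            float((np.asarray(raw_scores[t], dtype=float)[idx] >= threshold).mean())
            if len(idx)
            else np.nan
            for t in times
        ]
    return pd.DataFrame(rows, index=times).T


# ---------------------------------------------------------------------------
# distances


def nearest_enhancer_distance(
    query_index: int,
    centers: np.ndarray,
    chroms: np.ndarray,
    reference_indices: np.ndarray,
) -> float:
    """Base distance from one enhancer to its nearest same-chromosome reference.

    The query itself is excluded; with no same-chromosome reference the
    distance is undefined (NaN).
    """
    centers = np.asarray(centers)
    chroms = np.asarray(chroms)
    refs = np.asarray(reference_indices)
    refs = refs[(refs != query_index) & (chroms[refs] == chroms[query_index])]
    if len(refs) == 0:
        return float("nan")
    return float(np.abs(centers[refs] - centers[query_index]).min())


def nearest_distances(
    query_indices: np.ndarray,
    centers: np.ndarray,
    chroms: np.ndarray,
    reference_indices: np.ndarray,
) -> np.ndarray:
    """Vectorized nearest-reference distances for many queries."""
    return np.array(
        [
            nearest_enhancer_distance(int(q), centers, chroms, reference_indices)
            for q in np.asarray(query_indices)
        ]
    )


@dataclass
class ProximityTestResult:
    from_class: str
    to_class: str
    reference_class: str
    median_changers: float
    median_stayers: float
    t_statistic: float = float("nan")
    p_value: float = float("nan")
    n_changers: int = 0
    n_stayers: int = 0
    flagged: bool = False


def transition_distance_test(
    changer_distances,
    stayer_distances,
    cohort: TransitionCohort | None = None,
    reference_class: str = "",
    log_transform: bool = True,
) -> ProximityTestResult:
    """Welch two-sided t-test of changer vs stayer nearest-reference distances.

    The test runs on log10 distances by default (genomic distances are
    heavy-tailed); medians are reported on the base scale.  Groups with
    fewer than two defined distances flag the result and leave the p value
    undefined.
    """
    ch = np.asarray(changer_distances, dtype=float)
    st = np.asarray(stayer_distances, dtype=float)
    ch, st = ch[np.isfinite(ch)], st[np.isfinite(st)]
    if np.any(ch <= 0) or np.any(st <= 0):
        raise ValueError("distances must be positive")
    res = ProximityTestResult(
        from_class=cohort.from_class if cohort else "",
        to_class=cohort.to_class if cohort else "",
        reference_class=reference_class,
        median_changers=float(np.median(ch)) if len(ch) else float("nan"),
        median_stayers=float(np.median(st)) if len(st) else float("nan"),
        n_changers=len(ch),
        n_stayers=len(st),
    )
    if len(ch) < 2 or len(st) < 2:
        res.flagged = True
        return res
    a, b = (np.log10(ch), np.log10(st)) if log_transform else (ch, st)
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        # identical constant samples: no evidence of difference
        res.t_statistic, res.p_value = 0.0, 1.0
        return res
    t, p = stats.ttest_ind(a, b, equal_var=False)
    res.t_statistic, res.p_value = float(t), float(p)
    return res


def proximity_matrix(
    cohorts: list[TransitionCohort],
    assignments_start: dict[TransitionCohort, np.ndarray] | np.ndarray,
    centers: np.ndarray,
    chroms: np.ndarray,
    reference_classes: list[str],
) -> pd.DataFrame:
    """Distance tests of every cohort against every reference class.

    Reference-class membership is evaluated on the interval-start
    assignments.  The reference class with the smallest changer median is
    flagged ``most_proximal`` per cohort.
    """
    rows = []
    for cohort in cohorts:
        assign0 = (
            assignments_start[cohort]
            if isinstance(assignments_start, dict)
            else assignments_start
        )
        assign0 = np.asarray(assign0, dtype=object)
        results = []
        for ref in reference_classes:
            refs = np.flatnonzero(assign0 == ref)
            d_ch = nearest_distances(cohort.members, centers, chroms, refs)
            d_st = nearest_distances(cohort.complement, centers, chroms, refs)
            results.append(
                transition_distance_test(d_ch, d_st, cohort=cohort, reference_class=ref)
            )
        medians = [
            r.median_changers if np.isfinite(r.median_changers) else np.inf
            for r in results
        ]
        best = int(np.argmin(medians))
        for i, r in enumerate(results):
            rows.append(
                {
                    "from_class": r.from_class,
                    "to_class": r.to_class,
                    "reference_class": r.reference_class,
                    "median_changers": r.median_changers,
                    "median_stayers": r.median_stayers,
                    "t_statistic": r.t_statistic,
                    "p_value": r.p_value,
                    "most_proximal": i == best,
                    "flagged": r.flagged,
                }
            )
    return pd.DataFrame(rows)
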