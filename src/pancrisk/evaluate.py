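"""Discrimination and reclassification metrics for paired risk models.

AUROC is the Mann-Whitney statistic (ties get half credit via midranks);
its standard error and the paired comparison of two models scored on the
same subjects use the DeLong structural-component (placement-value)
covariance estimator.  Reclassification between two models at a fixed
risk threshold is tabulated separately for cases and controls, and the
category-based net reclassification improvement (NRI) is computed with
its large-sample standard error and a one-sided upper-tail test of
improvement (two-sided also reported).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["AUROCResult", "ReclassificationTable", "NRIResult",
           "auroc", "delong_compare", "reclassify", "nri"]


@dataclass
class AUROCResult:
    auc: float
    se: float
    ci95: tuple[float, float]
    n_cases: int
    n_controls: int


@dataclass
class ReclassificationTable:
    """2x2 movement counts between two models at a risk threshold.

    ``cases`` and ``controls`` are 2x2 integer arrays indexed
    [old category][new category], with category 0 = at or below the
    threshold ('low') and 1 = strictly above it ('high').
    """

    threshold: float
    cases: np.ndarray
    controls: np.ndarray

    def __post_init__(self) -> None:
        for name in ("cases", "controls"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (2, 2) or np.any(arr < 0) \
                    or not np.issubdtype(arr.dtype, np.integer):
                raise ValueError(f"{name} must be a 2x2 nonnegative integer array")
            setattr(self, name, arr)


@dataclass
class NRIResult:
    nri: float
    se: float
    z: float
    p_one_sided: float
    p_two_sided: float
    event_net: float
    nonevent_net: float


def _placements(case_scores: np.ndarray, control_scores: np.ndarray
                ) -> tuple[float, np.ndarray, np.ndarray]:
    """(auc, case placement values, control placement values) via midranks."""
    m, n = len(case_scores), len(control_scores)
    combined = np.concatenate([case_scores, control_scores])
    ranks = stats.rankdata(combined)                    # midranks
    case_ranks = stats.rankdata(case_scores)
    control_ranks = stats.rankdata(control_scores)
    v_cases = (ranks[:m] - case_ranks) / n              # P(score > random control)
    v_controls = 1.0 - (ranks[m:] - control_ranks) / m
    auc = float(v_cases.mean())
    return auc, v_cases, v_controls


def auroc(case_scores: Sequence[float], control_scores: Sequence[float]
          ) -> AUROCResult:
    """Mann-Whitney AUROC with a DeLong standard error.

    auc = [#(case > control) + 0.5 #(case = control)] / (m * n), computed
    from midranks in O(n log n).  The 95% CI is normal-approximation on the
    AUC scale, clipped to [0, 1].
    """
    cs = np.asarray(case_scores, dtype=float)
    ks = np.asarray(control_scores, dtype=float)
    if cs.size == 0 or ks.size == 0:
        raise ValueError("need at least one case and one control score")
    auc, v10, v01 = _placements(cs, ks)
    var = 0.0
    if cs.size > 1:
        var += np.var(v10, ddof=1) / cs.size
    if ks.size > 1:
        var += np.var(v01, ddof=1) / ks.size
    se = math.sqrt(var)
    half = 1.959963984540054 * se
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return AUROCResult(auc=auc, se=se, ci95=ci,
                       n_cases=int(cs.size), n_controls=int(ks.size))


def delong_compare(case_scores_a: Sequence[float],
                   control_scores_a: Sequence[float],
                   case_scores_b: Sequence[float],
                   control_scores_b: Sequence[float]
                   ) -> tuple[float, float, float, float, float]:
    """Paired comparison of two AUCs computed on the same subjects.

    Scores must be paired: entry i of each case vector (and j of each
    control vector) belongs to the same subject under models A and B.
    Returns (auc_a, auc_b, difference, z, two-sided p).
    """
    ca, ka = np.asarray(case_scores_a, float), np.asarray(control_scores_a, float)
    cb, kb = np.asarray(case_scores_b, float), np.asarray(control_scores_b, float)
    if ca.shape != cb.shape or ka.shape != kb.shape:
        raise ValueError("scores are not paired on the same subjects")
    if ca.size == 0 or ka.size == 0:
        raise ValueError("need at least one case and one control")
    auc_a, v10a, v01a = _placements(ca, ka)
    auc_b, v10b, v01b = _placements(cb, kb)
    m, n = ca.size, ka.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    s = s10 / m + s01 / n
    diff = auc_a - auc_b
    var = s[0, 0] + s[1, 1] - 2.0 * s[0, 1]
    z = 0.0 if var <= 0 else diff / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return auc_a, auc_b, diff, z, p


def reclassify(risks_old: Sequence[float], risks_new: Sequence[float],
               status: Sequence[str], threshold: float) -> ReclassificationTable:
    """Cross-tabulate movement across a risk threshold between two models.

    'High risk' is strictly greater than the threshold; at-threshold values
    are 'low'.  Counts are kept separately for cases and controls.
    """
    ro = np.asarray(risks_old, float)
    rn = np.asarray(risks_new, float)
    st = np.asarray(status, dtype=object)
    if not (ro.shape == rn.shape == st.shape):
        raise ValueError("risks_old, risks_new and status must align")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if np.any((ro < 0) | (ro > 1) | (rn < 0) | (rn > 1)):
        raise ValueError("risks must lie in [0, 1]")
    old_hi = (ro > threshold).astype(int)
    new_hi = (rn > threshold).astype(int)
    cases = np.zeros((2, 2), dtype=int)
    controls = np.zeros((2, 2), dtype=int)
    for oh, nh, s in zip(old_hi, new_hi, st):
        if s == "case":
            cases[oh, nh] += 1
        elif s == "control":
            controls[oh, nh] += 1
        else:
            raise ValueError(f"status must be 'case' or 'control', got {s!r}")
    return ReclassificationTable(threshold=threshold, cases=cases,
                                 controls=controls)


def nri(table: ReclassificationTable) -> NRIResult:
    """Category-based net reclassification improvement with its standard error.

    NRI = (up - down)/n among cases minus (up - down)/n among controls,
    where 'up' means moving above the threshold under the new model.  The
    variance is the standard large-sample form; the one-sided p-value
    tests improvement (upper tail).
    """
    up_c, down_c = int(table.cases[0, 1]), int(table.cases[1, 0])
    up_k, down_k = int(table.controls[0, 1]), int(table.controls[1, 0])
    n_c, n_k = int(table.cases.sum()), int(table.controls.sum())
    if n_c == 0 or n_k == 0:
        raise ValueError("need at least one case and one control")
    event_net = (up_c - down_c) / n_c
    nonevent_net = -(up_k - down_k) / n_k    # controls should move down
    value = event_net + nonevent_net
    var = ((up_c + down_c) / n_c**2 - (up_c - down_c)**2 / n_c**3
           + (up_k + down_k) / n_k**2 - (up_k - down_k)**2 / n_k**3)
    se = math.sqrt(max(var, 0.0))
    z = 0.0 if se == 0 else value / se
    return NRIResult(nri=value, se=se, z=z,
                     p_one_sided=float(stats.norm.sf(z)),
                     p_two_sided=float(2.0 * stats.norm.sf(abs(z))),
                     event_net=event_net, nonevent_net=nonevent_net)
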