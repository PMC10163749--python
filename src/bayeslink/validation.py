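"""Evaluation of linkage accuracy: signal-detection metrics and sweeps.

A proband is either present in the sample or not, and the system either
declares a match or not, giving the standard signal-detection outcomes
(TP/TN/FP/FN) plus the misidentification rate MID = P(wrong person |
match declared).  A true positive counts any declared match for an
in-sample proband — including a match to the wrong person — which is why
MID is tracked separately.  The weighted performance metric
WPM = FNR + w_MID·MID (default w_MID = 20) expresses a preference for
accuracy over comprehensive linkage and is what the default thresholds
minimise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.metrics import roc_auc_score

from .comparison import NEG_INF
from .engine import LinkageResult, decide_match

__all__ = ["SdtCounts", "classify_outcomes", "wpm", "threshold_sweep",
           "auroc", "two_by_two_chi_square"]

#: Finite stand-in for −∞ log odds in rank-based analyses.
AUROC_NEG_INF_SUBSTITUTE = -1e5


@dataclass(frozen=True)
class SdtCounts:
    """Signal-detection outcome counts for one linkage run.

    ``misidentified`` counts declared matches naming the wrong candidate
    (every false positive is necessarily wrong; a true positive may be).
    """
    tp: int
    tn: int
    fp: int
    fn: int
    misidentified: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def declared(self) -> int:
        return self.tp + self.fp

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def tnr(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else float("nan")

    @property
    def fnr(self) -> float:
        return self.fn / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def mid(self) -> float:
        return self.misidentified / self.declared if self.declared else 0.0

    def wpm(self, w_mid: float = 20.0) -> float:
        return wpm(self.fnr, self.mid, w_mid)


def wpm(fnr: float, mid: float, w_mid: float = 20.0) -> float:
    """Weighted performance metric FNR + w_MID·MID."""
    return fnr + w_mid * mid


def classify_outcomes(results: Sequence[LinkageResult],
                      truth: dict[str, str | None],
                      theta: float | None = None,
                      delta: float | None = None) -> SdtCounts:
    """Score linkage results against ground truth.

    ``truth`` maps each proband local ID to its true sample local ID (None
    if absent from the sample).  When θ/δ are given, decisions are
    re-derived from the stored leader/runner-up scores; otherwise the
    declared matches are used as-is.
    """
    tp = tn = fp = fn = misidentified = 0
    for result in results:
        if result.proband_local_id not in truth:
            raise ValueError(f"proband {result.proband_local_id!r} missing "
                             "from the truth map")
        true_id = truth[result.proband_local_id]
        if theta is not None and delta is not None:
            declared_id = decide_match(result, theta, delta)
        else:
            declared_id = result.match_local_id
        in_sample = true_id is not None
        declared = declared_id is not None
        if in_sample and declared:
            tp += 1
        elif in_sample:
            fn += 1
        elif declared:
            fp += 1
        else:
            tn += 1
        if declared and declared_id != true_id:
            misidentified += 1
    return SdtCounts(tp=tp, tn=tn, fp=fp, fn=fn, misidentified=misidentified)


def threshold_sweep(results: Sequence[LinkageResult],
                    truth: dict[str, str | None],
                    theta_grid: Sequence[float] = tuple(range(16)),
                    delta_grid: Sequence[float] = tuple(range(16))) -> pd.DataFrame:
    """Full metric surface over a θ/δ grid from a single linkage run.

    Candidate scores do not depend on the thresholds, so the sample is
    scored once and each grid cell only re-applies the decision rule.
    Returns one row per (θ, δ) with counts and rates.
    """
    if not len(theta_grid) or not len(delta_grid):
        raise ValueError("threshold grids must be nonempty")
    rows = []
    for theta in theta_grid:
        for delta in delta_grid:
            counts = classify_outcomes(results, truth, theta=theta, delta=delta)
            rows.append({
                "theta": theta, "delta": delta,
                "tp": counts.tp, "tn": counts.tn, "fp": counts.fp, "fn": counts.fn,
                "misidentified": counts.misidentified,
                "tpr": counts.tpr, "tnr": counts.tnr, "fpr": counts.fpr,
                "fnr": counts.fnr, "mid": counts.mid, "wpm": counts.wpm(),
            })
    return pd.DataFrame(rows)


def auroc(log_odds: Sequence[float], in_sample: Sequence[bool]) -> float:
    """Rank-based AUROC of leader log odds predicting sample membership.

    −∞ scores (candidates ruled out entirely) are replaced by the
    arbitrary low finite value −10⁵; ties use the midrank convention.
    """
    flags = np.asarray(in_sample, dtype=bool)
    if flags.all() or not flags.any():
        raise ValueError("AUROC undefined: need both positive and negative probands")
    scores = np.asarray([AUROC_NEG_INF_SUBSTITUTE if x == NEG_INF else x
                         for x in log_odds], dtype=float)
    return float(roc_auc_score(flags, scores))


def two_by_two_chi_square(a: int, n1: int, b: int, n2: int,
                          continuity_correction: bool = True) -> float:
    """Pearson χ² comparing proportions a/n1 vs b/n2.

    Yates continuity correction applied by default (matching standard R
    behaviour for 2×2 tables).  Undefined (raises) when a margin is zero.
    """
    if not (0 <= a <= n1 and 0 <= b <= n2):
        raise ValueError("need 0 <= a <= n1 and 0 <= b <= n2")
    table = np.array([[a, n1 - a], [b, n2 - b]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero margin")
    statistic, _, _, _ = chi2_contingency(table, correction=continuity_correction)
    return float(statistic)
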