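"""Per-session and cohort evaluation of a depth-of-anesthesia index.

Three metrics mirror the clinical validation protocol: the Pearson
correlation between the predicted index and a reference consciousness
track, their mean squared error, and the area under the ROC curve after
binarizing the reference at 65 (above 65 = awake, the positive class, so an
AUC near 1 means the index is high when the patient is awake).

The AUC is computed by the Mann-Whitney pair-count formulation with ties
scored 1/2; the trapezoidal integral of the ROC curve is computed alongside
and the two agree to numerical precision, each acting as a check on the
other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import IndexSeries, SessionBundle

__all__ = [
    "RocCurve",
    "EvalReport",
    "align",
    "pearson",
    "mse",
    "roc_auc",
    "evaluate_cohort",
    "AWAKE_THRESHOLD",
]

#: reference value separating awake from anesthetized
AWAKE_THRESHOLD = 65.0

_METRIC_COLUMNS = [
    "r_pred_vs_eacl",
    "r_pred_vs_bisref",
    "r_eacl_vs_bisref",
    "mse_pred_vs_eacl",
    "mse_pred_vs_bisref",
    "mse_eacl_vs_bisref",
    "auc_vs_eacl",
    "auc_vs_bisref",
]


@dataclass
class RocCurve:
    """ROC sweep of a continuous score against a binary reference."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float  # Mann-Whitney pair-count value (ties counted 1/2)

    @property
    def trapezoidal_auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


@dataclass
class EvalReport:
    """Per-session metric rows plus cohort mean +/- SD summaries."""

    per_session: pd.DataFrame
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        cols = [c for c in _METRIC_COLUMNS if c in self.per_session.columns]
        mean = self.per_session[cols].mean(skipna=True)
        # sample SD (n-1); undefined at n=1, reported as missing
        sd = self.per_session[cols].std(ddof=1, skipna=True)
        self.summary = pd.DataFrame({"mean": mean, "sd": sd})

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            self.per_session.to_csv(fh, index=False, float_format="%.6f")
            fh.write("\n")
            self.summary.to_csv(fh, float_format="%.6f", index_label="metric")


def align(a: IndexSeries, b: IndexSeries) -> tuple[np.ndarray, np.ndarray]:
    """Pair two index tracks on ``a``'s time grid.

    ``b`` is linearly interpolated onto the times of ``a`` restricted to the
    overlap of the two spans; pairs containing a non-finite value are
    dropped.
    """
    t0 = max(a.times[0], b.times[0])
    t1 = min(a.times[-1], b.times[-1])
    if t0 > t1:
        raise ValueError("index series have no overlapping time span")
    sel = (a.times >= t0) & (a.times <= t1)
    ta, va = a.times[sel], a.values[sel]
    vb = np.interp(ta, b.times, b.values)
    ok = np.isfinite(va) & np.isfinite(vb)
    return va[ok], vb[ok]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; NaN when either side is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def mse(x: np.ndarray, y: np.ndarray, root: bool = False) -> float:
    """Mean of squared differences; ``root=True`` returns the RMSE."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    v = float(np.mean(d**2))
    return float(np.sqrt(v)) if root else v


def roc_auc(
    scores: np.ndarray,
    reference: np.ndarray,
    threshold: float = AWAKE_THRESHOLD,
) -> RocCurve:
    """ROC of continuous ``scores`` against ``reference`` binarized at
    ``threshold`` (strictly above = awake = positive).

    The AUC is P(score_awake > score_anesthesia) + P(tie)/2, computed from
    midranks; when only one class is present the AUC is undefined (NaN).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(reference, dtype=float) > threshold
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return RocCurve(np.array([]), np.array([]), np.array([]), float("nan"))

    ranks = rankdata(scores)  # midranks score ties as 1/2 wins
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    distinct = np.flatnonzero(np.diff(sorted_scores)) + 1
    cut = np.concatenate([distinct, [scores.size]]) - 1  # last index per distinct score
    tp = np.cumsum(sorted_labels)[cut]
    fp = np.cumsum(~sorted_labels)[cut]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    thresholds = np.concatenate([[np.inf], sorted_scores[cut]])
    return RocCurve(thresholds, tpr, fpr, float(auc))


def _session_metrics(
    prediction: IndexSeries,
    eacl: IndexSeries,
    bis_ref: IndexSeries | None,
    threshold: float,
    root: bool,
) -> dict:
    row: dict = {}
    p, e = align(prediction, eacl)
    row["r_pred_vs_eacl"] = pearson(p, e)
    row["mse_pred_vs_eacl"] = mse(p, e, root)
    row["auc_vs_eacl"] = roc_auc(p, e, threshold).auc
    if bis_ref is not None:
        pb, b = align(prediction, bis_ref)
        row["r_pred_vs_bisref"] = pearson(pb, b)
        row["mse_pred_vs_bisref"] = mse(pb, b, root)
        row["auc_vs_bisref"] = roc_auc(pb, b, threshold).auc
        ea, bb = align(eacl, bis_ref)
        row["r_eacl_vs_bisref"] = pearson(ea, bb)
        row["mse_eacl_vs_bisref"] = mse(ea, bb, root)
    else:
        for c in ("r_pred_vs_bisref", "mse_pred_vs_bisref", "auc_vs_bisref",
                  "r_eacl_vs_bisref", "mse_eacl_vs_bisref"):
            row[c] = float("nan")
    return row


def evaluate_cohort(
    sessions: list[SessionBundle],
    predictions: dict[str, IndexSeries],
    threshold: float = AWAKE_THRESHOLD,
    root_mse: bool = False,
) -> EvalReport:
    """Per-session metrics for every session with a prediction, plus the
    cohort mean +/- sample-SD summary.

    Three comparisons are reported where the tracks exist: prediction vs
    EACL, prediction vs the BIS-like reference, and EACL vs the BIS-like
    reference. Sessions with undefined metrics carry NaN, which is excluded
    from the summary numerator and denominator.
    """
    if not sessions:
        raise ValueError("need at least one session")
    rows = []
    for s in sessions:
        sid = s.session_id
        if sid not in predictions:
            continue
        row = {"session_id": sid}
        row.update(
            _session_metrics(predictions[sid], s.eacl, s.bis_ref, threshold, root_mse)
        )
        rows.append(row)
    if not rows:
        raise ValueError("no session has a prediction")
    return EvalReport(per_session=pd.DataFrame(rows))
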