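"""Score-level evaluation: group t-test, ROC/Youden cutoff, confusion
metrics, and the WPGMA clustering view.

Classification rule: a sample is called high-risk when its posterior score
is >= the cutoff. Candidate cutoffs are the observed score values plus a
+inf sentinel (call nothing positive); this grid attains every achievable
confusion table. The operating cutoff maximizes the Youden index
(sensitivity + specificity - 1); ties are broken toward the cutoff with
higher specificity, then toward the larger cutoff.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .datamodel import ExpressionMatrix, SampleMetadata, risk_labels
from .discovery import two_sample_t
from .predictor import RiskScore

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RocCurve:
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden: np.ndarray
    optimal_cutoff: float
    optimal_index: int


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    youden: Optional[float]


def _split_scores(scores: Iterable[RiskScore], metadata) -> Tuple[np.ndarray, np.ndarray]:
    scores = list(scores)
    values = np.array([s.posterior_high for s in scores], dtype=float)
    high = risk_labels(metadata, [s.sample_id for s in scores])
    if high.all() or not high.any():
        raise ValueError("both risk classes must be present among the scored samples")
    return values, high


def score_group_ttest(scores: Iterable[RiskScore], metadata) -> float:
    """Two-sided pooled-variance t-test p-value, high-risk vs control scores."""
    values, high = _split_scores(scores, metadata)
    _, p = two_sample_t(values[high], values[~high])
    return p


def roc_with_youden(scores: Iterable[RiskScore], metadata) -> RocCurve:
    values, high = _split_scores(scores, metadata)
    if not np.all(np.isfinite(values)):
        raise ValueError("scores must be finite")
    cutoffs = np.append(np.unique(values), np.inf)
    if cutoffs.size == 2:  # single distinct score
        warnings.warn(
            "all scores identical; degenerate ROC with Youden 0",
            RuntimeWarning,
            stacklevel=2,
        )
    n_pos = int(high.sum())
    n_neg = int((~high).sum())
    sens = np.empty(cutoffs.size)
    spec = np.empty(cutoffs.size)
    for i, c in enumerate(cutoffs):
        pred = values >= c
        sens[i] = np.sum(pred & high) / n_pos
        spec[i] = np.sum(~pred & ~high) / n_neg
    youden = sens + spec - 1.0
    # argmax of youden; ties -> higher specificity, then larger cutoff
    order = np.lexsort((cutoffs, spec, youden))
    best = int(order[-1])
    return RocCurve(
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        youden=youden,
        optimal_cutoff=float(cutoffs[best]),
        optimal_index=best,
    )


def confusion_at_cutoff(
    scores: Iterable[RiskScore], metadata, cutoff: float
) -> ConfusionMetrics:
    values, high = _split_scores(scores, metadata)
    pred = values >= cutoff
    tp = int(np.sum(pred & high))
    fp = int(np.sum(pred & ~high))
    tn = int(np.sum(~pred & ~high))
    fn = int(np.sum(~pred & high))
    return _metrics_from_counts(tp, fp, tn, fn)


def _rate(num: int, denom: int, name: str) -> Optional[float]:
    if denom == 0:
        warnings.warn(
            f"{name} undefined (zero denominator)", RuntimeWarning, stacklevel=3
        )
        return None
    return num / denom


def _metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    sensitivity = _rate(tp, tp + fn, "sensitivity")
    specificity = _rate(tn, tn + fp, "specificity")
    ppv = _rate(tp, tp + fp, "PPV")
    npv = _rate(tn, tn + fn, "NPV")
    youden = (
        sensitivity + specificity - 1.0
        if sensitivity is not None and specificity is not None
        else None
    )
    return ConfusionMetrics(tp, fp, tn, fn, sensitivity, specificity, ppv, npv, youden)


def metrics_from_rates(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> ConfusionMetrics:
    """Reconstruct a confusion table from reported rates and group sizes.

    ``tp = round(sensitivity * n_pos)``, ``tn = round(specificity * n_neg)``;
    PPV/NPV/Youden follow from the reconstructed counts.
    """
    for name, rate in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {rate}")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("group sizes must be positive")
    tp = int(np.floor(sensitivity * n_pos + 0.5))
    tn = int(np.floor(specificity * n_neg + 0.5))
    fn = n_pos - tp
    fp = n_neg - tn
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("rounded counts are negative; inconsistent rates")
    return _metrics_from_counts(tp, fp, tn, fn)


@dataclass(frozen=True)
class WpgmaTree:
    """Agglomerative merge list in scipy linkage form (label indices refer
    to ``labels``; merged clusters are numbered ``len(labels) + step``)."""

    labels: Tuple[str, ...]
    merges: np.ndarray  # (n-1) x 4 linkage matrix


def wpgma_cluster(std_matrix: ExpressionMatrix, axis: str = "probes") -> WpgmaTree:
    """WPGMA (McQuitty) hierarchical clustering on Euclidean distances.

    The merge distance to a newly formed cluster is the unweighted mean of
    the two members' distances, which is robust to very uneven cluster
    sizes. Deterministic given input order.
    """
    if axis == "probes":
        items = std_matrix.values
        labels = std_matrix.probe_ids
    elif axis == "samples":
        items = std_matrix.values.T
        labels = std_matrix.sample_ids
    else:
        raise ValueError(f"axis must be 'probes' or 'samples', got {axis!r}")
    if items.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    merges = linkage(pdist(items, metric="euclidean"), method="weighted")
    return WpgmaTree(labels=labels, merges=merges)


def evaluation_row(
    dataset_id: str,
    panel_label: str,
    n_genes: int,
    scores: Iterable[RiskScore],
    metadata,
) -> dict:
    """One Table-style report row: t-test p + confusion metrics at the
    Youden-optimal cutoff."""
    scores = list(scores)
    p = score_group_ttest(scores, metadata)
    roc = roc_with_youden(scores, metadata)
    cm = confusion_at_cutoff(scores, metadata, roc.optimal_cutoff)
    return {
        "dataset": dataset_id,
        "panel": panel_label,
        "n_genes": n_genes,
        "t_test_p": p,
        "cutoff": roc.optimal_cutoff,
        "sensitivity_pct": None if cm.sensitivity is None else 100 * cm.sensitivity,
        "specificity_pct": None if cm.specificity is None else 100 * cm.specificity,
        "ppv_pct": None if cm.ppv is None else 100 * cm.ppv,
        "npv_pct": None if cm.npv is None else 100 * cm.npv,
        "youden": cm.youden,
    }


def format_report(rows: List[dict]) -> pd.DataFrame:
    """Render rows with the reporting precisions (rates 1 dp in percent,
    Youden 2 dp, p-values 3 significant digits)."""
    out = []
    for row in rows:
        out.append(
            {
                "dataset": row["dataset"],
                "panel": row["panel"],
                "n_genes": row["n_genes"],
                "t_test_p": f"{row['t_test_p']:.3g}",
                "sensitivity_pct": _fmt(row["sensitivity_pct"], "{:.1f}"),
                "specificity_pct": _fmt(row["specificity_pct"], "{:.1f}"),
                "ppv_pct": _fmt(row["ppv_pct"], "{:.1f}"),
                "npv_pct": _fmt(row["npv_pct"], "{:.1f}"),
                "youden": _fmt(row["youden"], "{:.2f}"),
            }
        )
    return pd.DataFrame(out)


def _fmt(value, spec: str) -> str:
    return "" if value is None else spec.format(value)


def write_report_tsv(rows: List[dict], path) -> None:
    format_report(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
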