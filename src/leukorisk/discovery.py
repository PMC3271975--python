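"""Stage 1: per-probe differential expression between risk classes.

Each probe is tested with a pooled-variance (Student) two-sample t-test
between high-risk and low-risk samples; p-values are converted to
Benjamini-Hochberg q-values (pi0 fixed at 1) and thresholded inclusively at
``q <= q_threshold``. Fold changes are reported on the linear scale with the
down-regulation convention: ``r = 2^(mean_high - mean_low)`` if ``r >= 1``,
else ``-1/r``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionMatrix, FunctionAnnotation, SampleMetadata, risk_labels

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """Both groups are constant; the t statistic is undefined."""


@dataclass(frozen=True)
class DiffExprRecord:
    probe_id: str
    t_stat: float
    p_value: float
    q_value: float
    fold_change: float
    significant: bool


def two_sample_t(group_a: Sequence[float], group_b: Sequence[float]):
    """Pooled-variance Student t-test; returns ``(t, two-sided p)``.

    ``t`` is signed by ``mean(group_a) - mean(group_b)``, with
    ``len(a) + len(b) - 2`` degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    sp2 = _pooled_variance(a, b)
    if sp2 <= 0:
        raise ZeroVarianceError("zero pooled variance; t statistic undefined")
    df = a.size + b.size - 2
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def _pooled_variance(a: np.ndarray, b: np.ndarray) -> float:
    df = a.size + b.size - 2
    return float(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df)


def fdr_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (pi0 = 1), aligned to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_fold_change(mean_high: float, mean_low: float) -> float:
    """Linear fold change with sign encoding direction (|fc| >= 1)."""
    r = 2.0 ** (mean_high - mean_low)
    return float(r if r >= 1.0 else -1.0 / r)


def discover_biomarkers(
    matrix: ExpressionMatrix,
    metadata: Iterable[SampleMetadata],
    q_threshold: float = 0.01,
) -> List[DiffExprRecord]:
    """Test every probe, ordered by ascending p-value.

    Probes with zero pooled variance are skipped with a logged warning; the
    q-value correction is applied over the tested probes.
    """
    if not 0 < q_threshold <= 1:
        raise ValueError("q_threshold must be in (0, 1]")
    high = risk_labels(metadata, matrix.sample_ids)
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high < 2 or n_low < 2:
        raise ValueError(
            f"both risk classes need >= 2 samples (high={n_high}, low={n_low})"
        )
    xh = matrix.values[:, high]
    xl = matrix.values[:, ~high]
    df = n_high + n_low - 2
    sp2 = ((n_high - 1) * xh.var(axis=1, ddof=1) + (n_low - 1) * xl.var(axis=1, ddof=1)) / df
    tested = sp2 > 0
    n_skipped = int((~tested).sum())
    if n_skipped:
        logger.warning("skipping %d zero-variance probes", n_skipped)
    mean_high = xh.mean(axis=1)
    mean_low = xl.mean(axis=1)
    se = np.sqrt(sp2[tested] * (1.0 / n_high + 1.0 / n_low))
    t = (mean_high[tested] - mean_low[tested]) / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    q = fdr_qvalues(p)
    probe_ids = np.asarray(matrix.probe_ids)[tested]
    records = [
        DiffExprRecord(
            probe_id=str(probe_ids[i]),
            t_stat=float(t[i]),
            p_value=float(p[i]),
            q_value=float(q[i]),
            fold_change=signed_fold_change(
                float(mean_high[tested][i]), float(mean_low[tested][i])
            ),
            significant=bool(q[i] <= q_threshold),
        )
        for i in range(probe_ids.size)
    ]
    records.sort(key=lambda r: (r.p_value, r.probe_id))
    n_flagged = sum(r.significant for r in records)
    logger.info(
        "discovery: %d probes tested, %d flagged at q <= %g",
        len(records), n_flagged, q_threshold,
    )
    return records


def discovery_table(
    records: Iterable[DiffExprRecord],
    annotations: Optional[Iterable[FunctionAnnotation]] = None,
) -> pd.DataFrame:
    """Tabulate records with optional gene symbols, mirroring a report layout
    of probe, symbol, p, q, fold change, flag."""
    symbol = {}
    if annotations is not None:
        symbol = {a.probe_id: a.gene_symbol for a in annotations}
    rows = [
        (
            r.probe_id,
            symbol.get(r.probe_id, ""),
            r.t_stat,
            r.p_value,
            r.q_value,
            r.fold_change,
            r.significant,
        )
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id", "gene_symbol", "t_stat", "p_value", "q_value",
            "fold_change", "significant",
        ],
    )


def write_discovery_tsv(records, path, annotations=None) -> None:
    discovery_table(records, annotations).to_csv(
        path, sep="\t", index=False, float_format="%.6g", lineterminator="\n"
    )


def read_discovery_tsv(path) -> List[DiffExprRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    return [
        DiffExprRecord(
            probe_id=str(row.probe_id),
            t_stat=float(row.t_stat),
            p_value=float(row.p_value),
            q_value=float(row.q_value),
            fold_change=float(row.fold_change),
            significant=bool(row.significant),
        )
        for row in frame.itertuples(index=False)
    ]
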