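"""CO-eXpression ExtrapolatioN (COXEN) biomarker selection.

A biomarker transfers between two cell types when its co-expression pattern
with the other panel members is preserved. For each dataset we build the
panel's Spearman co-expression matrix; probe *i*'s concordance is then the
Pearson correlation between its two co-expression vectors (row *i* of each
matrix with the self-correlation removed, length ``g - 1``). Significance
uses the standard correlation t transform, ``t = r * sqrt((g-3)/(1-r^2))``
with ``g - 3`` degrees of freedom, and probes with ``p < alpha`` (strict,
unadjusted) are selected.

By default co-expression uses every sample of a set; passing sample
metadata with ``sample_scope="controls"`` computes it on low-risk samples
only, which isolates constitutive co-expression from the case/control
effect (the pipeline's default; see the methods note).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, SampleMetadata, risk_labels
from .triage import BiomarkerPanel, EmptyPanelError

logger = logging.getLogger(__name__)


class EmptySelectionError(ValueError):
    """No probe met the concordance threshold."""


@dataclass(frozen=True)
class CoxenResult:
    probe_id: str
    concordance_r: float
    concordance_p: float
    selected: bool
    alpha: float


def coexpression_matrix(
    matrix: ExpressionMatrix,
    panel: BiomarkerPanel,
    sample_scope: str = "all",
    metadata: Optional[Iterable[SampleMetadata]] = None,
) -> np.ndarray:
    """Spearman rank correlation matrix of the panel probes across samples.

    Constant probes get zero correlations (diagonal stays 1) with a warning.
    """
    sub = matrix.subset_probes(panel.probe_ids)
    values = sub.values
    if sample_scope == "controls":
        if metadata is None:
            raise ValueError("sample_scope='controls' requires metadata")
        high = risk_labels(metadata, sub.sample_ids)
        values = values[:, ~high]
    elif sample_scope != "all":
        raise ValueError(f"unknown sample_scope {sample_scope!r}")
    if values.shape[1] < 3:
        raise ValueError(
            f"need >= 3 samples for co-expression, got {values.shape[1]}"
        )
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant probes; their correlations set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        # avoid 0/0 inside corrcoef; the affected rows are zeroed below
        ranks[constant, 0] += 1.0
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(ranks)
    if constant.any():
        cor[constant, :] = 0.0
        cor[:, constant] = 0.0
    np.fill_diagonal(cor, 1.0)
    return cor


def concordance_scores(
    cor_a: np.ndarray,
    cor_b: np.ndarray,
    probe_ids: Sequence[str],
    alpha: float = 0.001,
) -> List[CoxenResult]:
    """Per-probe second-order concordance between two co-expression matrices."""
    cor_a = np.asarray(cor_a, dtype=float)
    cor_b = np.asarray(cor_b, dtype=float)
    if cor_a.shape != cor_b.shape or cor_a.ndim != 2 or cor_a.shape[0] != cor_a.shape[1]:
        raise ValueError(
            f"correlation matrices must be square with identical shape, "
            f"got {cor_a.shape} and {cor_b.shape}"
        )
    g = cor_a.shape[0]
    if len(probe_ids) != g:
        raise ValueError("probe_ids length must match matrix dimension")
    if g < 4:
        raise ValueError(f"need at least 4 probes for a concordance p-value, got {g}")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    off = ~np.eye(g, dtype=bool)
    df = g - 3  # vectors have g-1 entries; correlation t test df = (g-1) - 2
    results: List[CoxenResult] = []
    for i in range(g):
        va = cor_a[i, off[i]]
        vb = cor_b[i, off[i]]
        r, p = _pearson_with_t_pvalue(va, vb, df)
        results.append(
            CoxenResult(
                probe_id=str(probe_ids[i]),
                concordance_r=r,
                concordance_p=p,
                selected=bool(p < alpha),
                alpha=alpha,
            )
        )
    return results


def _pearson_with_t_pvalue(x: np.ndarray, y: np.ndarray, df: int):
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        warnings.warn(
            "constant concordance vector; r set to 0", RuntimeWarning, stacklevel=3
        )
        return 0.0, 1.0
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def select_coxen_panel(
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    panel: BiomarkerPanel,
    alpha: float = 0.001,
    sample_scope: str = "all",
    metadata: Optional[Iterable[SampleMetadata]] = None,
) -> BiomarkerPanel:
    """Sub-panel of probes whose co-expression is concordant across sets.

    Panel order is preserved; raises if nothing is selected (the threshold
    ``alpha`` should then be reviewed).
    """
    metadata = list(metadata) if metadata is not None else None
    cor_a = coexpression_matrix(train, panel, sample_scope, metadata)
    cor_b = coexpression_matrix(test, panel, sample_scope, metadata)
    results = concordance_scores(cor_a, cor_b, panel.probe_ids, alpha)
    selected = [r.probe_id for r in results if r.selected]
    if not selected:
        raise EmptySelectionError(
            f"no probe concordant at p < {alpha} between {train.dataset_id!r} "
            f"and {test.dataset_id!r}; review alpha"
        )
    logger.info(
        "coxen: %d of %d panel probes concordant between %s and %s at alpha=%g",
        len(selected), len(panel), train.dataset_id, test.dataset_id, alpha,
    )
    try:
        return BiomarkerPanel(
            probe_ids=tuple(selected),
            source="coxen",
            training_dataset_id=panel.training_dataset_id,
            description=(
                f"COXEN panel for {test.dataset_id} "
                f"({len(selected)}/{len(panel)} probes, alpha={alpha:g})"
            ),
        )
    except EmptyPanelError as exc:  # pragma: no cover - guarded above
        raise EmptySelectionError(str(exc)) from exc


def coxen_table(results: Iterable[CoxenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.probe_id, r.concordance_r, r.concordance_p, r.selected) for r in results],
        columns=["probe_id", "concordance_r", "concordance_p", "selected"],
    )


def write_coxen_tsv(results, path) -> None:
    coxen_table(results).to_csv(
        path, sep="\t", index=False, float_format="%.6g", lineterminator="\n"
    )
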