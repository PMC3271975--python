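"""Stage 2: functional triage of discovered biomarkers.

The original analysis narrowed differentially expressed probes to those
whose annotated biological function is directly relevant to atherogenesis
(inflammation, lipid and other metabolic processes, hematological system
development). Here that knowledge base is a plain annotation table; the
default allowed vocabulary is the set of categories such a curation retains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Set, Tuple

from .datamodel import FunctionAnnotation
from .discovery import DiffExprRecord

logger = logging.getLogger(__name__)

DEFAULT_ALLOWED_CATEGORIES: frozenset = frozenset(
    {
        "Inflammatory Response",
        "Inflammatory Disease",
        "Immunological Disease",
        "Lipid Metabolism",
        "Other Metabolic Processes",
        "Carbohydrate Metabolism",
        "Hematological System Development and Function",
    }
)


class EmptyPanelError(ValueError):
    """Filtering produced an empty panel."""


@dataclass(frozen=True)
class BiomarkerPanel:
    """Ordered probe list with provenance (universal vs COXEN-selected)."""

    probe_ids: Tuple[str, ...]
    source: str  # "universal" or "coxen"
    training_dataset_id: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_ids", tuple(str(p) for p in self.probe_ids))
        if not self.probe_ids:
            raise EmptyPanelError("a biomarker panel must be non-empty")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probes in panel")
        if self.source not in ("universal", "coxen"):
            raise ValueError(f"unknown panel source {self.source!r}")

    def __len__(self) -> int:
        return len(self.probe_ids)


def filter_by_function(
    records: Iterable[DiffExprRecord],
    annotations: Iterable[FunctionAnnotation],
    allowed_categories: Set[str] = DEFAULT_ALLOWED_CATEGORIES,
    training_dataset_id: str = "",
) -> BiomarkerPanel:
    """Keep flagged probes whose annotation category is allowed.

    Order of the input records (ascending p-value from discovery) is
    preserved. Flagged probes without any annotation are dropped with a
    logged count; an empty result raises, suggesting the category set be
    reviewed.
    """
    allowed = set(allowed_categories)
    if not allowed:
        raise ValueError("allowed_categories must not be empty")
    category = {a.probe_id: a.category for a in annotations}
    kept: List[str] = []
    n_unannotated = 0
    n_flagged = 0
    for record in records:
        if not record.significant:
            continue
        n_flagged += 1
        if record.probe_id in kept:
            continue
        if record.probe_id not in category:
            n_unannotated += 1
            continue
        if category[record.probe_id] in allowed:
            kept.append(record.probe_id)
    if n_unannotated:
        logger.info("triage: dropped %d flagged probes without annotation", n_unannotated)
    if not kept:
        raise EmptyPanelError(
            f"no flagged probe matched the {len(allowed)} allowed categories; "
            "review allowed_categories or the annotation table"
        )
    logger.info("triage: %d of %d flagged probes retained", len(kept), n_flagged)
    return BiomarkerPanel(
        probe_ids=tuple(kept),
        source="universal",
        training_dataset_id=training_dataset_id,
        description=f"function-triaged panel ({len(kept)} probes)",
    )
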