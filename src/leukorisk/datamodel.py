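"""Core in-memory containers for the risk-prediction pipeline.

The study design is a case/control transcriptomic cohort: each dataset is a
probes x samples matrix of log2 expression intensities for one leukocyte cell
type, and every sample carries a two-level risk class (``high`` for familial
hypercholesterolemia / atherosclerosis patients, ``low`` for healthy controls)
plus a finer subclass used only for effect modelling and plotting.

Values are assumed to be already log2-transformed and normalized; no
normalization is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

RISK_HIGH = "high"
RISK_LOW = "low"

#: subclass -> implied risk class
SUBCLASS_RISK: Mapping[str, str] = {
    "homozygous_FH": RISK_HIGH,
    "heterozygous_FH": RISK_HIGH,
    "atherosclerosis": RISK_HIGH,
    "control": RISK_LOW,
}


class FormatError(ValueError):
    """A file or table violates the declared dialect or an invariant."""


@dataclass(frozen=True)
class SampleMetadata:
    """Risk annotation for one sample.

    ``subclass`` must be consistent with ``risk_class``: controls are low
    risk, every patient subclass is high risk.
    """

    sample_id: str
    risk_class: str
    subclass: str

    def __post_init__(self) -> None:
        if self.subclass not in SUBCLASS_RISK:
            raise FormatError(
                f"unknown subclass {self.subclass!r} for sample {self.sample_id!r}; "
                f"expected one of {sorted(SUBCLASS_RISK)}"
            )
        if self.risk_class not in (RISK_HIGH, RISK_LOW):
            raise FormatError(
                f"unknown risk class {self.risk_class!r} for sample {self.sample_id!r}"
            )
        implied = SUBCLASS_RISK[self.subclass]
        if self.risk_class != implied:
            raise FormatError(
                f"sample {self.sample_id!r}: subclass {self.subclass!r} implies "
                f"risk_class {implied!r}, got {self.risk_class!r}"
            )


@dataclass(frozen=True)
class FunctionAnnotation:
    """Probe-level functional annotation (one category per probe record)."""

    probe_id: str
    gene_symbol: str
    category: str


@dataclass(frozen=True, eq=False)
class ExpressionMatrix:
    """Probes x samples log2 intensity matrix for one dataset / cell type."""

    dataset_id: str
    cell_type: str
    probe_ids: tuple
    sample_ids: tuple
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_ids", tuple(str(p) for p in self.probe_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise FormatError(f"values must be 2-D, got shape {values.shape}")
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise FormatError(
                f"shape {values.shape} does not match {len(self.probe_ids)} probes "
                f"x {len(self.sample_ids)} samples"
            )
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise FormatError(f"duplicate {name} id {dup!r} in dataset {self.dataset_id!r}")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at probe {self.probe_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r} in dataset {self.dataset_id!r}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self) -> dict:
        return {p: i for i, p in enumerate(self.probe_ids)}

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``probe_ids`` in the given order; error on missing probes."""
        index = self.probe_index()
        missing = [p for p in probe_ids if p not in index]
        if missing:
            raise KeyError(
                f"probes missing from dataset {self.dataset_id!r}: {sorted(missing)}"
            )
        rows = [index[p] for p in probe_ids]
        return ExpressionMatrix(
            self.dataset_id, self.cell_type, tuple(probe_ids), self.sample_ids,
            self.values[rows, :],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(
                f"samples missing from dataset {self.dataset_id!r}: {sorted(missing)}"
            )
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(
            self.dataset_id, self.cell_type, self.probe_ids, tuple(sample_ids),
            self.values[:, cols],
        )

    def equals(self, other: "ExpressionMatrix", rtol: float = 1e-7, atol: float = 1e-9) -> bool:
        return (
            self.probe_ids == other.probe_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values, other.values, rtol=rtol, atol=atol)
        )


def _first_duplicate(items: Iterable[str]):
    seen = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None


def intersect_probes(a: ExpressionMatrix, b: ExpressionMatrix):
    """Restrict both matrices to their shared probes, lexicographically ordered.

    Probe order is canonicalized (sorted on probe id) so that downstream PCA
    loadings and reports are deterministic regardless of input file order.
    Sample columns are untouched.
    """
    shared = sorted(set(a.probe_ids) & set(b.probe_ids))
    if not shared:
        raise ValueError(
            f"datasets {a.dataset_id!r} and {b.dataset_id!r} share no probes"
        )
    return a.subset_probes(shared), b.subset_probes(shared)


def metadata_by_id(metadata: Iterable[SampleMetadata]) -> dict:
    out = {}
    for record in metadata:
        if record.sample_id in out and out[record.sample_id] != record:
            raise FormatError(f"conflicting metadata for sample {record.sample_id!r}")
        out[record.sample_id] = record
    return out


def risk_labels(metadata: Iterable[SampleMetadata], sample_ids: Sequence[str]) -> np.ndarray:
    """Boolean high-risk indicator aligned to ``sample_ids``."""
    table = metadata_by_id(metadata)
    missing = [s for s in sample_ids if s not in table]
    if missing:
        raise KeyError(f"samples without metadata: {sorted(missing)}")
    return np.array([table[s].risk_class == RISK_HIGH for s in sample_ids], dtype=bool)
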