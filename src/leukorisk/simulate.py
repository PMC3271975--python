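"""Synthetic multi-cell-type expression cohorts with known ground truth.

The generator emulates the study design the pipeline was built for: a
monocyte training cohort of familial hypercholesterolemia (FH) patients and
controls (3 homozygous + 7 heterozygous + 13 controls), a T-cell cohort from
the same subjects, a small whole-white-blood-cell cohort (5 + 5), and a
macrophage atherosclerosis cohort (14 + 14).

Generative model, per cell type, on the log2 scale::

    value(g, s) = mu_g + sum_k lambda_gk(cell) * f_ks + delta_g * z(s) + eps

* ``mu_g`` -- probe baseline, uniform on [5, 9].
* ``f_ks`` -- per-sample latent co-expression factor scores, iid N(0, 1).
  A subject's factor scores are a property of the subject: datasets that
  reuse the subjects of an earlier set (the FH1/FH2 pattern) share the same
  realized scores, while the residual noise is always drawn fresh.
* ``lambda_gk`` -- sparse factor loadings (each probe loads on one factor
  with magnitude ``loading_scale`` and random sign). Concordant probes keep
  the same loadings in every cell type; discordant probes are reassigned to
  a *different* factor (fresh random sign) in every non-reference cell type,
  so their co-expression pattern is genuinely cell-type specific rather
  than coincidentally preserved or merely sign-flipped.
* ``delta_g`` -- log2 risk effect, nonzero only for the ``n_de`` truly
  differential probes, with ``|delta|`` uniform in ``log2_effect_range`` and
  random sign; multiplied by ``homozygous_multiplier`` for homozygous FH
  samples (clinically the most severely affected subclass).
* ``z(s)`` -- 1 for high-risk samples, 0 for controls.
* ``eps`` -- iid N(0, noise_sd^2) residual.

Annotations mimic a curated function table: every differential probe is
annotated, a configurable fraction with an out-of-vocabulary category so the
triage stage has something to drop; background probes are annotated with
probability ``background_annotated_fraction``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Tuple

import numpy as np

from . import io
from .datamodel import SUBCLASS_RISK, ExpressionMatrix, FunctionAnnotation, SampleMetadata

logger = logging.getLogger(__name__)

#: controlled vocabulary of atherosclerosis-relevant function categories
VOCABULARY = (
    "Inflammatory Response",
    "Inflammatory Disease",
    "Immunological Disease",
    "Lipid Metabolism",
    "Other Metabolic Processes",
    "Carbohydrate Metabolism",
    "Hematological System Development and Function",
)

#: deliberately out-of-vocabulary category used to exercise triage
OUT_OF_VOCAB_CATEGORY = "Neuronal Signaling"


@dataclass(frozen=True)
class DatasetDesign:
    """Sample layout of one dataset: subclass counts and subject sharing."""

    dataset_id: str
    cell_type: str
    subclass_counts: Tuple[Tuple[str, int], ...]
    share_subjects_with: str = ""

    def n_samples(self) -> int:
        return sum(n for _, n in self.subclass_counts)


DEFAULT_DESIGNS: Tuple[DatasetDesign, ...] = (
    DatasetDesign("FH1", "monocyte",
                  (("homozygous_FH", 3), ("heterozygous_FH", 7), ("control", 13))),
    DatasetDesign("FH2", "t_cell",
                  (("homozygous_FH", 3), ("heterozygous_FH", 7), ("control", 13)),
                  share_subjects_with="FH1"),
    DatasetDesign("FH3", "wbc",
                  (("heterozygous_FH", 5), ("control", 5))),
    DatasetDesign("ATHERO1", "macrophage",
                  (("atherosclerosis", 14), ("control", 14))),
)


@dataclass(frozen=True)
class CohortConfig:
    """Tunable knobs of the generator; defaults are the study conditions."""

    n_probes: int = 2000
    n_de: int = 100
    designs: Tuple[DatasetDesign, ...] = DEFAULT_DESIGNS
    log2_effect_range: Tuple[float, float] = (0.26, 0.92)
    homozygous_multiplier: float = 1.8
    concordant_fraction: float = 0.5
    n_latent: int = 5
    loading_scale: float = 0.21
    noise_sd: float = 0.09
    out_of_vocab_fraction: float = 0.2
    background_annotated_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.concordant_fraction <= 1:
            raise ValueError("concordant_fraction must be in [0, 1]")
        if self.n_de > self.n_probes:
            raise ValueError(
                f"n_de={self.n_de} exceeds n_probes={self.n_probes}"
            )
        if self.n_de < 0 or self.n_probes <= 0:
            raise ValueError("n_probes must be positive and n_de non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.log2_effect_range
        if not (0 <= lo <= hi):
            raise ValueError("log2_effect_range must satisfy 0 <= lo <= hi")
        if self.n_latent < 1:
            raise ValueError("n_latent must be at least 1")
        if not self.designs:
            raise ValueError("at least one dataset design is required")
        for design in self.designs:
            for subclass, n in design.subclass_counts:
                if subclass not in SUBCLASS_RISK:
                    raise ValueError(f"unknown subclass {subclass!r} in design")
                if n < 0:
                    raise ValueError("negative sample count in design")


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth of a generated cohort."""

    de_probes: Tuple[str, ...]
    concordant_probes: Tuple[str, ...]
    log2_effects: Mapping[str, float]


@dataclass
class Cohort:
    matrices: Dict[str, ExpressionMatrix]
    metadata: Tuple[SampleMetadata, ...]
    annotations: Tuple[FunctionAnnotation, ...]
    truth: CohortTruth
    config: CohortConfig = field(repr=False)


def _probe_id(i: int) -> str:
    return f"P{i:05d}_at"


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full multi-cell-type cohort; bit-identical for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_probes
    probe_ids = [_probe_id(i) for i in range(n)]

    # ground truth: differential probes, effects, concordance mask
    de_idx = np.sort(rng.choice(n, size=config.n_de, replace=False))
    lo, hi = config.log2_effect_range
    magnitudes = rng.uniform(lo, hi, size=config.n_de)
    signs = rng.choice([-1.0, 1.0], size=config.n_de)
    effects = np.zeros(n)
    effects[de_idx] = signs * magnitudes
    n_conc = int(round(config.concordant_fraction * n))
    conc_idx = np.sort(rng.choice(n, size=n_conc, replace=False))
    concordant = np.zeros(n, dtype=bool)
    concordant[conc_idx] = True

    baseline = rng.uniform(5.0, 9.0, size=n)
    ref_factor = rng.integers(config.n_latent, size=n)
    ref_sign = rng.choice([-1.0, 1.0], size=n)

    def loadings_for(redraw: bool) -> np.ndarray:
        factor = ref_factor.copy()
        sign = ref_sign.copy()
        if redraw:
            disc = ~concordant
            n_disc = int(disc.sum())
            if config.n_latent > 1:
                # shift by 1..n_latent-1 so the new factor always differs
                shift = rng.integers(1, config.n_latent, size=n_disc)
                factor[disc] = (factor[disc] + shift) % config.n_latent
            sign[disc] = rng.choice([-1.0, 1.0], size=n_disc)
        lam = np.zeros((n, config.n_latent))
        lam[np.arange(n), factor] = sign * config.loading_scale
        return lam

    # subjects & metadata: datasets may reuse the subjects of an earlier set
    sample_ids: Dict[str, Tuple[str, ...]] = {}
    z_values: Dict[str, np.ndarray] = {}
    metadata: Dict[str, SampleMetadata] = {}
    for design in config.designs:
        if design.share_subjects_with:
            source = design.share_subjects_with
            if source not in sample_ids:
                raise ValueError(
                    f"design {design.dataset_id!r} shares subjects with "
                    f"unknown dataset {source!r}"
                )
            sample_ids[design.dataset_id] = sample_ids[source]
            z_values[design.dataset_id] = z_values[source]
            continue
        ids, zs = [], []
        counter = 0
        for subclass, count in design.subclass_counts:
            for _ in range(count):
                sid = f"{design.dataset_id}_S{counter:02d}"
                counter += 1
                ids.append(sid)
                metadata[sid] = SampleMetadata(sid, SUBCLASS_RISK[subclass], subclass)
                if subclass == "control":
                    zs.append(0.0)
                elif subclass == "homozygous_FH":
                    zs.append(config.homozygous_multiplier)
                else:
                    zs.append(1.0)
        sample_ids[design.dataset_id] = tuple(ids)
        z_values[design.dataset_id] = np.array(zs)

    # expression values; the first design is the reference cell type whose
    # loadings define the concordance target
    matrices: Dict[str, ExpressionMatrix] = {}
    factor_scores: Dict[str, np.ndarray] = {}
    for k, design in enumerate(config.designs):
        lam = loadings_for(redraw=k > 0)
        ids = sample_ids[design.dataset_id]
        z = z_values[design.dataset_id]
        n_s = len(ids)
        if design.share_subjects_with:
            f = factor_scores[design.share_subjects_with]
        else:
            f = rng.standard_normal((config.n_latent, n_s))
        factor_scores[design.dataset_id] = f
        eps = rng.normal(0.0, config.noise_sd, size=(n, n_s))
        values = baseline[:, None] + lam @ f + effects[:, None] * z[None, :] + eps
        matrices[design.dataset_id] = ExpressionMatrix(
            design.dataset_id, design.cell_type, tuple(probe_ids), ids, values
        )

    annotations = _draw_annotations(rng, config, probe_ids, de_idx)

    truth = CohortTruth(
        de_probes=tuple(probe_ids[i] for i in de_idx),
        concordant_probes=tuple(probe_ids[i] for i in conc_idx),
        log2_effects={probe_ids[i]: float(effects[i]) for i in de_idx},
    )
    logger.info(
        "generated cohort: %d probes, %d differential, %d concordant, %d datasets",
        n, config.n_de, n_conc, len(config.designs),
    )
    return Cohort(matrices, tuple(metadata.values()), annotations, truth, config)


def _draw_annotations(rng, config, probe_ids, de_idx):
    n = len(probe_ids)
    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True
    gene_symbols = [f"GENE{i:05d}" for i in range(n)]
    annotations = []
    vocab = list(VOCABULARY)
    for i in range(n):
        if is_de[i]:
            if rng.random() < config.out_of_vocab_fraction:
                category = OUT_OF_VOCAB_CATEGORY
            else:
                category = vocab[int(rng.integers(len(vocab)))]
        else:
            if rng.random() >= config.background_annotated_fraction:
                continue
            pool = vocab + [OUT_OF_VOCAB_CATEGORY]
            category = pool[int(rng.integers(len(pool)))]
        annotations.append(FunctionAnnotation(probe_ids[i], gene_symbols[i], category))
    return tuple(annotations)


def write_cohort(cohort: Cohort, directory) -> Dict[str, Path]:
    """Materialize a cohort: one expression TSV per dataset, shared metadata
    and annotation tables, truth JSON, and a small manifest for reloading."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    manifest = {"datasets": {}}
    for dataset_id, matrix in cohort.matrices.items():
        path = directory / f"expression_{dataset_id}.tsv"
        io.write_expression_matrix(matrix, path)
        paths[f"expression_{dataset_id}"] = path
        manifest["datasets"][dataset_id] = {
            "cell_type": matrix.cell_type,
            "file": path.name,
        }
    paths["metadata"] = directory / "metadata.tsv"
    io.write_metadata(cohort.metadata, paths["metadata"])
    paths["annotations"] = directory / "annotations.tsv"
    io.write_annotations(cohort.annotations, paths["annotations"])
    paths["truth"] = directory / "truth.json"
    io.write_json(
        {
            "de_probes": list(cohort.truth.de_probes),
            "concordant_probes": list(cohort.truth.concordant_probes),
            "log2_effects": dict(cohort.truth.log2_effects),
        },
        paths["truth"],
    )
    paths["manifest"] = directory / "cohort.json"
    io.write_json(manifest, paths["manifest"])
    return paths


def read_cohort(directory):
    """Reload the matrices/metadata/annotations written by :func:`write_cohort`.

    Returns ``(matrices, metadata, annotations)``; the truth JSON is not
    required (real cohorts have none).
    """
    directory = Path(directory)
    manifest = io.read_json(directory / "cohort.json")
    matrices = {
        dataset_id: io.read_expression_matrix(
            directory / entry["file"], dataset_id, entry["cell_type"]
        )
        for dataset_id, entry in manifest["datasets"].items()
    }
    metadata = io.read_metadata(directory / "metadata.tsv")
    annotations = io.read_annotations(directory / "annotations.tsv")
    return matrices, metadata, annotations


def null_config(**overrides) -> CohortConfig:
    """Convenience: a cohort with no differential probes (pure null)."""
    base = CohortConfig(n_de=0)
    return replace(base, **overrides)
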