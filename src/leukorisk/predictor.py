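"""Stage 3: the multivariate risk model.

Expression is standardized within each gene *per set* (each dataset was
produced under its own experimental settings, so train and test sets are
standardized independently), reduced to the top three principal components
of the panel, and classified with a two-class Gaussian linear discriminant.
The model output is the posterior probability of the high-risk class, a
continuous score in [0, 1].

PCA is computed on the standardized matrix (equivalently, correlation PCA)
with samples as observations and panel probes as variables; the component
count is fixed at three, with a logged warning when they explain <= 70% of
the variance. LDA uses the two class means, the pooled within-class
covariance, and equal priors by default ("equal weights" for false
positives and false negatives); class-frequency priors are available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from .datamodel import ExpressionMatrix, SampleMetadata, risk_labels
from .io import read_json, write_json
from .triage import BiomarkerPanel

logger = logging.getLogger(__name__)

N_COMPONENTS = 3
EXPLAINED_WARN_THRESHOLD = 0.70
RIDGE_FACTOR = 1e-6


@dataclass(frozen=True)
class PCAModel:
    panel_probe_ids: Tuple[str, ...]
    loadings: np.ndarray  # probes x 3, orthonormal columns
    explained_variance_fraction: np.ndarray  # length 3, non-increasing
    n_components: int = N_COMPONENTS


@dataclass(frozen=True)
class LDAModel:
    class_labels: Tuple[str, str]  # (low, high)
    class_means: np.ndarray  # 2 x 3, rows follow class_labels
    pooled_covariance: np.ndarray  # 3 x 3 symmetric positive-definite
    priors: np.ndarray  # length 2, sums to 1


@dataclass(frozen=True)
class RiskScore:
    sample_id: str
    posterior_high: float


@dataclass(frozen=True)
class TrainedPredictor:
    panel: BiomarkerPanel
    pca: PCAModel
    lda: LDAModel
    training_dataset_id: str


def standardize_within_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each probe row to mean 0, sd 1 (ddof=1) within the set.

    Constant rows become all-zero with a warning; idempotent up to floating
    point.
    """
    if matrix.n_samples < 2:
        raise ValueError("standardization needs at least 2 samples")
    values = matrix.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant probes standardized to zero",
            RuntimeWarning,
            stacklevel=2,
        )
    sd[sd == 0] = 1.0
    out = (values - mean) / sd
    out[constant, :] = 0.0
    return ExpressionMatrix(
        matrix.dataset_id, matrix.cell_type, matrix.probe_ids, matrix.sample_ids, out
    )


def fit_pca(std_matrix: ExpressionMatrix, n_components: int = N_COMPONENTS) -> PCAModel:
    """Top principal components of the standardized panel matrix.

    Observations are samples, variables are probes. Loadings are the leading
    right singular vectors of the (centered) samples x probes matrix; each
    column's sign is fixed so its largest-magnitude entry is positive.
    """
    if std_matrix.n_probes < n_components:
        raise ValueError(
            f"panel has {std_matrix.n_probes} probes; need >= {n_components}"
        )
    if std_matrix.n_samples < 4:
        raise ValueError("PCA needs at least 4 samples")
    x = std_matrix.values.T  # samples x probes
    xc = x - x.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0:
        raise ValueError("standardized matrix has no variance")
    loadings = vt[:n_components].T.copy()
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
    explained = (s[:n_components] ** 2) / total
    if float(explained.sum()) <= EXPLAINED_WARN_THRESHOLD:
        logger.warning(
            "top %d components explain only %.1f%% of variance (<= 70%%)",
            n_components, 100 * float(explained.sum()),
        )
    return PCAModel(
        panel_probe_ids=std_matrix.probe_ids,
        loadings=loadings,
        explained_variance_fraction=explained,
        n_components=n_components,
    )


def pca_scores(pca: PCAModel, std_matrix: ExpressionMatrix) -> np.ndarray:
    """Project a standardized matrix onto the loadings -> samples x k scores.

    Standardized rows have mean zero, so no further centering is applied and
    train/test projections are symmetric.
    """
    if std_matrix.probe_ids != pca.panel_probe_ids:
        raise ValueError("matrix probes do not match the PCA panel (order matters)")
    return std_matrix.values.T @ pca.loadings


def fit_lda(
    pc_scores: np.ndarray,
    labels_high: Sequence[bool],
    priors: str = "equal",
) -> LDAModel:
    """Two-class Gaussian LDA: class means + pooled within-class covariance.

    A near-singular covariance is ridge-regularized by ``1e-6 * trace / k``
    with a logged message.
    """
    x = np.asarray(pc_scores, dtype=float)
    y = np.asarray(labels_high, dtype=bool)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("pc_scores must be samples x k aligned with labels")
    n_high, n_low = int(y.sum()), int((~y).sum())
    if n_high < 2 or n_low < 2:
        raise ValueError("each class needs at least 2 samples")
    k = x.shape[1]
    mu_low = x[~y].mean(axis=0)
    mu_high = x[y].mean(axis=0)
    resid_low = x[~y] - mu_low
    resid_high = x[y] - mu_high
    cov = (resid_low.T @ resid_low + resid_high.T @ resid_high) / (y.size - 2)
    cov = (cov + cov.T) / 2.0
    trace = float(np.trace(cov))
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 1e-10 * max(trace, 1e-300):
        eps = RIDGE_FACTOR * trace / k if trace > 0 else RIDGE_FACTOR
        logger.warning("singular pooled covariance; adding ridge epsilon %.3g", eps)
        cov = cov + eps * np.eye(k)
    if priors == "equal":
        prior = np.array([0.5, 0.5])
    elif priors == "frequency":
        prior = np.array([n_low, n_high], dtype=float) / y.size
    else:
        raise ValueError(f"unknown priors mode {priors!r}")
    return LDAModel(
        class_labels=("low", "high"),
        class_means=np.vstack([mu_low, mu_high]),
        pooled_covariance=cov,
        priors=prior,
    )


def lda_posterior(lda: LDAModel, pc_scores: np.ndarray) -> np.ndarray:
    """Posterior probability of the high-risk class for each score row.

    With a shared covariance the log posterior odds are linear in x:
    ``log P(high|x)/P(low|x) = (mu_h - mu_l)' S^-1 x
    - (mu_h' S^-1 mu_h - mu_l' S^-1 mu_l)/2 + log(pi_h/pi_l)``.
    """
    x = np.atleast_2d(np.asarray(pc_scores, dtype=float))
    mu_low, mu_high = lda.class_means
    chol = cho_factor(lda.pooled_covariance)
    w = cho_solve(chol, mu_high - mu_low)
    bias = -0.5 * (mu_high + mu_low) @ w + np.log(lda.priors[1] / lda.priors[0])
    return expit(x @ w + bias)


def train_predictor(
    matrix: ExpressionMatrix,
    metadata: Iterable[SampleMetadata],
    panel: BiomarkerPanel,
    priors: str = "equal",
    n_components: int = N_COMPONENTS,
) -> TrainedPredictor:
    """Standardize -> PCA -> LDA on the training set restricted to the panel."""
    metadata = list(metadata)
    std = standardize_within_genes(matrix.subset_probes(panel.probe_ids))
    pca = fit_pca(std, n_components)
    scores = pca_scores(pca, std)
    labels = risk_labels(metadata, std.sample_ids)
    lda = fit_lda(scores, labels, priors)
    return TrainedPredictor(
        panel=panel, pca=pca, lda=lda, training_dataset_id=matrix.dataset_id
    )


def predict_scores(predictor: TrainedPredictor, test: ExpressionMatrix) -> List[RiskScore]:
    """Score an independent set: standardize within the test set, project
    onto the training loadings, apply the Gaussian posterior."""
    sub = test.subset_probes(predictor.panel.probe_ids)  # raises listing missing
    std = standardize_within_genes(sub)
    scores = pca_scores(predictor.pca, std)
    posterior = lda_posterior(predictor.lda, scores)
    return [
        RiskScore(sample_id=s, posterior_high=float(p))
        for s, p in zip(std.sample_ids, posterior)
    ]


# -- serialization -------------------------------------------------------

def save_predictor(predictor: TrainedPredictor, path) -> None:
    write_json(
        {
            "panel": {
                "probe_ids": list(predictor.panel.probe_ids),
                "source": predictor.panel.source,
                "training_dataset_id": predictor.panel.training_dataset_id,
                "description": predictor.panel.description,
            },
            "pca": {
                "loadings": predictor.pca.loadings.tolist(),
                "explained_variance_fraction":
                    predictor.pca.explained_variance_fraction.tolist(),
                "n_components": predictor.pca.n_components,
            },
            "lda": {
                "class_labels": list(predictor.lda.class_labels),
                "class_means": predictor.lda.class_means.tolist(),
                "pooled_covariance": predictor.lda.pooled_covariance.tolist(),
                "priors": predictor.lda.priors.tolist(),
            },
            "training_dataset_id": predictor.training_dataset_id,
        },
        path,
    )


def load_predictor(path) -> TrainedPredictor:
    blob = read_json(path)
    panel = BiomarkerPanel(
        probe_ids=tuple(blob["panel"]["probe_ids"]),
        source=blob["panel"]["source"],
        training_dataset_id=blob["panel"]["training_dataset_id"],
        description=blob["panel"].get("description", ""),
    )
    pca = PCAModel(
        panel_probe_ids=panel.probe_ids,
        loadings=np.asarray(blob["pca"]["loadings"], dtype=float),
        explained_variance_fraction=np.asarray(
            blob["pca"]["explained_variance_fraction"], dtype=float
        ),
        n_components=int(blob["pca"]["n_components"]),
    )
    lda = LDAModel(
        class_labels=tuple(blob["lda"]["class_labels"]),
        class_means=np.asarray(blob["lda"]["class_means"], dtype=float),
        pooled_covariance=np.asarray(blob["lda"]["pooled_covariance"], dtype=float),
        priors=np.asarray(blob["lda"]["priors"], dtype=float),
    )
    return TrainedPredictor(
        panel=panel, pca=pca, lda=lda,
        training_dataset_id=blob["training_dataset_id"],
    )
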