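"""Nearest-centroid rank-correlation classifier of spatial phenotypes.

The classifier is built from a discovery cohort whose samples carry a
staining-derived spatial phenotype (excluded / ignored / inflamed):

1. *Gene selection.* A gene becomes a classifier gene with signature
   phenotype ``p`` when its mean log2 expression in ``p`` exceeds the
   mean in *each* other phenotype by more than the log2-fold-change
   threshold (default 1.0), and both pairwise Welch two-sample tests are
   significant after Benjamini–Hochberg adjustment (adjusted per
   contrast across all genes, default alpha 0.05). A one-vs-rest
   contrast is available behind ``contrast="one-vs-rest"``.
2. *Centroids.* Per phenotype, classifier-gene expressions are averaged
   over that phenotype's samples and converted to ranks (average ranks
   for ties, ascending: highest expression gets the highest rank).
3. *Assignment.* An unknown sample is correlated (Spearman) against each
   phenotype's rank vector and assigned to the phenotype with the
   highest correlation. Samples whose top two correlations are equal
   within a tolerance are left unassigned ("correlation tie"), as are
   samples covering fewer than half of the classifier genes or with
   degenerate (all-tied) values.

Because assignment is rank-based, it is invariant under any strictly
increasing transform of a sample's values — the property that lets one
classifier transfer across expression platforms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .metrics import benjamini_hochberg
from .phenotypes import PHENOTYPES, UNASSIGNED

logger = logging.getLogger(__name__)


class ClassifierBuildError(ValueError):
    """Raised when a classifier cannot be built from the discovery data."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable parameters of gene selection and assignment."""

    logfc_threshold: float = 1.0
    alpha: float = 0.05
    tie_epsilon: float = 1e-12
    min_genes_per_phenotype: int = 1
    min_coverage: float = 0.5
    contrast: str = "all-pairwise"  # or "one-vs-rest"

    def __post_init__(self) -> None:
        if self.logfc_threshold <= 0:
            raise ValueError("logfc_threshold must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.tie_epsilon < 0:
            raise ValueError("tie_epsilon must be >= 0")
        if self.contrast not in ("all-pairwise", "one-vs-rest"):
            raise ValueError("contrast must be all-pairwise or one-vs-rest")


DEFAULT_CONFIG = ClassifierConfig()


@dataclass
class ClassifierModel:
    """Selected classifier genes with per-phenotype centroids and ranks.

    ``signature`` maps each classifier gene to exactly one phenotype;
    ``means`` and ``ranks`` are (gene x phenotype) DataFrames, the rank
    columns being average-rank transforms of the mean columns.
    """

    signature: pd.Series  # index gene_id -> phenotype
    means: pd.DataFrame  # genes x PHENOTYPES
    ranks: pd.DataFrame  # genes x PHENOTYPES

    @property
    def genes(self) -> list[str]:
        return list(self.signature.index)

    def to_frame(self) -> pd.DataFrame:
        """Serialize as the model table (TSV dialect)."""
        out = pd.DataFrame({"signature_phenotype": self.signature})
        for p in PHENOTYPES:
            out[f"mean_{p}"] = self.means[p]
        for p in PHENOTYPES:
            out[f"rank_{p}"] = self.ranks[p]
        out.index.name = "gene_id"
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ClassifierModel":
        means = frame[[f"mean_{p}" for p in PHENOTYPES]].copy()
        means.columns = list(PHENOTYPES)
        ranks = frame[[f"rank_{p}" for p in PHENOTYPES]].copy()
        ranks.columns = list(PHENOTYPES)
        return cls(frame["signature_phenotype"].copy(), means, ranks)


@dataclass(frozen=True)
class AssignmentResult:
    """Per-sample classifier output."""

    sample_id: str
    correlations: dict[str, float]
    assigned: str  # phenotype label or "unassigned"
    reason: str | None = None


def _phenotype_columns(discovery: ExpressionMatrix) -> dict[str, np.ndarray]:
    labels = discovery.phenotype_labels()
    groups = {}
    for p in PHENOTYPES:
        idx = np.flatnonzero((labels == p).to_numpy())
        if len(idx) < 2:
            raise ClassifierBuildError(
                f"phenotype {p!r} has {len(idx)} samples; need >= 2"
            )
        groups[p] = idx
    return groups


def select_classifier_genes(
    discovery: ExpressionMatrix,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> pd.Series:
    """Select classifier genes and their signature phenotypes.

    Returns a Series mapping gene_id -> signature phenotype, ordered by
    phenotype then gene. Raises :class:`ClassifierBuildError` when any
    phenotype ends up with fewer than ``min_genes_per_phenotype`` genes.
    """
    groups = _phenotype_columns(discovery)
    X = discovery.values.to_numpy()
    means = {p: X[:, idx].mean(axis=1) for p, idx in groups.items()}

    # Welch t-test p-values per contrast, BH-adjusted across all genes
    # within each contrast.
    padj: dict[frozenset, np.ndarray] = {}
    if config.contrast == "all-pairwise":
        for i, p in enumerate(PHENOTYPES):
            for q in PHENOTYPES[i + 1:]:
                with np.errstate(invalid="ignore", divide="ignore"):
                    res = stats.ttest_ind(
                        X[:, groups[p]], X[:, groups[q]],
                        axis=1, equal_var=False,
                    )
                pvals = np.nan_to_num(res.pvalue, nan=1.0)
                padj[frozenset((p, q))] = benjamini_hochberg(pvals)
    else:  # one-vs-rest
        for p in PHENOTYPES:
            rest = np.concatenate(
                [groups[q] for q in PHENOTYPES if q != p]
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                res = stats.ttest_ind(
                    X[:, groups[p]], X[:, rest], axis=1, equal_var=False
                )
            pvals = np.nan_to_num(res.pvalue, nan=1.0)
            padj[frozenset((p, "rest"))] = benjamini_hochberg(pvals)

    selected: list[tuple[str, str]] = []
    genes = np.asarray(discovery.gene_ids)
    for p in PHENOTYPES:
        others = [q for q in PHENOTYPES if q != p]
        if config.contrast == "all-pairwise":
            mask = np.ones(len(genes), dtype=bool)
            for q in others:
                mask &= means[p] - means[q] > config.logfc_threshold
                mask &= padj[frozenset((p, q))] < config.alpha
        else:
            rest_idx = np.concatenate([groups[q] for q in others])
            rest_mean = X[:, rest_idx].mean(axis=1)
            mask = means[p] - rest_mean > config.logfc_threshold
            mask &= padj[frozenset((p, "rest"))] < config.alpha
        n_sel = int(mask.sum())
        if n_sel < config.min_genes_per_phenotype:
            raise ClassifierBuildError(
                f"phenotype {p!r} selected {n_sel} genes; need >= "
                f"{config.min_genes_per_phenotype}"
            )
        selected.extend((g, p) for g in genes[mask])

    # keep phenotype-block order; under one-vs-rest a gene can in
    # principle satisfy two contrasts — the first phenotype wins
    seen: dict[str, str] = {}
    for g, p in selected:
        if g in seen:
            logger.warning(
                "gene %s matched contrasts for %s and %s; keeping %s",
                g, seen[g], p, seen[g],
            )
            continue
        seen[g] = p
    return pd.Series(seen, name="signature_phenotype")


def build_model(
    discovery: ExpressionMatrix,
    signature: pd.Series,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> ClassifierModel:
    """Compute per-phenotype centroid means and rank vectors.

    Means are taken over each phenotype's discovery samples for the
    signature genes; ranks are average-rank transforms of each
    phenotype's mean vector (ascending: highest mean -> highest rank).
    """
    missing = [g for g in signature.index if g not in discovery.values.index]
    if missing:
        raise ClassifierBuildError(
            f"genes absent from discovery matrix: {missing[:5]}"
        )
    groups = _phenotype_columns(discovery)
    sub = discovery.values.loc[list(signature.index)]
    means = pd.DataFrame(
        {p: sub.iloc[:, idx].mean(axis=1) for p, idx in groups.items()}
    )[list(PHENOTYPES)]
    ranks = means.apply(lambda col: stats.rankdata(col), axis=0)
    return ClassifierModel(signature.copy(), means, ranks)


def train_classifier(
    discovery: ExpressionMatrix,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> ClassifierModel:
    """Convenience: gene selection followed by centroid construction."""
    return build_model(
        discovery, select_classifier_genes(discovery, config), config
    )


def spearman_rho(x, y) -> float:
    """Spearman correlation: Pearson on average-rank-transformed vectors.

    Returns NaN with a warning when either vector has zero variance
    after ranking (all values tied).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        warnings.warn(
            "spearman_rho undefined for an all-tied vector", stacklevel=2
        )
        return float("nan")
    rho = ((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy)
    return float(min(1.0, max(-1.0, rho)))


def assign_sample(
    model: ClassifierModel,
    sample_values: pd.Series,
    config: ClassifierConfig = DEFAULT_CONFIG,
    sample_id: str = "",
) -> AssignmentResult:
    """Assign one sample by its highest Spearman correlation.

    ``sample_values`` is indexed by gene id (classifier genes; extra
    genes are ignored, missing or NaN genes are dropped pairwise). The
    sample is left unassigned when fewer than ``min_coverage`` of the
    classifier genes are available, when all correlations are undefined,
    or when the top two correlations agree within ``tie_epsilon``.
    """
    present = sample_values.reindex(model.genes).dropna()
    coverage = len(present) / len(model.genes)
    if coverage < config.min_coverage:
        return AssignmentResult(
            sample_id, {}, UNASSIGNED,
            f"low coverage ({coverage:.0%} of classifier genes)",
        )
    rhos: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in PHENOTYPES:
            rhos[p] = spearman_rho(
                present.to_numpy(),
                model.ranks.loc[present.index, p].to_numpy(),
            )
    finite = {p: r for p, r in rhos.items() if np.isfinite(r)}
    if not finite:
        return AssignmentResult(
            sample_id, rhos, UNASSIGNED, "degenerate sample (all ranks tied)"
        )
    ordered = sorted(finite.items(), key=lambda kv: kv[1], reverse=True)
    if len(ordered) > 1 and ordered[0][1] - ordered[1][1] <= config.tie_epsilon:
        return AssignmentResult(sample_id, rhos, UNASSIGNED, "correlation tie")
    return AssignmentResult(sample_id, rhos, ordered[0][0], None)


@dataclass
class CohortAssignment:
    """Cohort-level assignment with phenotype proportions."""

    results: list[AssignmentResult]
    proportions: dict[str, float]
    n_assigned: int
    n_unassigned: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {"sample_id": r.sample_id, "assigned": r.assigned,
                   "reason": r.reason or ""}
            for p in PHENOTYPES:
                row[f"rho_{p}"] = r.correlations.get(p, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


def assign_cohort(
    model: ClassifierModel,
    cohort: ExpressionMatrix,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> CohortAssignment:
    """Assign every sample of a cohort and summarize proportions.

    Unassigned samples are reported but excluded from the phenotype
    proportions (with a logged count).
    """
    results = [
        assign_sample(model, cohort.values[sid], config, sample_id=sid)
        for sid in cohort.sample_ids
    ]
    assigned = [r.assigned for r in results if r.assigned != UNASSIGNED]
    n_un = len(results) - len(assigned)
    if n_un:
        logger.info("%d of %d samples left unassigned", n_un, len(results))
    total = len(assigned)
    proportions = {
        p: (assigned.count(p) / total if total else float("nan"))
        for p in PHENOTYPES
    }
    return CohortAssignment(results, proportions, total, n_un)
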