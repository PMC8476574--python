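"""Synthetic data generators for the spatial-immunophenotype pipeline.

Every downstream stage (density phenotyping, gene classifier, clinical
evaluation, TCR metrics) can be exercised without any real cohort: this
module generates

* expression cohorts with phenotype-specific marker genes over Gaussian
  log2-scale noise,
* stamp-based cell point patterns (homogeneous Poisson per stamp) whose
  CD8 border/center densities follow the three phenotype archetypes,
* clonally skewed TCR repertoires (symmetric Dirichlet proportions,
  multinomial read counts),
* phenotype-dependent anti-PD1 response labels.

All generators are pure functions of their configuration plus an explicit
integer seed (``numpy.random.default_rng``); no global RNG state is used.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .phenotypes import PHENOTYPES, validate_phenotype
from .repertoire import TCRRepertoire
from .spatial import STAMP_GEOMETRY

logger = logging.getLogger(__name__)

#: Gene-name prefixes per phenotype for planted marker genes.
_MARKER_PREFIX = {"excluded": "EXC", "ignored": "IGN", "inflamed": "INF"}

#: Demo relabeling of the first marker genes with genes reported high in
#: each phenotype (stromal/matrix genes for excluded, S100A7 for ignored,
#: T cell effector chemokines/granzymes for inflamed). For demos only.
DEMO_GENE_NAMES = {
    "excluded": ["COL10A1", "THBS2", "ASPN", "COL5A1", "GREM1", "SPON1",
                 "FAP", "SPOCK1"],
    "ignored": ["S100A7"],
    "inflamed": ["CXCL13", "CCL5", "GZMB", "WARS", "TRBC1", "CORO1A",
                 "CCL18", "IL2RG", "NKG7", "IGHG1"],
}

#: CD8 archetype intensities in cells/mm^2 as (border, center); chosen so
#: the density thresholds (200 at border, 150 low, ratio 10) recover the
#: generating phenotype with margin.
ARCHETYPE_INTENSITIES: dict[str, dict[str, tuple[float, float]]] = {
    "excluded": {"CD8": (400.0, 10.0)},
    "ignored": {"CD8": (50.0, 30.0)},
    "inflamed": {"CD8": (400.0, 300.0)},
}

#: Default response probabilities per phenotype: 6/10 responders among
#: inflamed, 4/39 among excluded+ignored (clinical-validation table rates).
DEFAULT_RESPONSE_RATES: dict[str, float] = {
    "excluded": 4.0 / 39.0,
    "ignored": 4.0 / 39.0,
    "inflamed": 6.0 / 10.0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration for :func:`generate_expression_cohort`.

    ``effect_size`` is the log2-fold-change of a marker gene in its own
    phenotype over the constant baseline; ``effect_size=0`` gives a null
    cohort in which markers and noise genes are indistinguishable.
    """

    n_per_phenotype: int = 30
    n_marker_genes_per_phenotype: int = 20
    n_noise_genes: int = 500
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_phenotype < 1:
            raise ValueError("n_per_phenotype must be >= 1")
        if self.n_marker_genes_per_phenotype < 1:
            raise ValueError("n_marker_genes_per_phenotype must be >= 1")
        if self.n_noise_genes < 0:
            raise ValueError("n_noise_genes must be >= 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def generate_expression_cohort(
    config: SimulationConfig, demo_gene_names: bool = False
) -> ExpressionMatrix:
    """Simulate a balanced, phenotype-labeled log2 expression cohort.

    Each phenotype contributes ``n_per_phenotype`` samples and owns
    ``n_marker_genes_per_phenotype`` marker genes whose mean is
    ``baseline + effect_size`` in that phenotype and ``baseline``
    elsewhere; noise genes have mean ``baseline`` everywhere. All values
    are mean + N(0, noise_sd) on the log2 scale.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_marker_genes_per_phenotype

    gene_ids: list[str] = []
    for phen in PHENOTYPES:
        names = [f"{_MARKER_PREFIX[phen]}_{i + 1:03d}" for i in range(k)]
        if demo_gene_names:
            demo = DEMO_GENE_NAMES[phen]
            names[: len(demo)] = demo[:k]
        gene_ids.extend(names)
    gene_ids.extend(
        f"NOISE_{i + 1:04d}" for i in range(config.n_noise_genes)
    )

    n = config.n_per_phenotype
    sample_ids = [f"S{i + 1:04d}" for i in range(3 * n)]
    labels = np.repeat(PHENOTYPES, n)

    means = np.full((len(gene_ids), 3 * n), config.baseline)
    for p_idx, phen in enumerate(PHENOTYPES):
        row_idx = np.arange(p_idx * k, (p_idx + 1) * k)
        col_idx = np.flatnonzero(labels == phen)
        means[np.ix_(row_idx, col_idx)] = config.baseline + config.effect_size

    values = means + rng.normal(0.0, config.noise_sd, means.shape)
    ann = pd.DataFrame(
        {"stained_phenotype": labels}, index=pd.Index(sample_ids)
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), ann
    )


def generate_cell_pattern(
    phenotype: str | None = None,
    n_stamps_border: int = 8,
    n_stamps_center: int = 8,
    marker_intensities: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    sample_id: str = "SYN001",
) -> pd.DataFrame:
    """Simulate a stamp-based cell table as a homogeneous Poisson pattern.

    For each marker and each stamp the cell count is Poisson with mean
    intensity x stamp area (0.670 x 0.502 mm^2) and coordinates are
    uniform over the stamp; stamps are disjoint fields of view with local
    origins. ``marker_intensities`` maps marker -> (border, center)
    intensity in cells/mm^2; if omitted, the CD8 archetype of
    ``phenotype`` is used. Tumor/stroma compartments are assigned 50/50
    at random.
    """
    if marker_intensities is None:
        if phenotype is None:
            raise ValueError("provide phenotype or marker_intensities")
        marker_intensities = ARCHETYPE_INTENSITIES[validate_phenotype(phenotype)]
    for marker, (b, c) in marker_intensities.items():
        if b < 0 or c < 0:
            raise ValueError(f"negative intensity for marker {marker!r}")
    if n_stamps_border < 1 or n_stamps_center < 1:
        raise ValueError("stamp counts must be >= 1")

    rng = np.random.default_rng(seed)
    area = STAMP_GEOMETRY.area_mm2
    w, h = STAMP_GEOMETRY.width_um, STAMP_GEOMETRY.height_um

    rows: list[pd.DataFrame] = []
    regions = [("border", n_stamps_border), ("center", n_stamps_center)]
    for marker, (int_border, int_center) in sorted(marker_intensities.items()):
        for (region, n_stamps), intensity in zip(
            regions, (int_border, int_center)
        ):
            for s in range(n_stamps):
                count = rng.poisson(intensity * area)
                if count == 0:
                    continue
                rows.append(
                    pd.DataFrame(
                        {
                            "sample_id": sample_id,
                            "stamp_id": f"{region}_{s + 1:02d}",
                            "region": region,
                            "compartment": rng.choice(
                                ["tumor", "stroma"], size=count
                            ),
                            "marker": marker,
                            "x_um": rng.uniform(0.0, w, count),
                            "y_um": rng.uniform(0.0, h, count),
                        }
                    )
                )
    columns = [
        "sample_id", "stamp_id", "region", "compartment",
        "marker", "x_um", "y_um",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.concat(rows, ignore_index=True)[columns]


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def generate_tcr_repertoire(
    n_clonotypes: int,
    total_reads: int,
    concentration: float,
    seed: int = 0,
) -> TCRRepertoire:
    """Simulate a clonally skewed TCR-Vbeta repertoire.

    Clonotype proportions are drawn from a symmetric Dirichlet with the
    given concentration (small concentration -> highly skewed, large ->
    near-uniform), read counts are multinomial with ``total_reads``
    draws. Clonotypes that receive zero reads are dropped with a logged
    count. Each clonotype gets a synthetic CDR3 amino-acid string.
    """
    if n_clonotypes < 1:
        raise ValueError("n_clonotypes must be >= 1")
    if total_reads < n_clonotypes:
        raise ValueError("total_reads must be >= n_clonotypes")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")

    rng = np.random.default_rng(seed)
    props = rng.dirichlet(np.full(n_clonotypes, concentration))
    counts = rng.multinomial(total_reads, props)

    ids = [f"CL{i + 1:05d}" for i in range(n_clonotypes)]
    cdr3 = [
        "CASS" + "".join(rng.choice(_AA, rng.integers(4, 9))) + "EQYF"
        for _ in range(n_clonotypes)
    ]
    keep = counts > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropped %d clonotypes with zero sampled reads", n_dropped
        )
    return TCRRepertoire(
        counts=pd.Series(
            counts[keep], index=pd.Index(np.array(ids)[keep], name="clonotype_id")
        ),
        cdr3=pd.Series(
            np.array(cdr3)[keep], index=pd.Index(np.array(ids)[keep], name="clonotype_id")
        ),
    )


def attach_response_labels(
    cohort: ExpressionMatrix,
    p_response_by_phenotype: dict[str, float] | None = None,
    seed: int = 0,
) -> ExpressionMatrix:
    """Add a Bernoulli anti-PD1 ``response`` annotation per sample.

    Response probability depends on the sample's ``stained_phenotype``;
    defaults are the clinical-validation rates (0.6 for inflamed,
    4/39 for excluded and ignored).
    """
    if p_response_by_phenotype is None:
        p_response_by_phenotype = DEFAULT_RESPONSE_RATES
    for phen, p in p_response_by_phenotype.items():
        validate_phenotype(phen)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for {phen!r} outside [0, 1]")

    labels = cohort.phenotype_labels()
    if labels.isna().any():
        raise ValueError("samples with missing stained_phenotype")

    rng = np.random.default_rng(seed)
    probs = labels.map(p_response_by_phenotype)
    if probs.isna().any():
        missing = sorted(labels[probs.isna()].unique())
        raise ValueError(f"no response probability for phenotypes {missing}")
    draws = rng.random(len(probs)) < probs.to_numpy()
    ann = cohort.annotations.copy()
    ann["response"] = np.where(draws, "responder", "nonresponder")
    return ExpressionMatrix(cohort.values.copy(), ann)
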