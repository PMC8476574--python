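"""In-memory containers for expression cohorts.

The package works on three tabular objects: an expression matrix
(genes x samples, log2 scale) with per-sample annotations, a cell table
(one row per segmented cell from multiplexed imaging), and a TCR clonotype
count table. The latter two are plain :class:`pandas.DataFrame` /
dataclasses defined in their home modules; the expression matrix gets a
thin validated wrapper here because it is shared between the generator,
the classifier and the evaluation code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values with per-sample annotations.

    Parameters
    ----------
    values
        DataFrame of shape (n_genes, n_samples); index = gene ids,
        columns = sample ids, all values finite, log2 scale.
    annotations
        DataFrame indexed by sample id. Recognised optional columns:
        ``stained_phenotype`` (excluded/ignored/inflamed, from CD8
        staining), ``response`` (responder/nonresponder to anti-PD1),
        ``cohort`` (free-form tag).
    """

    values: pd.DataFrame
    annotations: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=self.values.columns)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        vals = self.values.to_numpy()
        if vals.size and not np.isfinite(vals).all():
            raise ValueError("expression matrix contains non-finite values")
        missing = self.values.columns.difference(self.annotations.index)
        if len(missing):
            raise ValueError(
                f"samples missing from annotations: {list(missing)[:5]}"
            )
        # keep annotation rows aligned with the sample order
        self.annotations = self.annotations.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def phenotype_labels(self) -> pd.Series:
        """Per-sample stained phenotype; raises if the column is absent."""
        if "stained_phenotype" not in self.annotations:
            raise ValueError("cohort has no stained_phenotype annotations")
        return self.annotations["stained_phenotype"]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(sample_ids)],
            self.annotations.loc[list(sample_ids)].copy(),
        )
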