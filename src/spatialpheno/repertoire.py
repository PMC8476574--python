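"""TCR repertoire clonality metrics from clonotype count tables.

A repertoire is a mapping clonotype -> read count (e.g. a MiXCR-style
TCR-Vbeta clonotype export). Two summary statistics are provided:

* *skewness* — the Gini–Simpson index ``1 - sum(p_i^2)`` over clonotype
  proportions: 0 for a monoclonal repertoire, approaching ``1 - 1/K``
  when all K clonotypes are equally abundant. Higher values mean a more
  even repertoire; clonal expansion lowers the index. An optional
  small-sample bias correction (``N/(N-1)`` rescaling) is available.
* *diversity* — the number of distinct clonotypes with at least one
  read (total reads are exposed separately).

Clonotype identity is taken from the id column as provided; collapsing
rules belong to the upstream aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class TCRRepertoire:
    """Clonotype read counts with optional CDR3 amino-acid strings."""

    counts: pd.Series  # index clonotype_id -> positive int
    cdr3: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate clonotype ids")
        if len(self.counts) and (self.counts <= 0).any():
            raise ValueError("clonotype counts must be >= 1")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def n_clonotypes(self) -> int:
        return int(len(self.counts))


def gini_simpson(rep: TCRRepertoire, bias_corrected: bool = False) -> float:
    """Gini–Simpson skewness index of a repertoire, in [0, 1).

    ``1 - sum(p_i^2)`` with p_i the clonotype read proportions. With
    ``bias_corrected=True`` the unbiased estimator
    ``N/(N-1) * (1 - sum(p_i^2))`` is returned instead.
    """
    if rep.n_clonotypes == 0:
        raise ValueError("empty repertoire")
    p = rep.counts.to_numpy(dtype=float)
    p = p / p.sum()
    index = 1.0 - float(np.square(p).sum())
    if bias_corrected:
        n = rep.total_reads
        if n < 2:
            raise ValueError("bias correction needs >= 2 reads")
        index *= n / (n - 1.0)
    return index


def tcr_diversity(rep: TCRRepertoire) -> int:
    """Number of distinct clonotypes with at least one read."""
    if rep.n_clonotypes == 0:
        logger.warning("empty repertoire has zero diversity")
        return 0
    return int((rep.counts >= 1).sum())


def read_repertoire(path) -> TCRRepertoire:
    """Read the clonotype TSV dialect (clonotype_id, cdr3_aa, count)."""
    df = pd.read_csv(path, sep="\t")
    required = {"clonotype_id", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"repertoire table needs columns {sorted(required)}")
    counts = df.set_index("clonotype_id")["count"].astype(int)
    cdr3 = (
        df.set_index("clonotype_id")["cdr3_aa"]
        if "cdr3_aa" in df.columns else None
    )
    return TCRRepertoire(counts=counts, cdr3=cdr3)


def write_repertoire(rep: TCRRepertoire, path) -> None:
    """Write the clonotype TSV dialect."""
    df = pd.DataFrame(
        {
            "clonotype_id": rep.counts.index,
            "cdr3_aa": (
                rep.cdr3.reindex(rep.counts.index).fillna("").to_numpy()
                if rep.cdr3 is not None else ""
            ),
            "count": rep.counts.to_numpy(),
        }
    )
    df.to_csv(path, sep="\t", index=False)
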