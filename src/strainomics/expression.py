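"""Container and TSV I/O for genes x samples log-expression studies."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ("strain", "time_h", "replicate")


@dataclass
class ExpressionStudy:
    """Log-scale expression matrix with sample and gene metadata.

    ``values``: DataFrame, genes x samples, no missing entries.
    ``samples``: DataFrame indexed by sample id with columns strain, time_h,
    replicate; every (strain, time_h) cell must hold >= 2 replicates so each
    replicate enters the analysis as an independent sample.
    ``genes``: DataFrame indexed by gene id with at least position_bp and
    strand; optional cog and core columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample sheet does not match matrix columns")
        if list(self.values.index) != list(self.genes.index):
            raise ValueError("gene sheet does not match matrix rows")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet lacks column {col!r}")
        counts = self.samples.groupby(["strain", "time_h"]).size()
        if (counts < 2).any():
            bad = counts[counts < 2].index[0]
            raise ValueError(f"fewer than 2 replicates at {bad}")

    @property
    def n_genes(self) -> int:
        return len(self.values)

    def subset_strain(self, strain: str) -> "ExpressionStudy":
        keep = self.samples.index[self.samples["strain"] == strain]
        return ExpressionStudy(
            values=self.values[keep], samples=self.samples.loc[keep], genes=self.genes
        )

    @property
    def times(self) -> np.ndarray:
        return self.samples["time_h"].to_numpy(dtype=float)

    def write(self, prefix) -> None:
        prefix = Path(prefix)
        self.values.to_csv(prefix.with_suffix(".matrix.tsv"), sep="\t")
        self.samples.to_csv(prefix.with_suffix(".samples.tsv"), sep="\t")
        self.genes.to_csv(prefix.with_suffix(".genes.tsv"), sep="\t")

    @classmethod
    def read(cls, prefix) -> "ExpressionStudy":
        prefix = Path(prefix)
        values = pd.read_csv(prefix.with_suffix(".matrix.tsv"), sep="\t", index_col=0)
        samples = pd.read_csv(prefix.with_suffix(".samples.tsv"), sep="\t", index_col=0)
        genes = pd.read_csv(prefix.with_suffix(".genes.tsv"), sep="\t", index_col=0)
        return cls(values=values, samples=samples, genes=genes)
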