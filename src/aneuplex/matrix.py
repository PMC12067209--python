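"""Genes x samples expression matrix with replicate grouping.

The container mirrors how this kind of data moves through RNA-seq work: a
genes-by-samples table of non-negative values (raw counts or normalised
expression) plus a sample sheet assigning every sample to the ``aneuploid``
or ``control`` group and a replicate index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ConfigurationError

__all__ = ["CountMatrix", "GROUPS"]

GROUPS = ("aneuploid", "control")


@dataclass(frozen=True)
class CountMatrix:
    """Expression values (genes x samples) with a sample sheet.

    ``values``: DataFrame indexed by gene_id, one column per sample.
    ``groups``: DataFrame indexed by sample_id with columns ``group``
    (``aneuploid``/``control``) and ``replicate`` (1-based int).
    """

    values: pd.DataFrame
    groups: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.groups.columns) < {"group", "replicate"}:
            raise ConfigurationError("sample sheet needs 'group' and 'replicate' columns")
        if set(self.values.columns) != set(self.groups.index):
            raise ConfigurationError("sample sheet does not match matrix columns")
        bad = set(self.groups["group"]) - set(GROUPS)
        if bad:
            raise ConfigurationError(f"unknown sample groups {sorted(bad)}")
        for g in GROUPS:
            if not (self.groups["group"] == g).any():
                raise ConfigurationError(f"no samples in group {g!r}")
        vals = self.values.to_numpy(float)
        if np.isnan(vals).any() or (vals < 0).any():
            raise ConfigurationError("expression values must be non-negative and not NaN")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups["group"] == group])

    @property
    def aneuploid(self) -> pd.DataFrame:
        return self.values[self.samples_in("aneuploid")]

    @property
    def control(self) -> pd.DataFrame:
        return self.values[self.samples_in("control")]

    def library_sizes(self) -> pd.Series:
        """Per-sample totals (mapped-read surrogates for normalisation)."""
        return self.values.sum(axis=0)

    def subset(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.values.loc[gene_ids], self.groups)

    # ---- TSV interface -------------------------------------------------------

    def to_tsv(self, counts_path, samples_path) -> None:
        """Write counts (gene_id + one column per sample) and sample sheet."""
        self.values.to_csv(counts_path, sep="\t", index_label="gene_id", float_format="%.10g")
        self.groups.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        values = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        groups = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        return cls(values, groups)
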