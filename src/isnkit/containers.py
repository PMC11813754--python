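"""Core data containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns the downstream stages may rely on; all optional except none.
KNOWN_METADATA = [
    "cohort", "disease", "therapy", "timepoint", "outcome",
    "age", "gender", "duration", "location",
    "microbial_load", "enterotype", "individual_id", "trajectory",
]


@dataclass
class CountMatrix:
    """Samples x taxa count table with taxonomy and per-sample metadata.

    counts
        DataFrame, rows = samples, columns = taxa, non-negative values.
        Integer for raw/rarefied profiles; QMP output (cells/g) is real-valued.
    taxonomy
        DataFrame indexed by taxon with at least ``family`` and ``genus``;
        ``copy_number`` (16S rRNA gene copies) is required only for QMP.
    metadata
        DataFrame indexed by sample id; one row per sample in ``counts``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame
    is_integer: bool = field(default=True)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if (self.counts.values < 0).any():
            bad = self.counts.columns[(self.counts.values < 0).any(axis=0)]
            raise ValueError(f"negative counts for taxa: {list(bad)[:5]}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()]
            raise ValueError(f"duplicate taxon ids: {sorted(set(dups))}")
        missing_meta = self.counts.index.difference(self.metadata.index)
        if len(missing_meta):
            raise ValueError(f"samples without metadata: {list(missing_meta)[:5]}")
        missing_tax = self.counts.columns.difference(self.taxonomy.index)
        if len(missing_tax):
            raise ValueError(f"taxa without taxonomy: {list(missing_tax)[:5]}")
        if self.is_integer:
            vals = self.counts.values
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("non-integer values in a count matrix marked integer")

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    @property
    def taxa(self) -> pd.Index:
        return self.counts.columns

    @property
    def depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[samples],
            self.taxonomy,
            self.metadata.loc[samples],
            is_integer=self.is_integer,
        )

    def subset_taxa(self, taxa) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(taxa)],
            self.taxonomy.loc[list(taxa)],
            self.metadata.loc[self.counts.index],
            is_integer=self.is_integer,
        )

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            self.counts.copy(), self.taxonomy.copy(), self.metadata.copy(),
            is_integer=self.is_integer,
        )
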