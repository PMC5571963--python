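"""Core data containers shared across the pipeline.

The pipeline's tabular objects are plain pandas structures with a documented
schema, wrapped in thin dataclasses only where two tables must travel
together (counts + sample metadata).

Schemas
-------
gene catalog : DataFrame indexed by gene id with columns
    ``cds_length`` (int, nucleotides, >= 1),
    ``loc_class``  (one of ``MPR``, ``CPR``, ``other``),
    ``feature_class`` (one of ``mRNA``, ``rRNA``, ``tRNA``, ``ncRNA``).
count matrix : genes x samples integer DataFrame plus a sample table indexed
    by sample id with columns ``fraction`` and ``replicate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOC_CLASSES = ("MPR", "CPR", "other")
FEATURE_CLASSES = ("mRNA", "rRNA", "tRNA", "ncRNA")


class ConsistencyError(ValueError):
    """Raised when two pipeline objects disagree about gene or sample ids."""


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene-catalog DataFrame and return it unchanged.

    Raises ``ValueError`` naming the offending column on any violation.
    """
    required = {"cds_length", "loc_class", "feature_class"}
    missing = required - set(catalog.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    if not catalog.index.is_unique:
        dup = catalog.index[catalog.index.duplicated()].tolist()
        raise ValueError(f"catalog gene ids not unique: {dup[:5]}")
    if (catalog["cds_length"] < 1).any():
        raise ValueError("cds_length: every CDS length must be >= 1 nt")
    bad_loc = set(catalog["loc_class"]) - set(LOC_CLASSES)
    if bad_loc:
        raise ValueError(f"loc_class: unknown labels {sorted(bad_loc)}")
    bad_feat = set(catalog["feature_class"]) - set(FEATURE_CLASSES)
    if bad_feat:
        raise ValueError(f"feature_class: unknown labels {sorted(bad_feat)}")
    return catalog


@dataclass
class CountMatrix:
    """Integer read counts per gene per library, with library metadata.

    Attributes
    ----------
    counts :
        genes x samples DataFrame of nonnegative integers.
    samples :
        per-sample metadata indexed by sample id with columns
        ``fraction`` (str) and ``replicate`` (int).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ConsistencyError(
                "count columns and sample metadata rows disagree: "
                f"{list(self.counts.columns)[:4]}... vs {list(self.samples.index)[:4]}..."
            )
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be nonnegative")
        if "fraction" not in self.samples.columns:
            raise ValueError("sample metadata must carry a 'fraction' column")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def check_catalog(self, catalog: pd.DataFrame) -> None:
        """Require every counted gene to be present in the catalog."""
        missing = self.counts.index.difference(catalog.index)
        if len(missing):
            raise ConsistencyError(
                f"{len(missing)} genes absent from catalog: {list(missing[:10])}"
            )

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[gene_ids], self.samples)


@dataclass
class EnrichmentTable:
    """Per-gene ratio of a fraction's RPKM to a reference sample's RPKM.

    ``ratios`` is a Series indexed by gene id; genes failing the detection
    filter are absent (never zero). ``dropped`` records why genes were
    excluded: a DataFrame (gene id index, column ``reason``).
    """

    ratios: pd.Series
    fraction: str
    reference: str
    min_rpkm: float
    dropped: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["reason"]))

    def __post_init__(self) -> None:
        if (self.ratios <= 0).any() or not np.isfinite(self.ratios).all():
            raise ValueError("enrichment ratios must be finite and positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.ratios.index
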