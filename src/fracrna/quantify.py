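"""Quantification: RPKM, enrichment ratios, and qPCR mass-balance portions.

The measurement units of the analysis:

* RPKM(g, s) = count(g, s) * 1e9 / (cds_length(g) * total_counts(s)),
  computed for mRNAs after removal of rRNA/tRNA/ncRNA-mapped reads, with
  the per-sample total taken over the retained mRNA rows (a flag restores
  the all-mapped-reads denominator).
* Enrichment of gene g in a fraction = RPKM_fraction(g) / RPKM_reference(g),
  the reference being the total extract (or the pull-down input). Genes
  not detected (RPKM below ``min_rpkm``) in either sample are dropped and
  reported, never imputed.
* qPCR: relative concentration fraction/extract = 2**(Ct_extract - Ct_fraction)
  (threshold cycle at 0.2 fluorescence units); the portion of a transcript
  in a fraction scales that by the fractions' RNA yields,
  portion = rel_conc * mass_fraction / mass_extract, optionally normalized
  to an endogenous control (RnpB or SsrA).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConsistencyError, CountMatrix, EnrichmentTable, validate_catalog

logger = logging.getLogger(__name__)


def filter_feature_classes(counts: CountMatrix, catalog: pd.DataFrame,
                           keep: str = "mRNA") -> CountMatrix:
    """Drop non-mRNA rows (rRNA, tRNA, other non-coding loci).

    Downstream RPKM totals are recomputed from the retained rows.
    """
    validate_catalog(catalog)
    counts.check_catalog(catalog)
    keep_ids = counts.gene_ids[
        catalog.loc[counts.gene_ids, "feature_class"] == keep
    ]
    if len(keep_ids) == 0:
        logger.warning("no %s rows retained: all features filtered out", keep)
    return counts.subset_genes(keep_ids)


def replicate_consistency(counts: CountMatrix, min_spearman: float = 0.9
                          ) -> pd.DataFrame:
    """Pairwise Spearman correlations between replicates of each fraction.

    Returns a table (fraction, sample_a, sample_b, spearman, consistent);
    pooling replicates below ``min_spearman`` should be reconsidered.
    """
    rows = []
    for fraction, group in counts.samples.groupby("fraction", sort=False):
        ids = list(group.index)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rho = stats.spearmanr(
                    counts.counts[ids[i]], counts.counts[ids[j]]).statistic
                rows.append((fraction, ids[i], ids[j], rho, rho >= min_spearman))
    return pd.DataFrame(
        rows, columns=["fraction", "sample_a", "sample_b", "spearman", "consistent"])


def pool_replicates(counts: CountMatrix, min_spearman: float = 0.9,
                    validate: bool = True) -> CountMatrix:
    """Sum replicate counts per fraction after a consistency check."""
    if validate and counts.samples["replicate"].max() > 1:
        qc = replicate_consistency(counts, min_spearman)
        bad = qc[~qc["consistent"]]
        if len(bad):
            logger.warning(
                "replicate pairs below Spearman %.2f: %s",
                min_spearman, bad[["sample_a", "sample_b"]].to_dict("records"))
    fractions = list(dict.fromkeys(counts.samples["fraction"]))
    pooled = pd.DataFrame(
        {f: counts.counts.loc[:, counts.samples["fraction"] == f].sum(axis=1)
         for f in fractions},
        index=counts.gene_ids,
    )
    samples = pd.DataFrame(
        {"fraction": fractions, "replicate": 1},
        index=pd.Index(fractions, name="sample_id"),
    )
    return CountMatrix(pooled, samples)


def compute_rpkm(counts: CountMatrix, catalog: pd.DataFrame,
                 totals: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase of CDS per million mapped reads.

    ``totals`` overrides the per-sample read totals (e.g. all mapped reads
    including non-mRNA); by default totals are the column sums of the
    (already filtered) matrix.
    """
    counts.check_catalog(catalog)
    if totals is None:
        totals = counts.counts.sum(axis=0)
    if (totals <= 0).any():
        zero = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero total counts: {zero}")
    lengths = catalog.loc[counts.gene_ids, "cds_length"].astype(float)
    rpkm = counts.counts.div(lengths, axis=0).div(totals, axis=1) * 1e9
    return rpkm


def enrichment_ratio(rpkm: pd.DataFrame, fraction: str, reference: str,
                     min_rpkm: float = 1.0) -> EnrichmentTable:
    """Per-gene fraction/reference RPKM ratio over detected genes.

    A gene is detected when its RPKM is at least ``min_rpkm`` in both the
    fraction and the reference; all other genes are dropped into the
    table's drop report with the failing side recorded.
    """
    if fraction == reference:
        raise ValueError("fraction and reference must differ")
    for label in (fraction, reference):
        if label not in rpkm.columns:
            raise KeyError(f"sample {label!r} not in RPKM table")
    f, r = rpkm[fraction], rpkm[reference]
    ok = (f >= min_rpkm) & (r >= min_rpkm)
    reasons = pd.Series(
        np.select(
            [(f < min_rpkm) & (r < min_rpkm), f < min_rpkm, r < min_rpkm],
            ["below_min_rpkm_both", "below_min_rpkm_fraction",
             "below_min_rpkm_reference"],
            default="",
        ),
        index=rpkm.index,
    )
    dropped = pd.DataFrame({"reason": reasons[~ok]})
    if not ok.any():
        raise ValueError(
            f"no gene passes the detection filter (min_rpkm={min_rpkm})")
    if len(dropped):
        logger.info("enrichment %s/%s: dropped %d of %d genes",
                    fraction, reference, len(dropped), len(rpkm))
    return EnrichmentTable(
        ratios=(f[ok] / r[ok]).rename("ratio"),
        fraction=fraction, reference=reference,
        min_rpkm=min_rpkm, dropped=dropped,
    )


def overlap_gene_set(tables: Sequence[EnrichmentTable],
                     catalog: pd.DataFrame | None = None) -> pd.Index:
    """Genes detected in every table (the shared landscape gene set)."""
    if not tables:
        raise ValueError("need at least one enrichment table")
    shared = tables[0].gene_ids
    for t in tables[1:]:
        shared = shared.intersection(t.gene_ids)
    if len(shared) == 0:
        logger.warning("overlap gene set is empty")
    if catalog is not None and len(shared):
        per_class = catalog.loc[shared, "loc_class"].value_counts().to_dict()
        logger.info("overlap set: %d genes (%s)", len(shared), per_class)
    return shared


def qpcr_relative_concentration(ct_extract: float, ct_fraction: float) -> float:
    """Fraction/extract concentration ratio, 2**(Ct_extract - Ct_fraction)."""
    if not (np.isfinite(ct_extract) and np.isfinite(ct_fraction)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (ct_extract - ct_fraction))


def qpcr_fraction_portion(rel_conc: float, rna_mass_fraction: float,
                          rna_mass_extract: float,
                          reference_rel_conc: float | None = None) -> float:
    """Portion of a transcript's molecules found in a fraction.

    ``portion = rel_conc * mass_fraction / mass_extract``; when the
    relative concentration of an endogenous control (RnpB/SsrA) in the
    same fraction is supplied, the transcript's rel_conc is divided by it
    first.
    """
    if rna_mass_fraction <= 0 or rna_mass_extract <= 0:
        raise ValueError("RNA masses must be > 0")
    if reference_rel_conc is not None:
        if reference_rel_conc <= 0:
            raise ValueError("reference relative concentration must be > 0")
        rel_conc = rel_conc / reference_rel_conc
    return float(rel_conc * rna_mass_fraction / rna_mass_extract)


def qpcr_portions(panel: pd.DataFrame, rna_mass: dict,
                  reference_gene: str | None = None) -> pd.DataFrame:
    """Per-gene per-fraction portions from a Ct table.

    ``panel`` has columns gene_id, sample, ct with one 'extract' row per
    gene. Returns genes x fractions portions. With ``reference_gene``
    (e.g. 'rnpB'), every gene's relative concentration is normalized to
    the control's in the same fraction.
    """
    wide = panel.pivot(index="gene_id", columns="sample", values="ct")
    if "extract" not in wide.columns:
        raise ValueError("panel lacks extract Cts")
    fractions = [c for c in wide.columns if c != "extract"]
    rel = pd.DataFrame(index=wide.index, columns=fractions, dtype=float)
    for f in fractions:
        rel[f] = 2.0 ** (wide["extract"] - wide[f])
    if reference_gene is not None:
        if reference_gene not in rel.index:
            raise KeyError(f"reference gene {reference_gene!r} not in panel")
        rel = rel.div(rel.loc[reference_gene], axis=1)
    out = pd.DataFrame(index=rel.index, columns=fractions, dtype=float)
    for f in fractions:
        if f not in rna_mass:
            raise ValueError(f"rna_mass missing fraction {f!r}")
        out[f] = rel[f] * rna_mass[f] / rna_mass["extract"]
    return out


def standard_curve_qc(dilution_log10: Iterable[float], cts: Iterable[float],
                      slope_range: tuple[float, float] = (-3.6, -3.0),
                      min_r2: float = 0.995) -> dict:
    """Primer-efficiency QC from a dilution series.

    Least-squares fit of Ct against log10 dilution; a primer pair passes
    with slope in [-3.6, -3] (perfect doubling gives -log2(10) = -3.32)
    and R^2 above 0.995.
    """
    x = np.asarray(list(dilution_log10), float)
    y = np.asarray(list(cts), float)
    if len(x) < 3:
        raise ValueError("standard curve needs at least 3 points")
    fit = stats.linregress(x, y)
    r2 = fit.rvalue ** 2
    passed = (slope_range[0] <= fit.slope <= slope_range[1]) and r2 > min_r2
    return {"slope": float(fit.slope), "r2": float(r2),
            "intercept": float(fit.intercept), "passed": bool(passed)}
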