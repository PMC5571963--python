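"""Readers and writers for the pipeline's plain-text formats.

TSV dialect: tab-separated, UTF-8, '#'-prefixed comment lines, mandatory
header. Floats are written at 6 significant digits. FASTA is read and
written through Biopython (wrapped at 60 columns). Motif sites are
exported as BED (0-based, half-open).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .core import CountMatrix, EnrichmentTable, validate_catalog
from .motifs import MotifSite, sites_to_bed

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------- reading

def read_catalog(path) -> pd.DataFrame:
    cat = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
    return validate_catalog(cat)


def read_counts(counts_path, samples_path) -> CountMatrix:
    """Read a genes x samples count TSV plus its sample-metadata TSV.

    Raises a parse error naming the first non-integer cell.
    """
    raw = pd.read_csv(counts_path, sep="\t", comment="#", index_col=0)
    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[vals.isna() | (vals != vals.round())]
        if len(bad):
            raise ValueError(
                f"{counts_path}: non-integer count at gene {bad[0]!r}, "
                f"sample {col!r}: {raw.loc[bad[0], col]!r}")
    samples = pd.read_csv(samples_path, sep="\t", comment="#",
                          index_col="sample_id")
    return CountMatrix(raw.astype(np.int64), samples)


def read_fasta(path, catalog: pd.DataFrame | None = None) -> dict[str, str]:
    """FASTA records as a gene id -> sequence map.

    Records absent from the catalog (when one is given) are ignored with a
    warning.
    """
    import logging
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if catalog is not None and rec.id not in catalog.index:
            logging.getLogger(__name__).warning(
                "FASTA record %s not in catalog: ignored", rec.id)
            continue
        seqs[rec.id] = str(rec.seq)
    return seqs


def read_gene_list(path) -> list[str]:
    """One gene id per line; '#' comments and blank lines ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_qpcr(path) -> pd.DataFrame:
    """qPCR Ct table: CSV with columns gene_id, sample, ct."""
    table = pd.read_csv(path, comment="#")
    missing = {"gene_id", "sample", "ct"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: qPCR table missing columns {sorted(missing)}")
    return table


def read_config(path) -> dict:
    """Plain key = value configuration; values parsed as JSON when possible."""
    cfg = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value'")
        key, _, value = line.partition("=")
        value = value.strip()
        try:
            cfg[key.strip()] = json.loads(value)
        except json.JSONDecodeError:
            cfg[key.strip()] = value
    return cfg


# ---------------------------------------------------------------- writing

def _to_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def write_catalog(catalog: pd.DataFrame, path) -> None:
    _to_tsv(catalog.rename_axis("gene_id"), path)


def write_counts(cm: CountMatrix, counts_path, samples_path) -> None:
    _to_tsv(cm.counts.rename_axis("gene_id"), counts_path)
    _to_tsv(cm.samples.rename_axis("sample_id"), samples_path)


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(list(records), str(path), "fasta")  # 60-column wrap


def write_enrichment(table: EnrichmentTable, path,
                     catalog: pd.DataFrame | None = None) -> None:
    df = table.ratios.rename("ratio").to_frame()
    if catalog is not None:
        df.insert(0, "loc_class", catalog.loc[df.index, "loc_class"])
    df["fraction"] = table.fraction
    df["reference"] = table.reference
    _to_tsv(df.rename_axis("gene_id"), path)


def write_drop_report(table: EnrichmentTable, path) -> None:
    _to_tsv(table.dropped.rename_axis("gene_id"), path)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_bed(sites: Iterable[MotifSite], path) -> None:
    bed = sites_to_bed(sites)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_truth_json(truth, path) -> None:
    """Serialize a SimTruth to JSON (baselines, multipliers, motif truth)."""
    payload = {
        "baseline": truth.baseline.to_dict(),
        "multipliers": {c: truth.multipliers[c].to_dict()
                        for c in truth.multipliers.columns},
    }
    if truth.portions is not None:
        payload["portions"] = {c: truth.portions[c].to_dict()
                               for c in truth.portions.columns}
    if truth.motif_counts is not None:
        payload["motif_counts"] = {c: truth.motif_counts[c].to_dict()
                                   for c in truth.motif_counts.columns}
    if truth.motif_sites is not None:
        payload["motif_sites"] = truth.motif_sites
    write_json(payload, path)
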