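"""Synthetic fractionation RNA-seq data with known ground truth.

Emulates the data a subcellular-fractionation experiment produces in
E. coli: triplicate sequencing libraries from the total extract and from
gradient / flotation fractions (ribosome-free, 70S, membrane, and a
pull-down input/elution pair), a qPCR panel over those fractions, and
coding sequences with planted CSP-recognition elements. Every generator
is seeded and returns the ground truth it planted, so parameter recovery
by the downstream quantification and statistics stages can be tested.

Count model
-----------
Reads per library are drawn per gene from a negative binomial with mean

    m_g = L * share * w_g / sum(w),   w_g = baseline_g * multiplier_g(f) * length_g

where ``L`` is the library size and ``share`` is the mRNA read share of the
fraction, 1 - rrna_load(f). Non-mRNA features (rRNA/tRNA/ncRNA catalog
rows) absorb the remaining ``rrna_load`` share, emulating the dominance of
ribosomal RNA in ribosome-containing fractions and its near-absence at the
top of the gradient. Variance is m + dispersion * m^2 (Poisson when
dispersion is 0).

Seeding: one master seed; each library draws from an independent
substream keyed by (seed, stream, fraction index, replicate), so adding a
library never perturbs the counts of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CountMatrix, ConsistencyError, validate_catalog
from .motifs import MotifRule, collapse_intervals, scan_sequence

DEFAULT_FRACTIONS = (
    "extract", "ribosome_free", "70S", "membrane",
    "pulldown_input", "pulldown_elution",
)

#: mRNA reads are scarce where ribosomes (rRNA) dominate the RNA mass and
#: plentiful at the ribosome-free top of the gradient.
DEFAULT_RRNA_LOAD = {
    "extract": 0.85,
    "ribosome_free": 0.15,
    "70S": 0.95,
    "membrane": 0.90,
    "pulldown_input": 0.15,
    "pulldown_elution": 0.30,
}


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Substream generator: deterministic in (seed, key...)."""
    return np.random.default_rng([int(seed), *map(int, key)])


@dataclass
class SimDesign:
    """Layout of a simulated fractionation experiment."""

    n_mpr: int = 200
    n_cpr: int = 800
    n_other: int = 20
    fractions: tuple[str, ...] = DEFAULT_FRACTIONS
    n_replicates: int = 3
    library_size: float = 5e6
    rrna_load: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_RRNA_LOAD))
    dispersion: float = 0.02
    seed: int = 0
    length_median: float = 900.0
    length_sigma: float = 0.55
    length_bounds: tuple[int, int] = (100, 6000)

    def __post_init__(self) -> None:
        for f in ("n_mpr", "n_cpr", "n_other"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.n_mpr + self.n_cpr + self.n_other < 1:
            raise ValueError("n_mpr + n_cpr + n_other: need at least one gene")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if "extract" not in self.fractions:
            raise ValueError("fractions must include 'extract'")
        for f in self.fractions:
            load = self.rrna_load_for(f)
            if not 0 <= load < 1:
                raise ValueError(f"rrna_load for {f!r} must be in [0, 1)")

    def rrna_load_for(self, fraction: str) -> float:
        if isinstance(self.rrna_load, Mapping):
            return float(self.rrna_load.get(fraction, 0.0))
        return float(self.rrna_load)


@dataclass
class SimTruth:
    """Ground truth planted by the generators.

    ``baseline`` is per-gene abundance in arbitrary concentration units;
    ``multipliers`` the genes x fractions true enrichment factors
    (identically 1 for the extract); ``portions`` per-gene per-fraction
    mass portions for qPCR; ``motif_counts``/``motif_sites`` planted motif
    ground truth per rule.
    """

    baseline: pd.Series
    multipliers: pd.DataFrame
    portions: pd.DataFrame | None = None
    motif_counts: pd.DataFrame | None = None
    motif_sites: dict | None = None

    def __post_init__(self) -> None:
        if (self.multipliers <= 0).any().any():
            raise ValueError("enrichment multipliers must be > 0")
        if "extract" in self.multipliers.columns:
            if not np.allclose(self.multipliers["extract"], 1.0):
                raise ValueError("extract multiplier must be identically 1")
        if self.portions is not None:
            if (self.portions < 0).any().any():
                raise ValueError("portions must be nonnegative")
            if (self.portions.sum(axis=1) > 1 + 1e-9).any():
                raise ValueError("portions must sum to <= 1 per gene")


def build_gene_catalog(design: SimDesign) -> pd.DataFrame:
    """Gene catalog for a design: ids, CDS lengths, localization classes.

    CDS lengths are log-normal with the design's median, clipped to the
    design bounds; non-mRNA features cycle through rRNA/tRNA/ncRNA.
    Deterministic in the design seed.
    """
    rng = _rng(design.seed, 0)
    ids, loc, feat = [], [], []
    for i in range(design.n_mpr):
        ids.append(f"mpr{i + 1:04d}"); loc.append("MPR"); feat.append("mRNA")
    for i in range(design.n_cpr):
        ids.append(f"cpr{i + 1:04d}"); loc.append("CPR"); feat.append("mRNA")
    nc_kinds = ("rRNA", "tRNA", "ncRNA")
    for i in range(design.n_other):
        ids.append(f"nc{i + 1:04d}"); loc.append("other")
        feat.append(nc_kinds[i % 3])
    n = len(ids)
    lengths = rng.lognormal(np.log(design.length_median), design.length_sigma, n)
    lengths = np.clip(np.round(lengths), *design.length_bounds).astype(int)
    catalog = pd.DataFrame(
        {"cds_length": lengths, "loc_class": loc, "feature_class": feat},
        index=pd.Index(ids, name="gene_id"),
    )
    return validate_catalog(catalog)


def make_truth(catalog: pd.DataFrame, design: SimDesign,
               class_effects: Mapping[str, Mapping[str, float]] | None = None,
               effect_sigma: float = 0.0,
               baseline_sigma: float = 1.0,
               closure: bool = True) -> SimTruth:
    """Construct ground truth with class-specific enrichment effects.

    ``class_effects`` maps fraction -> {loc_class: multiplier}; e.g.
    ``{"membrane": {"MPR": 2.0}}`` plants a two-fold membrane enrichment
    for every MPR. ``effect_sigma`` adds log-normal gene-to-gene spread
    around each class multiplier. Baselines are log-normal.

    A fraction redistributes a fixed sequencing budget, so only enrichment
    relative to the pool average is identifiable from RPKM ratios. With
    ``closure=True`` (default) each fraction's multipliers are rescaled to
    a baseline-length-weighted mean of 1 over the mRNA pool, making the
    planted multiplier equal the true fraction/extract RPKM ratio — the
    quantity the estimator recovers. The raw (unclosed) multipliers are
    the closed ones up to that constant.
    """
    rng = _rng(design.seed, 100)
    baseline = pd.Series(
        rng.lognormal(0.0, baseline_sigma, len(catalog)),
        index=catalog.index, name="baseline",
    )
    mult = pd.DataFrame(1.0, index=catalog.index, columns=list(design.fractions))
    for fraction, effects in (class_effects or {}).items():
        if fraction == "extract":
            raise ValueError("the extract is the reference: multiplier fixed at 1")
        if fraction not in mult.columns:
            raise ValueError(f"unknown fraction {fraction!r}")
        for loc_class, m in effects.items():
            mask = catalog["loc_class"] == loc_class
            vals = np.full(mask.sum(), float(m))
            if effect_sigma > 0:
                vals *= rng.lognormal(0.0, effect_sigma, mask.sum())
            mult.loc[mask, fraction] = vals
    if closure:
        is_mrna = catalog["feature_class"] == "mRNA"
        w = (baseline * catalog["cds_length"])[is_mrna]
        for fraction in mult.columns:
            if fraction == "extract":
                continue
            c = (w * mult.loc[is_mrna, fraction]).sum() / w.sum()
            mult[fraction] /= c
    return SimTruth(baseline=baseline, multipliers=mult)


def simulate_fraction_counts(catalog: pd.DataFrame, design: SimDesign,
                             truth: SimTruth) -> CountMatrix:
    """Draw seeded negative-binomial read counts for every library."""
    validate_catalog(catalog)
    missing = catalog.index.difference(truth.baseline.index)
    if len(missing):
        raise ConsistencyError(f"truth lacks baseline for genes: {list(missing[:5])}")
    missing_f = [f for f in design.fractions if f not in truth.multipliers.columns]
    if missing_f:
        raise ConsistencyError(f"truth lacks multipliers for fractions: {missing_f}")

    is_mrna = (catalog["feature_class"] == "mRNA").to_numpy()
    lengths = catalog["cds_length"].to_numpy(float)
    baseline = truth.baseline.loc[catalog.index].to_numpy(float)

    cols, meta = {}, []
    for fi, fraction in enumerate(design.fractions):
        load = design.rrna_load_for(fraction)
        mult = truth.multipliers.loc[catalog.index, fraction].to_numpy(float)
        w = baseline * mult * lengths
        mean = np.zeros(len(catalog))
        for mask, share in ((is_mrna, 1.0 - load), (~is_mrna, load)):
            tot = w[mask].sum()
            if tot > 0:
                mean[mask] = design.library_size * share * w[mask] / tot
        for r in range(design.n_replicates):
            rng = _rng(design.seed, 1, fi, r)
            if design.dispersion == 0:
                counts = rng.poisson(mean)
            else:
                size = 1.0 / design.dispersion
                p = size / (size + mean)
                counts = np.where(mean > 0, rng.negative_binomial(size, p), 0)
            sample = f"{fraction}_rep{r + 1}"
            cols[sample] = counts.astype(np.int64)
            meta.append((sample, fraction, r + 1))
    counts = pd.DataFrame(cols, index=catalog.index)
    samples = pd.DataFrame(
        meta, columns=["sample_id", "fraction", "replicate"]
    ).set_index("sample_id")
    return CountMatrix(counts, samples)


def simulate_qpcr_panel(truth: SimTruth, rna_mass: Mapping[str, float],
                        seed: int = 0, noise_sd: float = 0.0) -> pd.DataFrame:
    """Emit a qPCR Ct table whose forward analysis recovers ``truth.portions``.

    The portion of transcript g in fraction f obeys
    ``portion = 2**(Ct_extract - Ct_fraction) * mass_f / mass_extract``, so
    the fraction Ct is set to ``Ct_extract - log2(portion * mass_e / mass_f)``.
    Extract Cts are drawn uniformly in [18, 24]. With ``noise_sd`` > 0,
    Gaussian noise is added to every Ct; the default (0) makes the
    inverse-forward round trip exact. ``rna_mass`` maps every fraction,
    including 'extract', to its RNA yield in micrograms.
    """
    if truth.portions is None:
        raise ValueError("truth carries no qPCR portions")
    for name, mass in rna_mass.items():
        if mass <= 0:
            raise ValueError(f"RNA mass for {name!r} must be > 0 (got {mass})")
    if "extract" not in rna_mass:
        raise ValueError("rna_mass must include 'extract'")
    rng = _rng(seed, 2)
    mass_e = rna_mass["extract"]
    rows = []
    for gene, row in truth.portions.iterrows():
        ct_e = rng.uniform(18.0, 24.0)
        rows.append((gene, "extract", ct_e))
        for fraction, portion in row.items():
            if fraction not in rna_mass:
                raise ValueError(f"rna_mass missing fraction {fraction!r}")
            if portion <= 0:
                continue  # transcript absent: no amplification, no Ct
            ct_f = ct_e - np.log2(portion * mass_e / rna_mass[fraction])
            rows.append((gene, fraction, ct_f))
    table = pd.DataFrame(rows, columns=["gene_id", "sample", "ct"])
    if noise_sd > 0:
        table["ct"] = table["ct"] + rng.normal(0.0, noise_sd, len(table))
    return table


def _background(rng: np.random.Generator, length: int) -> list[str]:
    """Random sequence containing no TTT run.

    Every built-in CSP rule window contains a T-run of length >= 3 (a
    7-window with at most one interruption has a T-run of at least 3;
    the literal elements contain TTTT or longer), so a TTT-free background
    carries no accidental built-in-rule matches.
    """
    bases = "ACGT"
    out: list[str] = []
    run = 0
    for _ in range(length):
        b = bases[rng.integers(0, 3 if run >= 2 else 4)]
        out.append(b)
        run = run + 1 if b == "T" else 0
    return out


def _realize_window(rule: MotifRule, rng: np.random.Generator) -> str:
    """One concrete window satisfying ``rule``."""
    if rule.kind == "exact_set":
        return rule.literals[rng.integers(0, len(rule.literals))]
    choices = [
        (pos, base)
        for pos, bases in sorted(rule.allowed_interruptions.items())
        for base in sorted(bases)
    ]
    if rule.min_interruptions == 0:
        choices.append((0, "T"))  # the pure run
    pos, base = choices[rng.integers(0, len(choices))]
    window = ["T"] * rule.run_length
    if pos:
        window[pos - 1] = base
    return "".join(window)


def simulate_transcripts_with_motifs(
        catalog: pd.DataFrame, rules: Sequence[MotifRule],
        plant_counts: Mapping[str, Mapping[str, int]],
        seed: int = 0, max_tries: int = 100,
) -> tuple[list[SeqRecord], SimTruth]:
    """CDS-like sequences with a known number of planted motif sites.

    ``plant_counts`` maps gene id -> rule id -> number of sites. Planted
    windows are separated by non-T flanks inside a TTT-free background, so
    scanning a gene with a planted rule finds exactly the planted sites.
    (A window can satisfy several rules at once — e.g. TTCTTTT is both the
    CspB heptamer and a legally interrupted CspE run — so the truth is
    recorded per planted rule only.) Each gene is rejection-checked: if any
    rule in ``rules`` matches the background outside planted windows, the
    gene is regenerated.

    Raises a capacity error when the requested sites (plus flanks) cannot
    fit in the CDS.
    """
    rule_by_id = {r.id: r for r in rules}
    unknown = {rid for per in plant_counts.values() for rid in per} - set(rule_by_id)
    if unknown:
        raise KeyError(f"plant_counts references unknown rules: {sorted(unknown)}")

    records: list[SeqRecord] = []
    counts = pd.DataFrame(
        0, index=catalog.index, columns=[r.id for r in rules], dtype=int)
    sites: dict[str, dict[str, list[tuple[int, int]]]] = {}

    for gi, (gene, length) in enumerate(catalog["cds_length"].items()):
        rng = _rng(seed, 3, gi)
        wanted = dict(plant_counts.get(gene, {}))
        planned: list[str] = []  # one window string per site, rule-tagged
        tags: list[str] = []
        for rid, k in wanted.items():
            for _ in range(int(k)):
                planned.append(_realize_window(rule_by_id[rid], rng))
                tags.append(rid)
        occupied = sum(len(w) + 2 for w in planned)  # 1 non-T flank per side
        if occupied > length:
            raise ValueError(
                f"gene {gene}: cannot fit {len(planned)} sites "
                f"({occupied} nt with flanks) in a {length}-nt CDS")

        for attempt in range(max_tries):
            seq = _background(rng, length)
            order = rng.permutation(len(planned))
            free = length - occupied
            cuts = np.sort(rng.integers(0, free + 1, size=len(planned)))
            gene_sites: dict[str, list[tuple[int, int]]] = {}
            pos = 0
            cursor = 0
            for j, oi in enumerate(order):
                window = planned[oi]
                start0 = cuts[j] + cursor + 1  # leave left flank
                seq[start0 - 1] = "AC"[rng.integers(0, 2)]
                seq[start0:start0 + len(window)] = list(window)
                seq[start0 + len(window)] = "AC"[rng.integers(0, 2)]
                gene_sites.setdefault(tags[oi], []).append(
                    (start0 + 1, start0 + len(window)))
                cursor += len(window) + 2
            s = "".join(seq)
            planted_intervals = collapse_intervals(
                [iv for ivs in gene_sites.values() for iv in ivs])
            clean = True
            for rule in rules:
                for hit in scan_sequence(s, rule, gene):
                    inside = any(a <= hit.start and hit.end <= b
                                 for a, b in planted_intervals)
                    if not inside:
                        clean = False
                        break
                if not clean:
                    break
            if clean:
                break
        else:
            raise RuntimeError(f"gene {gene}: no clean background in {max_tries} tries")

        records.append(SeqRecord(Seq(s), id=str(gene), description=""))
        for rid, ivs in gene_sites.items():
            counts.loc[gene, rid] = len(ivs)
        sites[str(gene)] = {rid: sorted(ivs) for rid, ivs in gene_sites.items()}

    fractions = ["extract"]
    truth = SimTruth(
        baseline=pd.Series(1.0, index=catalog.index),
        multipliers=pd.DataFrame(1.0, index=catalog.index, columns=fractions),
        motif_counts=counts, motif_sites=sites,
    )
    return records, truth
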