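"""Ground-truth generators: determinism, planted effects, mass balance."""

import numpy as np
import pandas as pd
import pytest

import fracrna as fr
from fracrna.simulate import _background


def test_catalog_respects_design_counts():
    d = fr.SimDesign(n_mpr=2, n_cpr=3, n_other=1, seed=7)
    cat = fr.build_gene_catalog(d)
    assert len(cat) == 6
    assert (cat["loc_class"] == "MPR").sum() == 2
    assert (cat["loc_class"] == "CPR").sum() == 3
    assert cat["cds_length"].between(100, 6000).all()


def test_catalog_deterministic_for_seed():
    d = fr.SimDesign(n_mpr=5, n_cpr=5, n_other=2, seed=7)
    pd.testing.assert_frame_equal(fr.build_gene_catalog(d),
                                  fr.build_gene_catalog(d))


def test_catalog_no_mpr_is_fine():
    d = fr.SimDesign(n_mpr=0, n_cpr=3, n_other=0, seed=1)
    cat = fr.build_gene_catalog(d)
    assert (cat["loc_class"] == "MPR").sum() == 0


@pytest.mark.parametrize("field,value", [
    ("n_mpr", -1), ("n_replicates", 0), ("library_size", 0),
    ("dispersion", -0.1),
])
def test_invalid_design_names_field(field, value):
    with pytest.raises(ValueError, match=field):
        fr.SimDesign(**{field: value})


def test_design_requires_extract():
    with pytest.raises(ValueError, match="extract"):
        fr.SimDesign(fractions=("membrane",))


def test_design_rrna_load_bounds():
    with pytest.raises(ValueError, match="rrna_load"):
        fr.SimDesign(fractions=("extract",), rrna_load=1.0)


def test_counts_deterministic_and_library_extension_stable():
    """Adding a fraction must not perturb the counts of existing libraries."""
    base = dict(n_mpr=5, n_cpr=10, n_other=2, n_replicates=2,
                library_size=1e5, seed=5)
    d2 = fr.SimDesign(fractions=("extract", "membrane"), **base)
    d3 = fr.SimDesign(fractions=("extract", "membrane", "70S"), **base)
    cat = fr.build_gene_catalog(d2)
    t2, t3 = fr.make_truth(cat, d2), fr.make_truth(cat, d3)
    c2 = fr.simulate_fraction_counts(cat, d2, t2)
    c3 = fr.simulate_fraction_counts(cat, d3, t3)
    shared = c2.counts.columns
    pd.testing.assert_frame_equal(c2.counts, c3.counts[shared])


def test_null_multipliers_give_equal_means_across_fractions():
    """With all multipliers 1 and equal rRNA load, per-gene Monte-Carlo mean
    counts agree between fractions."""
    d = fr.SimDesign(n_mpr=4, n_cpr=8, n_other=2,
                     fractions=("extract", "membrane"), n_replicates=1,
                     library_size=2e5, rrna_load=0.3, dispersion=0.02, seed=0)
    cat = fr.build_gene_catalog(d)
    truth = fr.make_truth(cat, d)
    sums = np.zeros((2, len(cat)))
    for rep in range(200):
        d_i = fr.SimDesign(n_mpr=4, n_cpr=8, n_other=2,
                           fractions=("extract", "membrane"), n_replicates=1,
                           library_size=2e5, rrna_load=0.3, dispersion=0.02,
                           seed=1000 + rep)
        cm = fr.simulate_fraction_counts(cat, d_i, truth)
        sums[0] += cm.counts["extract_rep1"].to_numpy()
        sums[1] += cm.counts["membrane_rep1"].to_numpy()
    means = sums / 200
    rel = np.abs(means[1] - means[0]) / means[0]
    assert np.median(rel) < 0.05


def test_planted_multiplier_recovered_in_mean_counts():
    """A gene with membrane multiplier 4 shows a ~4x mean-count ratio
    (Monte-Carlo over 200 seeded replicates)."""
    d = fr.SimDesign(n_mpr=1, n_cpr=30, n_other=0,
                     fractions=("extract", "membrane"), n_replicates=1,
                     library_size=1e6, rrna_load=0.0, dispersion=0.02, seed=0)
    cat = fr.build_gene_catalog(d)
    truth = fr.make_truth(cat, d, class_effects={"membrane": {"MPR": 4.0}})
    planted = truth.multipliers.loc["mpr0001", "membrane"]
    tot_e = tot_m = 0.0
    for rep in range(200):
        d_i = fr.SimDesign(n_mpr=1, n_cpr=30, n_other=0,
                           fractions=("extract", "membrane"), n_replicates=1,
                           library_size=1e6, rrna_load=0.0, dispersion=0.02,
                           seed=2000 + rep)
        cm = fr.simulate_fraction_counts(cat, d_i, truth)
        tot_e += cm.counts.loc["mpr0001", "extract_rep1"]
        tot_m += cm.counts.loc["mpr0001", "membrane_rep1"]
    assert tot_m / tot_e == pytest.approx(planted, rel=0.05)
    # one gene among 31: closure barely moves the planted value
    assert planted == pytest.approx(4.0, rel=0.15)


def test_high_rrna_load_starves_mrna_reads():
    d = fr.SimDesign(n_mpr=5, n_cpr=5, n_other=3,
                     fractions=("extract", "70S"), n_replicates=1,
                     library_size=1e6, rrna_load={"extract": 0.0, "70S": 0.99},
                     dispersion=0.0, seed=4)
    cat = fr.build_gene_catalog(d)
    cm = fr.simulate_fraction_counts(cat, d, fr.make_truth(cat, d))
    mrna = cat.index[cat["feature_class"] == "mRNA"]
    share = cm.counts.loc[mrna, "70S_rep1"].sum() / cm.counts["70S_rep1"].sum()
    assert share == pytest.approx(0.01, abs=0.005)


def test_truth_requires_extract_multiplier_one(small_catalog):
    mult = pd.DataFrame(1.0, index=small_catalog.index,
                        columns=["extract", "membrane"])
    mult["extract"] = 2.0
    with pytest.raises(ValueError, match="extract"):
        fr.SimTruth(baseline=pd.Series(1.0, index=small_catalog.index),
                    multipliers=mult)


def test_counts_missing_gene_in_truth_raises(small_design, small_catalog):
    truth = fr.make_truth(small_catalog, small_design)
    bad = fr.SimTruth(baseline=truth.baseline.iloc[:-1],
                      multipliers=truth.multipliers.iloc[:-1])
    with pytest.raises(fr.ConsistencyError):
        fr.simulate_fraction_counts(small_catalog, small_design, bad)


# ------------------------------------------------------------------- qPCR

def _portion_truth(portions: pd.DataFrame) -> fr.SimTruth:
    idx = portions.index
    return fr.SimTruth(
        baseline=pd.Series(1.0, index=idx),
        multipliers=pd.DataFrame(1.0, index=idx, columns=["extract"]),
        portions=portions,
    )


def test_qpcr_half_portion_equal_mass_is_one_cycle():
    portions = pd.DataFrame({"free": [0.5]}, index=["gA"])
    panel = fr.simulate_qpcr_panel(_portion_truth(portions),
                                   {"extract": 10.0, "free": 10.0}, seed=1)
    wide = panel.pivot(index="gene_id", columns="sample", values="ct")
    assert wide.loc["gA", "free"] - wide.loc["gA", "extract"] == pytest.approx(1.0)


def test_qpcr_roundtrip_exact_and_portions_sum_to_one():
    portions = pd.DataFrame(
        {"free": [0.2, 0.5], "70S": [0.3, 0.25], "membrane": [0.5, 0.25]},
        index=["gA", "gB"])
    masses = {"extract": 40.0, "free": 8.0, "70S": 20.0, "membrane": 5.0}
    panel = fr.simulate_qpcr_panel(_portion_truth(portions), masses, seed=9)
    recovered = fr.qpcr_portions(panel, masses)
    assert np.allclose(recovered[portions.columns], portions, atol=1e-9)
    assert np.allclose(recovered.sum(axis=1), 1.0, atol=1e-9)


def test_qpcr_nonpositive_mass_rejected():
    portions = pd.DataFrame({"free": [0.5]}, index=["gA"])
    with pytest.raises(ValueError, match="mass"):
        fr.simulate_qpcr_panel(_portion_truth(portions),
                               {"extract": 0.0, "free": 1.0})


# ------------------------------------------------- motif-planted transcripts

def test_background_has_no_ttt_run():
    rng = np.random.default_rng(0)
    seq = "".join(_background(rng, 5000))
    assert "TTT" not in seq


def test_planted_literal_sites_are_found_exactly():
    cat = pd.DataFrame({"cds_length": [600], "loc_class": ["MPR"],
                        "feature_class": ["mRNA"]},
                       index=pd.Index(["gX"], name="gene_id"))
    rules = fr.compile_builtin_rules()
    recs, truth = fr.simulate_transcripts_with_motifs(
        cat, rules, {"gX": {"R1": 3}}, seed=2)
    r1 = next(r for r in rules if r.id == "R1")
    sites = fr.scan_sequence(str(recs[0].seq), r1, "gX")
    assert len(sites) == 3
    assert truth.motif_counts.loc["gX", "R1"] == 3
    assert sorted((s.start, s.end) for s in sites) == truth.motif_sites["gX"]["R1"]


def test_plant_zero_sites_everywhere_scanner_finds_none():
    cat = pd.DataFrame({"cds_length": [400, 500], "loc_class": ["MPR", "CPR"],
                        "feature_class": ["mRNA", "mRNA"]},
                       index=pd.Index(["gA", "gB"], name="gene_id"))
    rules = fr.compile_builtin_rules()
    recs, truth = fr.simulate_transcripts_with_motifs(cat, rules, {}, seed=3)
    for rec in recs:
        for rule in rules:
            assert fr.scan_sequence(str(rec.seq), rule) == []
    assert (truth.motif_counts == 0).all().all()


def test_planted_cspe_sites_census():
    cat = pd.DataFrame({"cds_length": [900, 900], "loc_class": ["MPR", "MPR"],
                        "feature_class": ["mRNA", "mRNA"]},
                       index=pd.Index(["gA", "gB"], name="gene_id"))
    rules = fr.compile_builtin_rules()
    recs, truth = fr.simulate_transcripts_with_motifs(
        cat, rules, {"gA": {"R5": 2}}, seed=4)
    seqs = {r.id: str(r.seq) for r in recs}
    census = fr.count_table(seqs, {"grp": ["gA", "gB"]}, rules)
    row = census.set_index("rule").loc["R5"]
    assert row["genes_with_site"] == 1 and row["total_sites"] == 2


def test_planting_capacity_error():
    cat = pd.DataFrame({"cds_length": [30], "loc_class": ["MPR"],
                        "feature_class": ["mRNA"]},
                       index=pd.Index(["gX"], name="gene_id"))
    rules = fr.compile_builtin_rules()
    with pytest.raises(ValueError, match="fit"):
        fr.simulate_transcripts_with_motifs(cat, rules, {"gX": {"R1": 5}}, seed=0)


def test_transcripts_deterministic():
    cat = pd.DataFrame({"cds_length": [300], "loc_class": ["MPR"],
                        "feature_class": ["mRNA"]},
                       index=pd.Index(["gX"], name="gene_id"))
    rules = fr.compile_builtin_rules()
    a, _ = fr.simulate_transcripts_with_motifs(cat, rules, {"gX": {"R2": 1}}, seed=8)
    b, _ = fr.simulate_transcripts_with_motifs(cat, rules, {"gX": {"R2": 1}}, seed=8)
    assert str(a[0].seq) == str(b[0].seq)
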