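"""Scan coding sequences for the five CSP-recognition elements.

Plants a known number of U-rich cold-shock-protein recognition sites into
synthetic coding sequences for two gene groups and produces the
genes-with-site (total sites) census.
"""

import pandas as pd

import fracrna as fr

rules = fr.compile_builtin_rules()
for r in rules:
    print(f"{r.id}: {r.description}")

ids = [f"weak{i}" for i in range(4)] + [f"strong{i}" for i in range(4)]
catalog = pd.DataFrame({"cds_length": 900, "loc_class": "MPR",
                        "feature_class": "mRNA"},
                       index=pd.Index(ids, name="gene_id"))
plant = {"strong0": {"R5": 3}, "strong1": {"R5": 1}, "strong2": {"R1": 2},
         "weak0": {"R5": 1}}
records, truth = fr.simulate_transcripts_with_motifs(catalog, rules, plant,
                                                     seed=1)
seqs = {rec.id: str(rec.seq) for rec in records}
census = fr.count_table(seqs, {"weak": ids[:4], "strong": ids[4:]}, rules)
print()
print(fr.format_count_table(census).to_string())
print()
print("Each cell is 'genes with >= 1 site (total sites)'. The planted truth")
print("was: strong group, 4 R5 sites in 2 genes and 2 R1 sites in 1 gene;")
print("weak group, 1 R5 site. One U-rich window can satisfy several rules:")
print("the CspB heptamer TTCTTTT is also a legal CspE window (so R5 counts")
print("include the R1 plants), a purine-interrupted CspE window is also a")
print("TmCsp element (R4), and a pure U7 plant contains the U6 hexamer (R3).")
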