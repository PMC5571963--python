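"""Cold-shock-protein (CSP) recognition-element scanning.

Bacterial cold shock proteins (CspA family; in E. coli notably CspE and
CspC) bind single-stranded, U-rich RNA. Five recognition-element
definitions are implemented: three literal element sets characterised for
B. subtilis CspB (an exact heptamer, and two degenerate-end variants, one
of which also admits a U6 hexamer), one for T. maritima TmCsp (a 7-base
U/T run interrupted by a single purine at an interior position), and one
for E. coli CspE (a 7-base U/T run interrupted at a single position, with
positional base exclusions).

All rules operate on the DNA alphabet; U in the input is mapped to T, so a
coding sequence and its transcript spelling give identical results. The
scan space is the sense strand of the coding sequence.

Overlapping raw window matches of one rule are collapsed greedily left to
right into maximal sites, since a single U-rich stretch of length > 7
would otherwise be counted once per sliding window. Raw window counts
remain available via ``collapse=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

_VALID = set("ACGTN")


@dataclass(frozen=True)
class MotifRule:
    """One CSP-recognition element definition.

    ``kind`` is ``exact_set`` (match any literal in ``literals``) or
    ``interrupted_run`` (a ``run_length`` window of T with at most
    ``max_interruptions`` non-T positions; an interruption is only legal at
    a 1-based window position listed in ``allowed_interruptions``, and only
    with one of the bases allowed there).
    """

    id: str
    kind: str
    description: str = ""
    literals: tuple[str, ...] = ()
    run_length: int = 7
    allowed_interruptions: Mapping[int, frozenset] = field(default_factory=dict)
    min_interruptions: int = 0
    max_interruptions: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("exact_set", "interrupted_run"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind == "exact_set" and not self.literals:
            raise ValueError("exact_set rule needs at least one literal")
        if self.kind == "interrupted_run":
            if self.run_length < 2:
                raise ValueError("run length must be >= 2")
            for pos, bases in self.allowed_interruptions.items():
                if not 1 <= pos <= self.run_length:
                    raise ValueError(f"interruption position {pos} outside window")
                if not set(bases) <= {"A", "C", "G"}:
                    raise ValueError("interrupting bases must be non-T: A, C or G")

    def window_lengths(self) -> tuple[int, ...]:
        if self.kind == "exact_set":
            return tuple(sorted({len(l) for l in self.literals}))
        return (self.run_length,)

    def matches_window(self, window: str) -> bool:
        """Test one already-normalised (uppercase, T-spelled) window."""
        if self.kind == "exact_set":
            return window in self.literals
        if len(window) != self.run_length:
            return False
        interruptions = [
            (i + 1, b) for i, b in enumerate(window) if b != "T"
        ]
        if "N" in window:
            return False
        k = len(interruptions)
        if not (self.min_interruptions <= k <= self.max_interruptions):
            return False
        for pos, base in interruptions:
            if base not in self.allowed_interruptions.get(pos, frozenset()):
                return False
        return True


@dataclass(frozen=True)
class MotifSite:
    """A located occurrence: 1-based inclusive coordinates on the sense strand."""

    gene_id: str
    rule_id: str
    start: int
    end: int
    sequence: str


def compile_builtin_rules() -> list[MotifRule]:
    """The five CSP-recognition element definitions.

    R1  CspB (B. subtilis): TTCTTTT.
    R2  CspB: GTCTTTT/G, i.e. {GTCTTTT, GTCTTTG}.
    R3  CspB: GUCUUUU/A or UUUUUU, i.e. {GTCTTTT, GTCTTTA} plus the
        hexamer TTTTTT.
    R4  TmCsp (T. maritima): 7-base T/U run interrupted by exactly one
        purine, at positions 2-5, G excluded at position 3.
    R5  CspE (E. coli): 7-base T/U run interrupted at a single position,
        positions 2-6, G excluded at position 3, purines excluded at
        position 6. An uninterrupted T7 run also qualifies (zero
        interruptions allowed); pass ``require_interruption`` to
        :func:`scan_sequence` consumers via a modified rule if the strict
        reading is wanted (see :func:`cspe_rule`).
    """
    pur = frozenset("AG")
    return [
        MotifRule("R1", "exact_set", "CspB heptamer TTCTTTT",
                  literals=("TTCTTTT",)),
        MotifRule("R2", "exact_set", "CspB GTCTTTT/G",
                  literals=("GTCTTTT", "GTCTTTG")),
        MotifRule("R3", "exact_set", "CspB GTCTTTT/A or TTTTTT",
                  literals=("GTCTTTT", "GTCTTTA", "TTTTTT")),
        MotifRule("R4", "interrupted_run",
                  "TmCsp T7 run, one purine interruption at 2-5, no G at 3",
                  run_length=7,
                  allowed_interruptions={2: pur, 3: frozenset("A"),
                                         4: pur, 5: pur},
                  min_interruptions=1, max_interruptions=1),
        cspe_rule(require_interruption=False),
    ]


def cspe_rule(require_interruption: bool = False) -> MotifRule:
    """The CspE U-rich element: T7 run interrupted at one of positions 2-6.

    G is excluded at position 3 and purines at position 6. With
    ``require_interruption=False`` (default) a pure T7 run also counts,
    zero interruptions being the limiting U-rich element.
    """
    return MotifRule(
        "R5", "interrupted_run",
        "CspE T7 run, one interruption at 2-6, no G at 3, no purine at 6",
        run_length=7,
        allowed_interruptions={2: frozenset("ACG"), 3: frozenset("AC"),
                               4: frozenset("ACG"), 5: frozenset("ACG"),
                               6: frozenset("C")},
        min_interruptions=1 if require_interruption else 0,
        max_interruptions=1,
    )


def normalize_sequence(seq: str) -> str:
    """Uppercase and map U to T; reject characters outside A/C/G/T/U/N."""
    s = str(seq).upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"illegal sequence characters: {sorted(bad)}")
    return s


def _raw_matches(seq: str, rule: MotifRule) -> list[tuple[int, int]]:
    """All matching windows as 1-based inclusive (start, end) intervals."""
    out = []
    for L in rule.window_lengths():
        for i in range(len(seq) - L + 1):
            if rule.matches_window(seq[i:i + L]):
                out.append((i + 1, i + L))
    out.sort()
    return out


def collapse_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping 1-based inclusive intervals, greedy left to right."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def scan_sequence(seq: str, rule: MotifRule, gene_id: str = "",
                  collapse: bool = True) -> list[MotifSite]:
    """Locate all occurrences of ``rule`` in ``seq``.

    Returns maximal collapsed sites by default; with ``collapse=False``,
    one site per matching raw window. Sites are sorted by start. An empty
    sequence yields an empty list.
    """
    s = normalize_sequence(seq)
    intervals = _raw_matches(s, rule)
    if collapse:
        intervals = collapse_intervals(intervals)
    return [
        MotifSite(gene_id, rule.id, a, b, s[a - 1:b]) for a, b in intervals
    ]


def scan_genes(sequences: Mapping[str, str], rule: MotifRule,
               collapse: bool = True) -> list[MotifSite]:
    sites: list[MotifSite] = []
    for gene_id in sequences:
        sites.extend(scan_sequence(sequences[gene_id], rule, gene_id, collapse))
    return sites


def count_table(sequences: Mapping[str, str],
                groups: Mapping[str, Iterable[str]],
                rules: Sequence[MotifRule] | None = None) -> pd.DataFrame:
    """Per-rule per-group motif census.

    For every rule and gene group: the number of genes carrying at least
    one site (``genes_with_site``), the summed collapsed-site count
    (``total_sites``), and the summed raw window count
    (``total_raw_windows``). Every listed gene must have a sequence.
    """
    rules = list(rules) if rules is not None else compile_builtin_rules()
    missing = sorted(
        {g for members in groups.values() for g in members} - set(sequences)
    )
    if missing:
        raise KeyError(f"no sequence for genes: {missing[:10]}")
    rows = []
    for rule in rules:
        per_gene = {
            g: (len(scan_sequence(sequences[g], rule, g)),
                len(scan_sequence(sequences[g], rule, g, collapse=False)))
            for g in {m for members in groups.values() for m in members}
        }
        for group, members in groups.items():
            members = list(members)
            n_genes = sum(1 for g in members if per_gene[g][0] > 0)
            n_sites = sum(per_gene[g][0] for g in members)
            n_raw = sum(per_gene[g][1] for g in members)
            rows.append((rule.id, group, len(members), n_genes, n_sites, n_raw))
    return pd.DataFrame(
        rows, columns=["rule", "group", "group_size", "genes_with_site",
                       "total_sites", "total_raw_windows"],
    )


def format_count_table(table: pd.DataFrame, raw: bool = False) -> pd.DataFrame:
    """Render the census as 'g (s)' cells: rules as rows, groups as columns."""
    col = "total_raw_windows" if raw else "total_sites"
    cells = table.assign(
        cell=table.apply(lambda r: f"{r['genes_with_site']} ({r[col]})", axis=1)
    )
    return cells.pivot(index="rule", columns="group", values="cell")


def sites_to_bed(sites: Iterable[MotifSite]) -> pd.DataFrame:
    """Convert 1-based inclusive sites to BED (0-based half-open) records."""
    rows = [(s.gene_id, s.start - 1, s.end, s.rule_id) for s in sites]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
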