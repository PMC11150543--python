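"""Codon counting, RSCU, amino-acid usage and start/stop codon tallies.

Relative synonymous codon usage of codon *c* in a synonymous family *F*::

    RSCU(c) = count(c) * |F| / sum_{c' in F} count(c')

so uniform usage inside a family gives RSCU = 1 for each member and the
family mean is always 1 whenever the family was used at all.  Leucine and
serine are split into their two codon families (Leu1 = CTN, Leu2 = TTR,
Ser1 = AGN, Ser2 = TCN) as is conventional for mitochondrial codon-usage
plots.  The default genetic code is the invertebrate mitochondrial code
(translation table 5), in which AGA/AGG encode Ser, ATA Met and TGA Trp.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.Data import CodonTable

log = logging.getLogger("mitocomp")

BASES = "TCAG"
ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]

SUPPORTED_CODES = (1, 2, 4, 5)

AA1_TO_3 = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}


class GeneticCode:
    """A translation table with split Leu/Ser synonymous families."""

    _cache: dict[int, "GeneticCode"] = {}

    def __init__(self, code_id: int):
        if code_id not in SUPPORTED_CODES:
            raise ValueError(f"unsupported genetic code {code_id}; "
                             f"choose one of {SUPPORTED_CODES}")
        self.id = code_id
        table = CodonTable.unambiguous_dna_by_id[code_id]
        self.stop_codons = frozenset(table.stop_codons)
        self.aa: dict[str, str] = dict(table.forward_table)  # codon -> 1-letter aa
        self.family: dict[str, str] = {}
        for codon, aa in self.aa.items():
            label = AA1_TO_3[aa]
            if aa == "L":
                label = "Leu2" if codon.startswith("TT") else "Leu1"
            elif aa == "S":
                label = "Ser1" if codon.startswith("AG") else "Ser2"
            self.family[codon] = label
        self.family_members: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            fam = self.family.get(codon)
            if fam is not None:
                self.family_members.setdefault(fam, []).append(codon)

    @classmethod
    def get(cls, code_id: int = 5) -> "GeneticCode":
        if code_id not in cls._cache:
            cls._cache[code_id] = GeneticCode(code_id)
        return cls._cache[code_id]

    def translate(self, codon: str) -> str:
        """1-letter amino acid, or '*' for a stop codon."""
        if codon in self.stop_codons:
            return "*"
        return self.aa[codon]


@dataclass
class CodonCounts:
    counts: Counter
    n_ambiguous: int
    code_id: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _as_named(cds_list) -> list[tuple[str, str]]:
    if isinstance(cds_list, dict):
        return list(cds_list.items())
    out = []
    for i, item in enumerate(cds_list):
        if isinstance(item, tuple):
            out.append(item)
        else:
            out.append((f"cds{i + 1}", item))
    return out


def count_codons(cds_list, code: int = 5) -> CodonCounts:
    """Count codons over a set of in-frame CDS.

    ``cds_list`` is a list of nucleotide strings, a list of (name, string)
    pairs, or a name→string mapping.  Codons containing N are excluded from
    the counts and tallied separately.
    """
    named = _as_named(cds_list)
    if not named:
        raise ValueError("no coding sequences given")
    GeneticCode.get(code)  # validates code id
    counts: Counter = Counter()
    n_amb = 0
    for name, seq in named:
        seq = seq.upper()
        if len(seq) % 3:
            raise ValueError(f"{name}: length {len(seq)} not divisible by 3 "
                             "(apply the incomplete-stop policy first)")
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            if set(codon) <= set("ACGT"):
                counts[codon] += 1
            else:
                n_amb += 1
    return CodonCounts(counts, n_amb, code)


@dataclass
class RSCUTable:
    """Per-codon and per-amino-acid usage summary."""

    codons: pd.DataFrame       # codon, aa, family, count, rscu
    amino_acids: pd.DataFrame  # aa, count, percent
    stop_counts: dict[str, int]
    code_id: int
    n_preferred: int           # codons with RSCU > 1
    preferred_at_ending_fraction: float | None

    @property
    def preferred_codons(self) -> list[str]:
        df = self.codons
        return list(df.loc[df["rscu"] > 1, "codon"])


def rscu(counts: CodonCounts, code: int | None = None) -> RSCUTable:
    """RSCU values, amino-acid frequencies and the preferred-codon summary.

    Stop codons are tabulated separately and never enter a synonymous
    family; a codon in a family with zero total usage has RSCU = 0.
    """
    gc = GeneticCode.get(code if code is not None else counts.code_id)
    stop_counts = {c: counts.counts.get(c, 0) for c in sorted(gc.stop_codons)}
    fam_totals = {fam: sum(counts.counts.get(c, 0) for c in members)
                  for fam, members in gc.family_members.items()}
    rows = []
    for codon in ALL_CODONS:
        if codon in gc.stop_codons:
            continue
        fam = gc.family[codon]
        cnt = counts.counts.get(codon, 0)
        total = fam_totals[fam]
        value = cnt * len(gc.family_members[fam]) / total if total else 0.0
        rows.append({"codon": codon, "aa": gc.aa[codon], "family": fam,
                     "count": cnt, "rscu": value})
    cdf = pd.DataFrame(rows)
    aa_counts = cdf.groupby("aa", sort=True)["count"].sum()
    total_aa = int(aa_counts.sum())
    adf = pd.DataFrame({
        "aa": aa_counts.index,
        "count": aa_counts.values,
        "percent": [100.0 * v / total_aa if total_aa else 0.0
                    for v in aa_counts.values],
    })
    preferred = cdf[cdf["rscu"] > 1]
    n_pref = len(preferred)
    at_frac = (float((preferred["codon"].str[-1].isin(["A", "T"])).mean())
               if n_pref else None)
    return RSCUTable(cdf, adf, stop_counts, gc.id, n_pref, at_frac)


def amino_acid_frequencies(counts: CodonCounts) -> pd.DataFrame:
    """aa, count, percent over all translated non-stop codons."""
    return rscu(counts).amino_acids


ATD_STARTS = ("ATA", "ATT", "ATG")


@dataclass
class StartStopSummary:
    per_gene: pd.DataFrame      # gene, start_codon, stop_codon
    start_tally: Counter        # grouped: ATD covers ATA/ATT/ATG
    stop_tally: Counter


def start_stop_summary(cds_list, code: int = 5,
                       incomplete_stops: dict[str, str] | None = None
                       ) -> StartStopSummary:
    """Initiation/termination codon per gene with an ATD-grouped tally.

    ``incomplete_stops`` maps gene name → the recorded trailing partial
    codon ("T" or "TA") for CDS whose stop is completed by polyadenylation;
    such stops are reported padded with '-' (e.g. "TA-").
    """
    named = _as_named(cds_list)
    incomplete_stops = incomplete_stops or {}
    GeneticCode.get(code)
    rows = []
    starts: Counter = Counter()
    stops: Counter = Counter()
    for name, seq in named:
        seq = seq.upper()
        if len(seq) % 3 or len(seq) < 6:
            raise ValueError(f"{name}: not an in-frame CDS of >= 2 codons")
        start = seq[:3]
        if name in incomplete_stops:
            stop = incomplete_stops[name].upper().ljust(3, "-")
        else:
            stop = seq[-3:]
        rows.append({"gene": name, "start_codon": start, "stop_codon": stop})
        starts[("ATD" if start in ATD_STARTS else start)] += 1
        stops[stop] += 1
    return StartStopSummary(pd.DataFrame(rows), starts, stops)


def codon_table_to_tsv(table: RSCUTable, path) -> None:
    df = table.codons.copy()
    df["aa_label"] = df["family"]
    df[["codon", "aa_label", "count", "rscu"]].to_csv(path, sep="\t", index=False)


def aa_table_to_tsv(table: RSCUTable, path) -> None:
    table.amino_acids.to_csv(path, sep="\t", index=False)
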