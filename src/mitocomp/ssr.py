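"""Perfect-microsatellite (mtSSR) detection and summary statistics.

A mitochondrial microsatellite here is a perfect tandem repeat of a
primitive 1–6 bp motif meeting minimum unit-count thresholds (defaults:
12 units for mononucleotides, 6 for dinucleotides, 4 for trinucleotides and
3 for tetra/penta/hexanucleotides; zero interruption between merged
repeats).  Scanning is forward-strand only, motifs are reported exactly as
they occur (no canonical collapsing), only complete units are counted, and
every repeat is reported once, at its shortest (primitive) period.  The
sequence is treated as linear: a repeat spanning the origin of a circular
genome is not detected.

Per-genome summaries use relative abundance RA = SSRs per kb of genome and
relative density RD = SSR bp per kb of genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd
from scipy import stats as _scipy_stats

from .composition import round_half_up
from .mito_io import MitoGenome

log = logging.getLogger("mitocomp")

_ACGT = set("ACGT")


@dataclass(frozen=True)
class SSRThresholds:
    """Minimum complete repeat units per motif length (period 1..6)."""

    min_units: dict[int, int] = field(
        default_factory=lambda: {1: 12, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3})
    max_interruption: int = 0

    def __post_init__(self):
        if set(self.min_units) != {1, 2, 3, 4, 5, 6}:
            raise ValueError("thresholds must cover motif lengths 1..6 exactly")
        if any(v < 1 for v in self.min_units.values()):
            raise ValueError("minimum unit counts must be >= 1")


DEFAULT_THRESHOLDS = SSRThresholds()


@dataclass(frozen=True)
class SSRecord:
    """One perfect tandem repeat (1-based inclusive coordinates)."""

    motif: str
    n_units: int
    size: int
    start: int
    end: int
    location: str | None = None
    compound: bool = False
    components: tuple = ()

    def __post_init__(self):
        if self.end - self.start + 1 != self.size:
            raise ValueError(f"span {self.start}..{self.end} inconsistent with "
                             f"size {self.size}")

    @property
    def sequence(self) -> str:
        return self.motif * self.n_units if not self.compound else ""


def smallest_period(s: str) -> int:
    """Smallest p with s[i] == s[i+p] for all valid i (failure function)."""
    n = len(s)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    return n - fail[-1] if n else 0


def scan_ssrs(seq: str, thresholds: SSRThresholds = DEFAULT_THRESHOLDS
              ) -> list[SSRecord]:
    """All maximal perfect tandem repeats meeting the thresholds.

    N breaks any repeat run; a trailing partial unit is excluded from the
    unit count and size; a candidate whose array has a smaller true period
    is left to the smaller-period scan (primitive-period reporting).
    """
    seq = seq.upper()
    if not seq:
        return []
    bad = set(seq) - _ACGT - {"N"}
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    n = len(seq)
    records: list[SSRecord] = []
    for p in range(1, 7):
        thr = thresholds.min_units[p]
        if n < p * thr:
            continue
        k = 0
        limit = n - p
        while k < limit:
            if seq[k] == seq[k + p] and seq[k] != "N":
                j = k
                while j < limit and seq[j] == seq[j + p] and seq[j] != "N":
                    j += 1
                m = j - k                     # matching run length
                units = (m + p) // p          # complete units from run start
                if units >= thr:
                    run = seq[k:k + m + p]
                    if smallest_period(run) == p:
                        size = units * p
                        records.append(SSRecord(seq[k:k + p], units, size,
                                                k + 1, k + size))
                k = j + 1
            else:
                k += 1
    records = sorted(set(records), key=lambda r: (r.start, len(r.motif)))
    return records


def merge_compound(records: list[SSRecord], max_interruption: int = 0
                   ) -> list[SSRecord]:
    """Flag runs of adjacent repeats (gap <= max_interruption) as compound.

    With the default interruption of zero only directly adjacent repeats
    merge; the compound record spans its components and retains them.
    """
    if not records:
        return []
    records = sorted(records, key=lambda r: r.start)
    out: list[SSRecord] = []
    group = [records[0]]
    for rec in records[1:]:
        gap = rec.start - group[-1].end - 1
        if gap <= max_interruption:
            group.append(rec)
        else:
            out.append(_finish_group(group))
            group = [rec]
    out.append(_finish_group(group))
    return out


def _finish_group(group: list[SSRecord]) -> SSRecord:
    if len(group) == 1:
        return group[0]
    start = group[0].start
    end = max(r.end for r in group)
    return SSRecord(motif="+".join(r.motif for r in group),
                    n_units=sum(r.n_units for r in group),
                    size=end - start + 1, start=start, end=end,
                    compound=True, components=tuple(group))


_GENIC_KINDS = ("CDS", "rRNA", "tRNA")

INTERGENIC_LABEL = "Intergenic region"
CONTROL_REGION_LABEL = "Control region"


def classify_locations(records: list[SSRecord], genome: MitoGenome
                       ) -> list[SSRecord]:
    """Assign each repeat the gene containing its start, else CR/intergenic."""
    out = []
    for rec in records:
        location = INTERGENIC_LABEL
        for f in genome.features:
            if f.start <= rec.start <= f.end and f.kind in _GENIC_KINDS:
                location = f.name
                break
        else:
            for f in genome.features:
                if f.start <= rec.start <= f.end and f.kind == "control_region":
                    location = CONTROL_REGION_LABEL
                    break
        out.append(replace(rec, location=location))
    return out


def coding_fraction(records: list[SSRecord]) -> float | None:
    """Fraction of classified repeats lying in genes (not CR/intergenic)."""
    located = [r for r in records if r.location is not None]
    if not located:
        return None
    coding = sum(1 for r in located
                 if r.location not in (INTERGENIC_LABEL, CONTROL_REGION_LABEL))
    return coding / len(located)


@dataclass
class SSRStats:
    """Per-genome repeat abundance/density and motif-class composition."""

    n_ssrs: int
    genome_size: int
    ra: float                     # SSRs per kb
    rd: float                     # SSR bp per kb
    gc_pct: float | None          # GC% of SSR nucleotides
    class_counts: dict[int, int]  # period -> count
    class_pct: dict[int, float]
    at_only_fraction: float | None

    def rounded(self) -> dict:
        return {"n_ssrs": self.n_ssrs, "genome_size": self.genome_size,
                "RA": round_half_up(self.ra, 2), "RD": round_half_up(self.rd, 2),
                "GC_pct": None if self.gc_pct is None
                else round_half_up(self.gc_pct, 1)}


def _motif_period(rec: SSRecord) -> int:
    if rec.compound:
        raise ValueError("motif class undefined for compound records; "
                         "classify components instead")
    return len(rec.motif)


def ssr_stats(records: list[SSRecord], genome_size: int) -> SSRStats:
    """RA/RD and motif-class composition for one genome's repeat list."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    simple = [r for r in records if not r.compound]
    kb = genome_size / 1000.0
    ra = len(simple) / kb
    total_bp = sum(r.size for r in simple)
    rd = total_bp / kb
    class_counts = {p: 0 for p in range(1, 7)}
    gc_bases = 0
    at_only = 0
    for r in simple:
        class_counts[_motif_period(r)] += 1
        gc_bases += (r.motif.count("G") + r.motif.count("C")) * r.n_units
        if set(r.motif) <= {"A", "T"}:
            at_only += 1
    n = len(simple)
    class_pct = {p: (100.0 * c / n if n else 0.0)
                 for p, c in class_counts.items()}
    return SSRStats(n, genome_size, ra, rd,
                    (100.0 * gc_bases / total_bp) if total_bp else None,
                    class_counts, class_pct,
                    (at_only / n) if n else None)


@dataclass
class CrossSpeciesSummary:
    per_species: pd.DataFrame     # species, genome_size, n_ssrs, RA, RD, GC_pct
    pooled_class_pct: dict[int, float]
    at_only_fraction: float | None
    coding_fraction: float | None
    r2: float | None              # Pearson r^2, SSR count vs genome size
    p_value: float | None


def cross_species_summary(panel) -> CrossSpeciesSummary:
    """Multi-genome repeat summary with the count-vs-size correlation.

    ``panel`` is a list of (genome, records) where ``genome`` is a
    MitoGenome or an (identifier, size_bp) pair.  The Pearson correlation
    is omitted (with a warning) for fewer than 3 genomes or degenerate
    variance.
    """
    rows, sizes, counts = [], [], []
    all_simple: list[SSRecord] = []
    for genome, records in panel:
        if isinstance(genome, MitoGenome):
            ident, size = genome.identifier, genome.length
        else:
            ident, size = genome
        st = ssr_stats(records, size)
        rows.append({"species": ident, "genome_size": size,
                     "n_ssrs": st.n_ssrs, "RA": st.ra, "RD": st.rd,
                     "GC_pct": st.gc_pct})
        sizes.append(size)
        counts.append(st.n_ssrs)
        all_simple.extend(r for r in records if not r.compound)
    pooled = ssr_stats(all_simple, max(1, sum(sizes)))
    r2 = p_value = None
    if len(sizes) < 3:
        log.warning("correlation omitted: need >= 3 genomes, got %d", len(sizes))
    elif len(set(sizes)) == 1 or len(set(counts)) == 1:
        log.warning("correlation omitted: zero variance in sizes or counts")
    else:
        r, p_value = _scipy_stats.pearsonr(sizes, counts)
        r2 = r * r
    return CrossSpeciesSummary(pd.DataFrame(rows), pooled.class_pct,
                               pooled.at_only_fraction,
                               coding_fraction(all_simple), r2, p_value)


def records_to_tsv(per_species: dict[str, list[SSRecord]], path) -> None:
    """Table-shaped TSV: species, motif, n_repeats, size, start, end, location."""
    rows = []
    for species, records in per_species.items():
        for r in records:
            rows.append({"species": species, "motif": r.motif,
                         "n_repeats": r.n_units, "size": r.size,
                         "start": r.start, "end": r.end,
                         "location": r.location or "",
                         "compound": int(r.compound)})
    pd.DataFrame(rows, columns=["species", "motif", "n_repeats", "size",
                                "start", "end", "location", "compound"]
                 ).to_csv(path, sep="\t", index=False)
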