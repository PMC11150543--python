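"""Reading, validating and slicing annotated mitochondrial genomes.

The universal input object for the pipeline is :class:`MitoGenome`: a
(usually circular) nucleotide sequence plus an ordered list of typed,
stranded features.  Genomes can be read from GenBank flat files or from a
FASTA file with a companion tab-separated annotation table, and written
back out to either representation.

Coordinates are 1-based inclusive throughout, matching the convention of
printed mitogenome tables.  A feature may wrap the origin (start > end)
only on a circular genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("mitocomp")

VALID_BASES = set("ACGTN")

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "control_region", "pseudogene", "intergenic")

#: the 13 mitochondrial protein-coding genes
PCG_NAMES = (
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
    "cox1", "cox2", "cox3", "atp6", "atp8", "cytb",
)

#: canonical tRNA inventory (22 genes; Leu and Ser are duplicated)
TRNA_NAMES = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI", "trnK",
    "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR", "trnS1",
    "trnS2", "trnT", "trnV", "trnW", "trnY",
)

RRNA_NAMES = ("rrnL", "rrnS")

#: the full 37-gene metazoan mitochondrial inventory
CANONICAL_GENES = PCG_NAMES + TRNA_NAMES + RRNA_NAMES


class FormatError(ValueError):
    """Input file failed to parse in the declared format."""


class ValidationError(ValueError):
    """Parsed genome violated a structural invariant."""


class EmptyPartitionError(ValueError):
    """A requested, syntactically valid partition has no members."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Feature:
    """One annotated element: gene label, kind, 1-based inclusive span, strand."""

    name: str
    kind: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r} for {self.name}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValidationError(f"{self.name}: coordinates are 1-based, got "
                                  f"{self.start}..{self.end}")

    @property
    def wraps_origin(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps_origin:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError("genome length required for an origin-wrapping feature")
        return genome_length - self.start + 1 + self.end


@dataclass
class MitoGenome:
    """A circular annotated mitochondrial genome."""

    identifier: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValidationError(f"{self.identifier}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValidationError(
                f"{self.identifier}: ambiguity codes other than N are rejected: "
                f"{sorted(bad)}")
        n = len(self.sequence)
        for f in self.features:
            if f.start > n or f.end > n:
                raise ValidationError(
                    f"{self.identifier}: feature {f.name} [{f.start}..{f.end}] "
                    f"outside sequence bounds (1..{n})")
            if f.wraps_origin and not self.circular:
                raise ValidationError(
                    f"{self.identifier}: feature {f.name} wraps the origin on a "
                    f"linear genome")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]

    def feature_by_name(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"{self.identifier}: no feature named {name!r}")


# --------------------------------------------------------------------------
# gene-name normalization
# --------------------------------------------------------------------------

_AA3_TO_1 = {
    "ala": "A", "cys": "C", "asp": "D", "glu": "E", "phe": "F", "gly": "G",
    "his": "H", "ile": "I", "lys": "K", "leu": "L", "met": "M", "asn": "N",
    "pro": "P", "gln": "Q", "arg": "R", "ser": "S", "thr": "T", "val": "V",
    "trp": "W", "tyr": "Y",
}

_GENE_ALIASES = {
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4l", "nd5": "nad5", "nd6": "nad6", "nadh1": "nad1",
    "nadh2": "nad2", "nadh3": "nad3", "nadh4": "nad4", "nadh4l": "nad4l",
    "nadh5": "nad5", "nadh6": "nad6", "nad4l": "nad4l",
    "co1": "cox1", "coi": "cox1", "coxi": "cox1", "cox1": "cox1",
    "co2": "cox2", "coii": "cox2", "coxii": "cox2", "cox2": "cox2",
    "co3": "cox3", "coiii": "cox3", "coxiii": "cox3", "cox3": "cox3",
    "atp6": "atp6", "atpase6": "atp6", "atp8": "atp8", "atpase8": "atp8",
    "cob": "cytb", "cytb": "cytb", "cyb": "cytb",
    "rrnl": "rrnL", "16s": "rrnL", "lrrna": "rrnL", "lsu": "rrnL",
    "16srrna": "rrnL", "rrn16": "rrnL",
    "rrns": "rrnS", "12s": "rrnS", "srrna": "rrnS", "ssu": "rrnS",
    "12srrna": "rrnS", "rrn12": "rrnS",
}

# codon-family notes used to tell the duplicated Leu/Ser tRNAs apart
_LEU_SER_FAMILIES = {
    "cun": "trnL1", "uag": "trnL1", "tag": "trnL1",
    "uur": "trnL2", "uaa": "trnL2", "taa": "trnL2",
    "agn": "trnS1", "ucu": "trnS1", "tct": "trnS1", "gcu": "trnS1", "gct": "trnS1",
    "ucn": "trnS2", "uga": "trnS2", "tga": "trnS2",
}


def normalize_gene_name(raw: str, note: str = "") -> str:
    """Map an annotation label to the canonical lowercase vocabulary.

    ``note`` may carry an anticodon or codon-family hint used to split the
    duplicated Leu/Ser tRNAs; a bare ``trnL``/``trnS`` without a hint is
    returned un-suffixed and resolved later by order of appearance.
    """
    s = raw.strip().lower().replace(" ", "").replace("_", "")
    s = s.replace("-", "") if not s.startswith("trna-") else s
    if s in _GENE_ALIASES:
        return _GENE_ALIASES[s]
    # tRNA spellings: trnI, trn-I, tRNA-Ile, trnL1, trna-leu(uur) ...
    # "trnA"/"trna" (alanine) must not be eaten by the "tRNA" prefix
    t = s
    if t.startswith("trna-"):
        t = "trn" + t[5:]
    elif t.startswith("trna") and t[4:7] in _AA3_TO_1:
        t = "trn" + t[4:]
    if t.startswith("trn"):
        rest = t[3:]
        hint = ""
        if "(" in rest:
            rest, _, hint = rest.partition("(")
            hint = hint.rstrip(")")
        if rest in _AA3_TO_1:
            rest = _AA3_TO_1[rest].lower()
        if rest in ("l", "s", "l1", "l2", "s1", "s2"):
            if len(rest) == 2:
                return "trn" + rest[0].upper() + rest[1]
            for key in (hint, note.lower()):
                for fam, name in _LEU_SER_FAMILIES.items():
                    if fam in key:
                        return name
            return "trn" + rest.upper()  # ambiguous, caller disambiguates
        if len(rest) == 1 and rest.isalpha():
            return "trn" + rest.upper()
    return s


def _disambiguate_duplicate_trnas(features: list[Feature]) -> list[Feature]:
    """Suffix bare trnL/trnS copies by order of appearance."""
    out: list[Feature] = []
    seen: dict[str, int] = {}
    for f in features:
        if f.name in ("trnL", "trnS"):
            seen[f.name] = seen.get(f.name, 0) + 1
            f = replace(f, name=f"{f.name}{min(seen[f.name], 2)}")
        out.append(f)
    return out


# --------------------------------------------------------------------------
# readers
# --------------------------------------------------------------------------

_GENBANK_KIND_MAP = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "control_region",
    "misc_feature": "control_region",
    "rep_origin": "control_region",
}


def read_annotated_genome(path: str | Path, format: str = "genbank",
                          table: str | Path | None = None) -> MitoGenome:
    """Read a mitogenome from ``genbank`` or ``fasta+table`` input.

    Unknown feature kinds are dropped with a logged warning; gene names are
    normalized to the canonical lowercase vocabulary.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genbank":
        return _read_genbank(path)
    if format == "fasta+table":
        if table is None:
            raise ValueError("fasta+table format requires a companion annotation table")
        return _read_fasta_table(path, Path(table))
    raise ValueError(f"unknown format {format!r}; expected 'genbank' or 'fasta+table'")


def _read_genbank(path: Path) -> MitoGenome:
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError with line info
        raise FormatError(f"{path}: not a readable GenBank record: {exc}") from exc
    circular = record.annotations.get("topology", "circular") == "circular"
    feats: list[Feature] = []
    for sf in record.features:
        if sf.type in ("source", "gene"):
            continue
        kind = _GENBANK_KIND_MAP.get(sf.type)
        if kind is None:
            log.warning("%s: dropping feature of unknown kind %r", path.name, sf.type)
            continue
        quals = sf.qualifiers
        raw = (quals.get("gene") or quals.get("product") or quals.get("note") or [sf.type])[0]
        note = " ".join(quals.get("note", []) + quals.get("codon_recognized", []))
        if "pseudo" in quals or "pseudogene" in quals:
            kind = "pseudogene"
        name = normalize_gene_name(raw, note)
        if kind == "control_region":
            name = "control_region"
        start = int(sf.location.start) + 1
        end = int(sf.location.end)
        strand = "-" if sf.location.strand == -1 else "+"
        feats.append(Feature(name, kind, start, end, strand))
    feats = _disambiguate_duplicate_trnas(feats)
    return MitoGenome(record.id or path.stem, str(record.seq), circular, feats)


def _read_fasta_table(fasta_path: Path, table_path: Path) -> MitoGenome:
    try:
        record = SeqIO.read(str(fasta_path), "fasta")
    except Exception as exc:
        raise FormatError(f"{fasta_path}: not a readable FASTA file: {exc}") from exc
    try:
        tab = pd.read_csv(table_path, sep="\t", dtype=str)
    except Exception as exc:
        raise FormatError(f"{table_path}: not a readable TSV table: {exc}") from exc
    required = {"name", "kind", "start", "end", "strand"}
    if not required.issubset(tab.columns):
        raise FormatError(
            f"{table_path}: annotation table needs columns {sorted(required)}, "
            f"got {list(tab.columns)}")
    feats = []
    for i, row in tab.iterrows():
        kind = str(row["kind"])
        if kind not in FEATURE_KINDS:
            log.warning("%s line %d: dropping feature of unknown kind %r",
                        table_path.name, i + 2, kind)
            continue
        try:
            feats.append(Feature(normalize_gene_name(str(row["name"])), kind,
                                 int(row["start"]), int(row["end"]), str(row["strand"])))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{table_path} line {i + 2}: {exc}") from exc
    feats = _disambiguate_duplicate_trnas(feats)
    return MitoGenome(record.id or fasta_path.stem, str(record.seq), True, feats)


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------

def write_fasta(genome: MitoGenome, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.identifier, description="")
    SeqIO.write([rec], str(path), "fasta")


def write_annotation_table(genome: MitoGenome, path: str | Path) -> None:
    rows = [{"name": f.name, "kind": f.kind, "start": f.start, "end": f.end,
             "strand": f.strand} for f in genome.features]
    pd.DataFrame(rows, columns=["name", "kind", "start", "end", "strand"]).to_csv(
        path, sep="\t", index=False)


def write_genome(genome: MitoGenome, fasta_path: str | Path,
                 table_path: str | Path) -> None:
    """Write the FASTA + annotation-table representation (round-trip safe)."""
    write_fasta(genome, fasta_path)
    write_annotation_table(genome, table_path)


def write_genbank(genome: MitoGenome, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.identifier,
                    name=genome.identifier[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.circular else "linear"
    inv_kind = {"control_region": "misc_feature", "pseudogene": "CDS",
                "intergenic": "misc_feature"}
    for f in genome.features:
        gb_type = inv_kind.get(f.kind, f.kind)
        quals = {"gene": [f.name]}
        if f.kind == "pseudogene":
            quals["pseudo"] = [""]
        loc = FeatureLocation(f.start - 1, f.end, strand=-1 if f.strand == "-" else 1)
        rec.features.append(SeqFeature(loc, type=gb_type, qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


# --------------------------------------------------------------------------
# sequence extraction
# --------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def feature_sequence(genome: MitoGenome, feature: Feature) -> str:
    """The feature's sequence oriented 5'→3' in reading direction."""
    if feature.wraps_origin:
        s = genome.sequence[feature.start - 1:] + genome.sequence[:feature.end]
    else:
        s = genome.sequence[feature.start - 1:feature.end]
    return reverse_complement(s) if feature.strand == "-" else s


_PARTITION_KINDS = {"PCG": ("CDS",), "tRNA": ("tRNA",), "rRNA": ("rRNA",)}


def extract_partition(genome: MitoGenome, partition: str) -> str:
    """Concatenated sequence of a named partition, in genome order.

    ``partition`` is one of ``full``, ``PCG``, ``tRNA``, ``rRNA`` or
    ``gene:<name>``.  Minus-strand features are reverse-complemented so each
    block reads 5'→3'.  Pseudogenes never enter the PCG partition.
    """
    if partition == "full":
        return genome.sequence
    if partition.startswith("gene:"):
        name = partition[5:]
        feats = [f for f in genome.features if f.name == name]
        if not feats:
            raise EmptyPartitionError(f"{genome.identifier}: no gene {name!r}")
        return "".join(feature_sequence(genome, f) for f in feats)
    if partition not in _PARTITION_KINDS:
        raise ValueError(
            f"unknown partition {partition!r}; expected full/PCG/tRNA/rRNA/gene:<name>")
    feats = genome.features_of_kind(*_PARTITION_KINDS[partition])
    if not feats:
        raise EmptyPartitionError(f"{genome.identifier}: partition {partition} is empty")
    return "".join(feature_sequence(genome, f) for f in feats)


def drop_incomplete_stop(cds: str) -> str:
    """Trim a trailing partial codon (incomplete stop) so length % 3 == 0."""
    return cds[: len(cds) - len(cds) % 3]


def coding_sequences(genome: MitoGenome) -> dict[str, str]:
    """name → reading-direction CDS (incomplete stop trimmed), genome order."""
    out: dict[str, str] = {}
    for f in genome.features_of_kind("CDS"):
        out[f.name] = drop_incomplete_stop(feature_sequence(genome, f))
    return out


# --------------------------------------------------------------------------
# inventory report
# --------------------------------------------------------------------------

@dataclass
class InventoryReport:
    """Per-feature table plus spacer/overlap arithmetic and gene bookkeeping."""

    features: pd.DataFrame      # gene, kind, strand, start, end, length
    junctions: pd.DataFrame     # prev, next, spacer (bp; negative = overlap)
    kind_counts: dict[str, int]
    gene_inventory: int         # features counted against the 37-gene inventory
    missing_genes: list[str]

    @property
    def max_spacer(self) -> int:
        sp = self.junctions["spacer"]
        return int(sp[sp > 0].max()) if (sp > 0).any() else 0

    @property
    def min_spacer(self) -> int:
        sp = self.junctions["spacer"]
        return int(sp[sp > 0].min()) if (sp > 0).any() else 0

    @property
    def max_overlap(self) -> int:
        sp = self.junctions["spacer"]
        return int(-sp[sp < 0].min()) if (sp < 0).any() else 0


def inventory_report(genome: MitoGenome) -> InventoryReport:
    """Tabulate features, intergenic spacers and overlaps, and missing genes.

    The spacer between consecutive features is ``next.start − prev.end − 1``;
    negative values are overlaps of that many bp.
    """
    if not genome.features:
        raise ValidationError(f"{genome.identifier}: no features to report")
    rows = [{"gene": f.name, "kind": f.kind, "strand": f.strand, "start": f.start,
             "end": f.end, "length": f.length(genome.length)}
            for f in genome.features]
    fdf = pd.DataFrame(rows)
    junctions = []
    for prev, nxt in zip(genome.features, genome.features[1:]):
        junctions.append({"prev": prev.name, "next": nxt.name,
                          "spacer": nxt.start - prev.end - 1})
    jdf = pd.DataFrame(junctions, columns=["prev", "next", "spacer"])
    kind_counts: dict[str, int] = {}
    for f in genome.features:
        kind_counts[f.kind] = kind_counts.get(f.kind, 0) + 1
    present = {f.name for f in genome.features if f.kind in ("CDS", "tRNA", "rRNA")}
    missing = [g for g in CANONICAL_GENES if g not in present]
    inventory = sum(kind_counts.get(k, 0) for k in ("CDS", "tRNA", "rRNA"))
    return InventoryReport(fdf, jdf, kind_counts, inventory, missing)
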