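"""Concatenated PCG supermatrix assembly and export.

Builds the multi-gene concatenated alignment used for phylogenetic
inference from per-gene alignments (alignment itself is an upstream step),
records per-gene block coordinates and codon-position partitions, and
writes FASTA, relaxed PHYLIP and NEXUS (with charsets) plus a RAxML-style
partition file.  The default gene order is the conventional 13-PCG
concatenation order nad1, nad4, nad3, cox3, cox1, nad4l, cytb, atp8,
nad6, nad2, cox2, atp6, nad5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .codon_usage import GeneticCode

log = logging.getLogger("mitocomp")

#: conventional concatenation order for the 13 mitochondrial PCGs
DEFAULT_GENE_ORDER = ("nad1", "nad4", "nad3", "cox3", "cox1", "nad4l", "cytb",
                      "atp8", "nad6", "nad2", "cox2", "atp6", "nad5")

_NAME_FIXES = {"nad4l": "nad4l", "nad4L": "nad4l"}


def _norm_gene(name: str) -> str:
    return _NAME_FIXES.get(name, name.lower())


@dataclass
class SupermatrixBundle:
    """Taxa, concatenated rows, and per-gene block coordinates (1-based)."""

    taxa: list[str]
    rows: dict[str, str]                     # taxon -> concatenated sequence
    blocks: list[tuple[str, int, int]]       # (gene, start, end) in matrix
    mode: str                                # "nt" or "aa"

    @property
    def length(self) -> int:
        return self.blocks[-1][2] if self.blocks else 0

    def codon_position_partitions(self) -> list[tuple[str, str]]:
        """RAxML-style codon-position partition specs (nt mode only)."""
        if self.mode != "nt":
            raise ValueError("codon positions only apply to nucleotide matrices")
        return [(f"{g}_pos{k}", f"{s + k - 1}-{e}\\3")
                for g, s, e in self.blocks for k in (1, 2, 3)]


def _translate_block(seq: str, code: int, gene: str, taxon: str) -> str:
    gc = GeneticCode.get(code)
    if len(seq) % 3:
        raise ValueError(f"{gene}/{taxon}: aligned length {len(seq)} not "
                         "divisible by 3; cannot translate")
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3].upper()
        if codon == "---":
            out.append("-")
        elif set(codon) - set("ACGT"):
            out.append("X")
        else:
            out.append(gc.translate(codon))
    return "".join(out)


def build_supermatrix(alignments: dict[str, dict[str, str]],
                      order=DEFAULT_GENE_ORDER, mode: str = "nt",
                      code: int = 5, allow_missing: bool = False
                      ) -> SupermatrixBundle:
    """Concatenate per-gene alignments in the given gene order.

    ``alignments`` maps gene → (taxon → aligned sequence).  By default a
    taxon missing from any gene is a hard error; with ``allow_missing`` its
    block is gap-filled with a warning.
    """
    if mode not in ("nt", "aa"):
        raise ValueError("mode must be 'nt' or 'aa'")
    alignments = {_norm_gene(g): taxa for g, taxa in alignments.items()}
    order = [_norm_gene(g) for g in order]
    for g in order:
        if g not in alignments:
            raise ValueError(f"gene {g!r} in order list has no alignment")
    taxa: list[str] = []
    for g in order:
        for t in alignments[g]:
            if t not in taxa:
                taxa.append(t)
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    blocks: list[tuple[str, int, int]] = []
    pos = 0
    for g in order:
        aln = alignments[g]
        lengths = {len(s) for s in aln.values()}
        if len(lengths) != 1:
            raise ValueError(f"gene {g}: aligned lengths differ ({sorted(lengths)})")
        gene_len = lengths.pop()
        if mode == "aa":
            aln = {t: _translate_block(s, code, g, t) for t, s in aln.items()}
            gene_len = len(next(iter(aln.values())))
        for t in taxa:
            if t in aln:
                parts[t].append(aln[t].upper() if mode == "nt" else aln[t])
            elif allow_missing:
                log.warning("gene %s: taxon %s missing, gap-filled", g, t)
                parts[t].append("-" * gene_len)
            else:
                raise ValueError(f"gene {g}: taxon {t!r} missing "
                                 "(use allow_missing to gap-fill)")
        blocks.append((g, pos + 1, pos + gene_len))
        pos += gene_len
    rows = {t: "".join(chunks) for t, chunks in parts.items()}
    return SupermatrixBundle(taxa, rows, blocks, mode)


# --------------------------------------------------------------------------
# writers / reader
# --------------------------------------------------------------------------

def write_matrix(bundle: SupermatrixBundle, path: str | Path,
                 format: str = "fasta") -> None:
    """Write the matrix as fasta, relaxed phylip, or nexus (with charsets)."""
    if not bundle.taxa:
        raise ValueError("empty supermatrix")
    if len(set(bundle.taxa)) != len(bundle.taxa):
        raise ValueError("duplicate taxon names")
    path = Path(path)
    if format == "fasta":
        with open(path, "w") as fh:
            for t in bundle.taxa:
                fh.write(f">{t}\n{bundle.rows[t]}\n")
    elif format == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{len(bundle.taxa)} {bundle.length}\n")
            for t in bundle.taxa:
                fh.write(f"{t[:250]}  {bundle.rows[t]}\n")
    elif format == "nexus":
        dtype = "dna" if bundle.mode == "nt" else "protein"
        with open(path, "w") as fh:
            fh.write("#NEXUS\nbegin data;\n")
            fh.write(f"  dimensions ntax={len(bundle.taxa)} "
                     f"nchar={bundle.length};\n")
            fh.write(f"  format datatype={dtype} missing=? gap=-;\n  matrix\n")
            for t in bundle.taxa:
                fh.write(f"    {t}  {bundle.rows[t]}\n")
            fh.write("  ;\nend;\n\nbegin sets;\n")
            for g, s, e in bundle.blocks:
                fh.write(f"  charset {g} = {s}-{e};\n")
            fh.write("end;\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def write_partition_file(bundle: SupermatrixBundle, path: str | Path,
                         by_codon_position: bool = False) -> None:
    """RAxML-style partition definitions ("DNA, gene = start-end")."""
    dtype = "DNA" if bundle.mode == "nt" else "WAG"
    with open(path, "w") as fh:
        if by_codon_position:
            for name, spec in bundle.codon_position_partitions():
                fh.write(f"{dtype}, {name} = {spec}\n")
        else:
            for g, s, e in bundle.blocks:
                fh.write(f"{dtype}, {g} = {s}-{e}\n")


def read_matrix_fasta(path: str | Path, blocks=None, mode: str = "nt"
                      ) -> SupermatrixBundle:
    """Read a FASTA matrix back (round-trip counterpart of write_matrix)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no sequences")
    rows = {r.id: str(r.seq) for r in records}
    taxa = [r.id for r in records]
    if blocks is None:
        blocks = [("all", 1, len(next(iter(rows.values()))))]
    return SupermatrixBundle(taxa, rows, list(blocks), mode)
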