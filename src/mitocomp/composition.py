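"""Per-partition nucleotide composition, AT/GC content and strand skews.

Skews measure compositional strand asymmetry::

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

computed on base counts of the sense (deposited) strand for the full genome
and on reading-direction sequences for gene partitions.  Reported values are
rounded half-up — percentages to one decimal, skews to three — while full
precision is retained on the dataclass.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .mito_io import EmptyPartitionError, MitoGenome, extract_partition

log = logging.getLogger("mitocomp")


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (Python's round() is banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class BaseStats:
    """One composition row: counts as percentages, AT/GC/GT content, skews.

    ``at_skew``/``gc_skew`` are ``None`` when the respective denominator is
    zero (no A/T or no G/C bases).
    """

    label: str
    size: int
    pct_t: float
    pct_c: float
    pct_a: float
    pct_g: float
    at_pct: float
    gc_pct: float
    gt_pct: float
    at_skew: float | None
    gc_skew: float | None

    def rounded_row(self) -> dict:
        """Reporting view: percentages to 1 decimal, skews to 3."""
        def sk(v):
            return "" if v is None else round_half_up(v, 3)
        return {
            "partition": self.label, "size_bp": self.size,
            "T": round_half_up(self.pct_t, 1), "C": round_half_up(self.pct_c, 1),
            "A": round_half_up(self.pct_a, 1), "G": round_half_up(self.pct_g, 1),
            "AT_pct": round_half_up(self.at_pct, 1),
            "GC_pct": round_half_up(self.gc_pct, 1),
            "GT_pct": round_half_up(self.gt_pct, 1),
            "AT_skew": sk(self.at_skew), "GC_skew": sk(self.gc_skew),
        }


def skew(plus: float, minus: float) -> float | None:
    """(plus - minus)/(plus + minus); None when the denominator is zero."""
    denom = plus + minus
    if denom == 0:
        return None
    return (plus - minus) / denom


def skews_from_percentages(pct_a: float, pct_t: float, pct_c: float,
                           pct_g: float) -> tuple[float | None, float | None]:
    """AT and GC skew computed directly from per-base percentages.

    Used for worked examples where a table prints percentages rather than
    raw counts; the skews are ratio statistics so the normalisation cancels.
    """
    return skew(pct_a, pct_t), skew(pct_g, pct_c)


def base_composition(seq: str, label: str = "sequence") -> BaseStats:
    """Composition statistics of one nucleotide string.

    ``N`` bases are excluded from every denominator (logged when present).
    """
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    seq = seq.upper()
    a, c, g, t = (seq.count(b) for b in "ACGT")
    n_amb = len(seq) - (a + c + g + t)
    if n_amb:
        log.info("%s: %d N bases excluded from composition denominators",
                 label, n_amb)
    total = a + c + g + t
    if total == 0:
        raise ValueError(f"{label}: no unambiguous bases")
    at_skew = skew(a, t)
    gc_skew = skew(g, c)
    if at_skew is None:
        log.warning("%s: A+T = 0, AT skew undefined", label)
    if gc_skew is None:
        log.warning("%s: G+C = 0, GC skew undefined", label)
    pct = {b: 100.0 * x / total for b, x in zip("ACGT", (a, c, g, t))}
    return BaseStats(
        label=label, size=len(seq),
        pct_t=pct["T"], pct_c=pct["C"], pct_a=pct["A"], pct_g=pct["G"],
        at_pct=pct["A"] + pct["T"], gc_pct=pct["C"] + pct["G"],
        gt_pct=pct["G"] + pct["T"], at_skew=at_skew, gc_skew=gc_skew,
    )


#: partition rows of a standard composition table, in reporting order
TABLE_PARTITIONS = ("full", "PCG", "tRNA", "rRNA", "rrnL", "rrnS")

_LABELS = {"full": "Full genome", "PCG": "PCGs", "tRNA": "tRNAs",
           "rRNA": "rRNAs", "rrnL": "rrnL", "rrnS": "rrnS"}


def partition_table(genome: MitoGenome) -> list[BaseStats]:
    """One BaseStats row per available standard partition.

    Absent partitions are skipped with a warning.  The rRNA row is the
    concatenation of rrnL and rrnS blocks in genome order.
    """
    rows: list[BaseStats] = []
    for part in TABLE_PARTITIONS:
        key = part if part in ("full", "PCG", "tRNA", "rRNA") else f"gene:{part}"
        try:
            seq = extract_partition(genome, key)
        except EmptyPartitionError:
            log.warning("%s: partition %s absent, skipped", genome.identifier, part)
            continue
        rows.append(base_composition(seq, _LABELS[part]))
    return rows


def table_to_tsv(rows: list[BaseStats], path) -> None:
    pd.DataFrame([r.rounded_row() for r in rows]).to_csv(path, sep="\t", index=False)


def table_to_json(rows: list[BaseStats], path) -> None:
    """Full-precision JSON variant of the composition table."""
    with open(path, "w") as fh:
        json.dump([r.__dict__ for r in rows], fh, indent=1)
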