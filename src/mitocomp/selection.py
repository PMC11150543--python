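"""Pairwise Nei–Gojobori (1986) ka/ks estimation per protein-coding gene.

The NG86 counting method:

* every codon contributes fractional synonymous (s) and nonsynonymous (n)
  site counts, s = (number of synonymous one-step changes)/3 summed over
  the three positions, n = 3 − s; changes into stop codons count as
  nonsynonymous (the standard convention);
* for a codon pair differing at k positions, the k! mutational pathways
  are enumerated and the synonymous/nonsynonymous difference counts are
  averaged over pathways that avoid intermediate stop codons (if every
  pathway passes through a stop, the unrestricted average is used, with a
  logged note);
* proportions pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
  d = −(3/4)·ln(1 − (4/3)p), giving ks and ka, and ω = ka/ks.

ω < 1 indicates purifying selection.  Sequences must be codon-aligned;
codon columns containing gaps, N, or an in-frame stop are skipped pairwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, permutations

import pandas as pd

from .codon_usage import GeneticCode

log = logging.getLogger("mitocomp")

_BASES = "ACGT"


class UndefinedDistanceError(ValueError):
    """Raised when no codon column is usable for a pair."""


# --------------------------------------------------------------------------
# per-codon site counting
# --------------------------------------------------------------------------

def codon_sites(codon: str, code: int = 5) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Each of the nine single-nucleotide changes is classified; changes to
    stop codons are nonsynonymous.  s + n = 3 exactly.
    """
    gc = GeneticCode.get(code)
    codon = codon.upper()
    if set(codon) - set(_BASES) or len(codon) != 3:
        raise ValueError(f"invalid codon {codon!r}")
    if codon in gc.stop_codons:
        raise ValueError(f"stop codon {codon} has no defined site counts")
    aa = gc.aa[codon]
    syn = 0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant not in gc.stop_codons and gc.aa[mutant] == aa:
                syn += 1
    s = syn / 3.0
    return s, 3.0 - s


def _pathway_differences(ca: str, cb: str, gc: GeneticCode
                         ) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) for one differing codon pair."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    valid: list[tuple[int, int]] = []
    unrestricted: list[tuple[int, int]] = []
    for order in permutations(positions):
        cur = ca
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in gc.stop_codons:
                blocked = True
                step_syn = False  # stop change counted nonsynonymous
            else:
                step_syn = (cur not in gc.stop_codons
                            and gc.aa.get(cur) == gc.aa.get(nxt))
            if step_syn:
                sd += 1
            else:
                nd += 1
            cur = nxt
        unrestricted.append((sd, nd))
        if not blocked:
            valid.append((sd, nd))
    pool = valid
    if not pool:
        log.info("codon pair %s/%s: all pathways pass through stops; "
                 "using unrestricted pathway average", ca, cb)
        pool = unrestricted
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when p >= 3/4 (saturated)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


# --------------------------------------------------------------------------
# pairwise estimate
# --------------------------------------------------------------------------

@dataclass
class KaKsResult:
    """NG86 site/difference counts and corrected distances for one pair."""

    id_a: str
    id_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    ks: float | None
    ka: float | None
    omega: float | None
    codons_used: int


def pairwise_ng86(seq_a: str, seq_b: str, code: int = 5,
                  id_a: str = "A", id_b: str = "B") -> KaKsResult:
    """NG86 ka/ks for one codon-aligned sequence pair.

    Codon columns containing gaps, N or an in-frame stop in either
    sequence are skipped.  ``omega`` is None when ks is zero or either
    corrected distance is undefined (saturation).
    """
    gc = GeneticCode.get(code)
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError(f"{id_a}/{id_b}: aligned lengths differ "
                         f"({len(seq_a)} vs {len(seq_b)})")
    if len(seq_a) % 3:
        raise ValueError(f"{id_a}/{id_b}: alignment length {len(seq_a)} "
                         "not divisible by 3")
    S = N = Sd = Nd = 0.0
    used = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if (set(ca) | set(cb)) - set(_BASES):
            continue  # gap or ambiguity in the column
        if ca in gc.stop_codons or cb in gc.stop_codons:
            continue
        sa, na = codon_sites(ca, code)
        sb, nb = codon_sites(cb, code)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        if ca != cb:
            sd, nd = _pathway_differences(ca, cb, gc)
            Sd += sd
            Nd += nd
        used += 1
    if used == 0:
        raise UndefinedDistanceError(
            f"{id_a}/{id_b}: zero overlapping usable codons")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ks = jukes_cantor(pS)
    ka = jukes_cantor(pN)
    if ks is None:
        log.warning("%s/%s: pS = %.3f >= 3/4, ks undefined", id_a, id_b, pS)
    if ka is None:
        log.warning("%s/%s: pN = %.3f >= 3/4, ka undefined", id_a, id_b, pN)
    omega = None
    if ka is not None and ks is not None and ks > 0:
        omega = ka / ks
    return KaKsResult(id_a, id_b, S, N, Sd, Nd, pS, pN, ks, ka, omega, used)


# --------------------------------------------------------------------------
# gene-level aggregation
# --------------------------------------------------------------------------

@dataclass
class GeneOmegaSummary:
    """Per-gene ka/ks aggregated over all unordered taxon pairs.

    ``omega`` is the ratio of means (mean ka / mean ks), robust to pairs
    with ks ≈ 0; ``omega_mean_of_ratios`` is the alternative aggregation
    (mean of per-pair ka/ks over pairs where it is defined), emitted for
    comparison since published per-gene values rarely state which was used.
    """

    gene: str
    mean_ka: float | None
    mean_ks: float | None
    omega: float | None
    omega_mean_of_ratios: float | None
    n_pairs: int

    @property
    def purifying(self) -> bool | None:
        return None if self.omega is None else self.omega < 1.0


def gene_omega(alignment, code: int = 5, gene: str = "gene") -> GeneOmegaSummary:
    """Aggregate NG86 over all unordered pairs of a per-gene alignment.

    ``alignment`` is a taxon→sequence mapping or list of (taxon, sequence)
    pairs (codon-aligned, equal lengths).
    """
    if isinstance(alignment, dict):
        items = list(alignment.items())
    else:
        items = list(alignment)
    if len(items) < 2:
        raise ValueError(f"{gene}: need >= 2 taxa, got {len(items)}")
    kas, kss, ratios = [], [], []
    n_pairs = 0
    for (na, sa), (nb, sb) in combinations(items, 2):
        res = pairwise_ng86(sa, sb, code, na, nb)
        n_pairs += 1
        if res.ka is not None and res.ks is not None:
            kas.append(res.ka)
            kss.append(res.ks)
        if res.omega is not None:
            ratios.append(res.omega)
    if not kas:
        log.warning("%s: every pair undefined; no summary", gene)
        return GeneOmegaSummary(gene, None, None, None, None, n_pairs)
    mean_ka = sum(kas) / len(kas)
    mean_ks = sum(kss) / len(kss)
    omega = mean_ka / mean_ks if mean_ks > 0 else None
    mean_ratio = sum(ratios) / len(ratios) if ratios else None
    return GeneOmegaSummary(gene, mean_ka, mean_ks, omega, mean_ratio, n_pairs)


def rank_genes(summaries: list[GeneOmegaSummary]) -> pd.DataFrame:
    """Genes ranked by ω ascending (most conserved first)."""
    rows = [{"gene": s.gene, "ka": s.mean_ka, "ks": s.mean_ks,
             "omega": s.omega, "omega_mean_of_ratios": s.omega_mean_of_ratios,
             "n_pairs": s.n_pairs} for s in summaries]
    df = pd.DataFrame(rows)
    return df.sort_values("omega", na_position="last").reset_index(drop=True)


def pairwise_table(alignment, code: int = 5, gene: str = "gene") -> pd.DataFrame:
    """All pairwise KaKsResult rows for one gene alignment."""
    items = list(alignment.items()) if isinstance(alignment, dict) else list(alignment)
    rows = []
    for (na, sa), (nb, sb) in combinations(items, 2):
        r = pairwise_ng86(sa, sb, code, na, nb)
        rows.append({"gene": gene, "taxon_a": na, "taxon_b": nb, "S": r.S,
                     "N": r.N, "Sd": r.Sd, "Nd": r.Nd, "pS": r.pS, "pN": r.pN,
                     "ks": r.ks, "ka": r.ka, "omega": r.omega,
                     "codons_used": r.codons_used})
    return pd.DataFrame(rows)
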