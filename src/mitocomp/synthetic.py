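"""Synthetic annotated mitogenomes and mutated CDS pairs with known truth.

The generator emulates a pentatomid-style circular mitogenome: an AT-rich
(~72–74% AT) molecule of ~15–17 kb carrying 13 protein-coding genes, 22
tRNAs and 2 rRNAs on two strands in the ancestral insect gene order, with
a large control region.  Perfect microsatellites can be embedded at known
coordinates and the background is scrubbed of incidental repeats meeting
the scanner thresholds, so the scanner's expected output is exactly the
embedded truth.  CDS are valid invertebrate-mitochondrial-code ORFs
(start ∈ {ATA, ATT, ATG, TTG}, no internal stops), and minus-strand genes
are generated in reading orientation then reverse-complemented into the
genome, exercising strand handling end-to-end.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; a fixed seed reproduces the output exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .codon_usage import GeneticCode
from .mito_io import Feature, MitoGenome, reverse_complement
from .ssr import (DEFAULT_THRESHOLDS, CONTROL_REGION_LABEL, INTERGENIC_LABEL,
                  SSRThresholds, scan_ssrs, smallest_period)

log = logging.getLogger("mitocomp")

_BASES = ("A", "C", "G", "T")
START_CODONS = ("ATA", "ATT", "ATG", "TTG")

#: ancestral insect / pentatomid gene order (23 sense / 14 antisense).
#: kind "intergenic" entries are unannotated spacers; the control region
#: length is filled to the requested genome length.
DEFAULT_LAYOUT: tuple[tuple[str, str, int, str], ...] = (
    ("trnI", "tRNA", 66, "+"), ("trnQ", "tRNA", 69, "-"), ("trnM", "tRNA", 66, "+"),
    ("nad2", "CDS", 1020, "+"), ("trnW", "tRNA", 66, "+"), ("trnC", "tRNA", 63, "-"),
    ("trnY", "tRNA", 66, "-"), ("cox1", "CDS", 1536, "+"), ("trnL2", "tRNA", 66, "+"),
    ("cox2", "CDS", 684, "+"), ("trnK", "tRNA", 69, "+"), ("trnD", "tRNA", 66, "+"),
    ("atp8", "CDS", 156, "+"), ("atp6", "CDS", 672, "+"), ("cox3", "CDS", 789, "+"),
    ("trnG", "tRNA", 63, "+"), ("nad3", "CDS", 354, "+"), ("trnA", "tRNA", 63, "+"),
    ("trnR", "tRNA", 63, "+"), ("trnN", "tRNA", 66, "+"), ("trnS1", "tRNA", 66, "+"),
    ("trnE", "tRNA", 63, "+"), ("trnF", "tRNA", 63, "-"), ("nad5", "CDS", 1677, "-"),
    ("trnH", "tRNA", 63, "-"), ("nad4", "CDS", 1341, "-"), ("nad4l", "CDS", 264, "-"),
    ("trnT", "tRNA", 63, "+"), ("trnP", "tRNA", 63, "-"), ("nad6", "CDS", 495, "+"),
    ("cytb", "CDS", 1137, "+"), ("trnS2", "tRNA", 66, "+"),
    ("spacer1", "intergenic", 300, "+"),
    ("nad1", "CDS", 924, "-"), ("trnL1", "tRNA", 66, "-"), ("rrnL", "rRNA", 657, "-"),
    ("trnV", "tRNA", 66, "-"), ("rrnS", "rRNA", 791, "-"),
)

#: AT-rich composition typical of a pentatomid mitogenome (percent)
DEFAULT_BASE_PCT = {"A": 42.5, "C": 15.0, "G": 11.0, "T": 31.5}


@dataclass(frozen=True)
class SSRInsert:
    """A perfect repeat to embed: motif × n_units at a location class.

    ``location`` is a gene name (e.g. "nad4"), "intergenic", or
    "control_region".
    """

    motif: str
    n_units: int
    location: str

    @property
    def size(self) -> int:
        return len(self.motif) * self.n_units


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic genome."""

    length: int = 15500
    base_pct: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_PCT))
    layout: tuple = DEFAULT_LAYOUT
    ssrs: tuple[SSRInsert, ...] = ()
    seed: int = 0
    identifier: str = "synthetic"
    thresholds: SSRThresholds = DEFAULT_THRESHOLDS

    def __post_init__(self):
        total = sum(self.base_pct.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"base percentages sum to {total}, expected 100")
        genic = sum(ln for _, _, ln, _ in self.layout)
        if genic + 1 > self.length:
            raise ValueError(f"layout needs {genic} bp but genome length is "
                             f"{self.length}")


def demo_genome_spec(seed: int = 0) -> SyntheticSpec:
    """A 17,197-bp AT-rich genome with three embedded repeats.

    Mirrors the worked configuration used throughout the tests: AAAT×3 in
    nad4, TAT×6 in nad6 and AATT×3 in an intergenic spacer.
    """
    return SyntheticSpec(
        length=17197,
        ssrs=(SSRInsert("AAAT", 3, "nad4"),
              SSRInsert("TAT", 6, "nad6"),
              SSRInsert("AATT", 3, "intergenic")),
        seed=seed, identifier=f"synthetic_demo_{seed}")


# --------------------------------------------------------------------------
# genome generation
# --------------------------------------------------------------------------

def _probs(base_pct: dict[str, float]) -> np.ndarray:
    p = np.array([base_pct[b] for b in _BASES], dtype=float)
    return p / p.sum()


def _draw_bases(rng: np.random.Generator, k: int, probs: np.ndarray) -> list[str]:
    idx = rng.choice(4, size=k, p=probs)
    return [_BASES[i] for i in idx]


def _random_orf(rng: np.random.Generator, length: int, probs: np.ndarray,
                gc: GeneticCode) -> str:
    """A reading-direction ORF: start codon, non-stop body, TAA stop."""
    if length % 3 or length < 9:
        raise ValueError(f"CDS length {length} must be a multiple of 3, >= 9")
    codons = [START_CODONS[rng.integers(len(START_CODONS))]]
    need = length // 3 - 2
    got = 0
    while got < need:
        c = "".join(_draw_bases(rng, 3, probs))
        if c in gc.stop_codons:
            continue
        codons.append(c)
        got += 1
    codons.append("TAA")
    return "".join(codons)


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing exactly to ``total``."""
    base = np.floor(targets).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(targets - base))
        base[order[:short]] += 1
    elif short < 0:
        order = np.argsort(targets - base)
        for i in order:
            if base[i] > 0 and short < 0:
                base[i] -= 1
                short += 1
    return base


@dataclass
class _Region:
    name: str
    kind: str
    start0: int   # 0-based inclusive
    end0: int     # 0-based exclusive
    strand: str


def _plan_regions(spec: SyntheticSpec) -> list[_Region]:
    regions = []
    pos = 0
    for name, kind, length, strand in spec.layout:
        regions.append(_Region(name, kind, pos, pos + length, strand))
        pos += length
    cr_len = spec.length - pos
    regions.append(_Region("control_region", "control_region", pos, spec.length, "+"))
    if cr_len < 1:
        raise ValueError("no room left for a control region")
    return regions


class GenerationError(RuntimeError):
    """The spec could not be realized (infeasible placement or scrub cap)."""


def _codon_positions(region: _Region, codon_idx: int) -> list[int]:
    """Genome (0-based) positions of one reading-direction codon."""
    if region.strand == "+":
        g = region.start0 + 3 * codon_idx
        return [g, g + 1, g + 2]
    g = region.end0 - 1 - 3 * codon_idx
    return [g, g - 1, g - 2]


def _read_codon(seq: list[str], region: _Region, codon_idx: int) -> str:
    pos = _codon_positions(region, codon_idx)
    chars = [seq[p] for p in pos]
    if region.strand == "-":
        chars = [reverse_complement(c) for c in chars]
    return "".join(chars)


def _write_codon(seq: list[str], region: _Region, codon_idx: int, codon: str) -> None:
    pos = _codon_positions(region, codon_idx)
    chars = list(codon)
    if region.strand == "-":
        chars = [reverse_complement(c) for c in chars]
    for p, ch in zip(pos, chars):
        seq[p] = ch


def _place_ssr(seq: list[str], region: _Region, insert: SSRInsert,
               rng: np.random.Generator, probs: np.ndarray, gc: GeneticCode,
               occupied: list[tuple[int, int]], margin: int = 3,
               tries: int = 400) -> tuple[int, int]:
    """Write the repeat into the region; returns 0-based [start, end)."""
    size = insert.size
    lo = region.start0 + margin
    hi = region.end0 - margin - size
    if region.kind == "CDS":
        lo = max(lo, region.start0 + 3)
        hi = min(hi, region.end0 - 3 - size)
    if hi < lo:
        raise GenerationError(
            f"SSR {insert.motif}x{insert.n_units} does not fit in "
            f"{region.name} ({region.end0 - region.start0} bp)")
    n_codons = (region.end0 - region.start0) // 3
    for _ in range(tries):
        s = int(rng.integers(lo, hi + 1))
        span = (s, s + size)
        if any(span[0] <= e + 2 and span[1] - 1 >= b - 2 for b, e in occupied):
            continue
        saved = seq[span[0]:span[1]]
        seq[span[0]:span[1]] = list(insert.motif * insert.n_units)
        if region.kind != "CDS":
            return span
        # keep the host ORF stop-free: check every codon touching the span
        if region.strand == "+":
            c0 = (span[0] - region.start0) // 3
            c1 = (span[1] - 1 - region.start0) // 3
        else:
            c0 = (region.end0 - span[1]) // 3
            c1 = (region.end0 - 1 - span[0]) // 3
        ok = True
        for ci in range(c0, c1 + 1):
            if ci <= 0 or ci >= n_codons - 1:
                ok = False
                break
            codon = _read_codon(seq, region, ci)
            if codon not in gc.stop_codons:
                continue
            # boundary codon: redraw its non-repeat bases to break the stop
            pos = _codon_positions(region, ci)
            free = [k for k, p in enumerate(pos) if not span[0] <= p < span[1]]
            if not free:
                ok = False
                break
            fixed = False
            for _ in range(30):
                cand = list(codon)
                for k in free:
                    cand[k] = _draw_bases(rng, 1, probs)[0]
                if "".join(cand) not in gc.stop_codons:
                    _write_codon(seq, region, ci, "".join(cand))
                    fixed = True
                    break
            if not fixed:
                ok = False
                break
        if ok:
            return span
        seq[span[0]:span[1]] = saved
    raise GenerationError(
        f"could not place SSR {insert.motif}x{insert.n_units} in {region.name} "
        f"after {tries} attempts")


def _location_label(region: _Region) -> str:
    if region.kind == "intergenic":
        return INTERGENIC_LABEL
    if region.kind == "control_region":
        return CONTROL_REGION_LABEL
    return region.name


def generate_genome(spec: SyntheticSpec) -> tuple[MitoGenome, dict]:
    """Realize a spec into a genome plus a complete ground-truth record.

    Post-conditions: realized composition within ±1% of targets, every
    embedded repeat is recovered by the scanner at its recorded
    coordinates, and no other repeat meeting the thresholds exists.
    """
    rng = np.random.default_rng(spec.seed)
    gc = GeneticCode.get(5)
    probs = _probs(spec.base_pct)
    regions = _plan_regions(spec)
    by_name = {r.name: r for r in regions}
    for ins in spec.ssrs:
        if set(ins.motif) - set(_BASES):
            raise ValueError(f"SSR motif {ins.motif!r} must be over ACGT")
        if smallest_period(ins.motif * 2) != len(ins.motif):
            raise ValueError(f"SSR motif {ins.motif!r} is not primitive")
        if ins.n_units < spec.thresholds.min_units[len(ins.motif)]:
            raise ValueError(
                f"{ins.motif}x{ins.n_units} is below the scan threshold and "
                "would not be recoverable")

    seq: list[str] = [""] * spec.length

    # 1. protein-coding genes first (they dominate the composition)
    for r in regions:
        if r.kind != "CDS":
            continue
        orf = _random_orf(rng, r.end0 - r.start0, probs, gc)
        block = reverse_complement(orf) if r.strand == "-" else orf
        seq[r.start0:r.end0] = list(block)

    # 2. fill remaining positions with a composition-compensating multiset
    target = _probs(spec.base_pct) * spec.length
    genic = np.array([sum(1 for ch in seq if ch == b) for b in _BASES], float)
    free_idx = [i for i, ch in enumerate(seq) if ch == ""]
    needed = np.clip(target - genic, 0.0, None)
    if needed.sum() == 0:
        needed = target.copy()
    needed *= len(free_idx) / needed.sum()
    alloc = _largest_remainder(needed, len(free_idx))
    pool = np.repeat(np.arange(4), alloc)
    rng.shuffle(pool)
    for i, b in zip(free_idx, pool):
        seq[i] = _BASES[b]

    # 3. embed the requested repeats
    truth_ssrs = []
    occupied: list[tuple[int, int]] = []
    for ins in spec.ssrs:
        if ins.location == "intergenic":
            cands = [r for r in regions if r.kind == "intergenic"
                     and r.end0 - r.start0 >= ins.size + 6]
            if not cands:
                raise GenerationError(
                    f"no intergenic spacer can host {ins.motif}x{ins.n_units}")
            region = cands[int(rng.integers(len(cands)))]
        elif ins.location == "intergenic_or_cr":
            # panel convenience: spill into the control region when the
            # spacer is already crowded
            spacers = [r for r in regions if r.kind == "intergenic"]
            region = spacers[int(rng.integers(len(spacers)))] if spacers else None
            try:
                if region is None:
                    raise GenerationError("no spacer")
                span = _place_ssr(seq, region, ins, rng, probs, gc, occupied,
                                  tries=100)
            except GenerationError:
                region = by_name["control_region"]
            else:
                occupied.append((span[0], span[1] - 1))
                truth_ssrs.append({"motif": ins.motif, "n_units": ins.n_units,
                                   "size": ins.size, "start": span[0] + 1,
                                   "end": span[1],
                                   "location": _location_label(region)})
                continue
        elif ins.location == "control_region":
            region = by_name["control_region"]
        else:
            if ins.location not in by_name:
                raise GenerationError(f"SSR host {ins.location!r} not in layout")
            region = by_name[ins.location]
        span = _place_ssr(seq, region, ins, rng, probs, gc, occupied)
        occupied.append((span[0], span[1] - 1))
        truth_ssrs.append({"motif": ins.motif, "n_units": ins.n_units,
                           "size": ins.size, "start": span[0] + 1,
                           "end": span[1], "location": _location_label(region)})

    # 4. scrub incidental repeats so the scanner output equals the truth
    _scrub(seq, regions, truth_ssrs, spec, rng, probs, gc)

    features = [Feature(r.name, r.kind, r.start0 + 1, r.end0, r.strand)
                for r in regions if r.kind != "intergenic"]
    genome = MitoGenome(spec.identifier, "".join(seq), True, features)
    counts = {b: genome.sequence.count(b) for b in _BASES}
    for b in _BASES:
        drift = abs(100.0 * counts[b] / spec.length - spec.base_pct[b])
        if drift > 1.0:
            log.warning("%s: %s composition drifted %.2f%% from target",
                        spec.identifier, b, drift)
    truth = {
        "identifier": spec.identifier, "seed": spec.seed, "length": spec.length,
        "base_counts": counts,
        "features": [{"name": f.name, "kind": f.kind, "start": f.start,
                      "end": f.end, "strand": f.strand} for f in features],
        "ssrs": truth_ssrs,
    }
    return genome, truth


def _scrub(seq, regions, truth_ssrs, spec, rng, probs, gc, cap: int = 1000):
    truth_keys = {(t["motif"], t["n_units"], t["start"], t["end"])
                  for t in truth_ssrs}
    truth_pos = set()
    for t in truth_ssrs:
        truth_pos.update(range(t["start"] - 1, t["end"]))
    cds_regions = [r for r in regions if r.kind == "CDS"]

    def owner(pos0):
        for r in cds_regions:
            if r.start0 <= pos0 < r.end0:
                return r
        return None

    for iteration in range(cap):
        found = scan_ssrs("".join(seq), spec.thresholds)
        bad = [r for r in found
               if (r.motif, r.n_units, r.start, r.end) not in truth_keys]
        if not bad:
            missing = truth_keys - {(r.motif, r.n_units, r.start, r.end)
                                    for r in found}
            if missing:
                raise GenerationError(
                    f"embedded repeats lost during generation: {missing}")
            return
        for rec in bad:
            eligible = [p for p in range(rec.start - 1, rec.end)
                        if p not in truth_pos]
            if not eligible:
                raise GenerationError(
                    f"incidental repeat {rec.motif}x{rec.n_units} at "
                    f"{rec.start} lies wholly inside an embedded repeat")
            done_codons = set()
            touched = False
            for p in eligible:
                r = owner(p)
                if r is None:
                    seq[p] = _draw_bases(rng, 1, probs)[0]
                    touched = True
                    continue
                if r.strand == "+":
                    ci = (p - r.start0) // 3
                else:
                    ci = (r.end0 - 1 - p) // 3
                n_codons = (r.end0 - r.start0) // 3
                if ci <= 0 or ci >= n_codons - 1 or (r.name, ci) in done_codons:
                    continue
                done_codons.add((r.name, ci))
                pos = _codon_positions(r, ci)
                free = [k for k, gp in enumerate(pos) if gp not in truth_pos]
                codon = list(_read_codon(seq, r, ci))
                for _ in range(30):
                    cand = list(codon)
                    for k in free:
                        cand[k] = _draw_bases(rng, 1, probs)[0]
                    if "".join(cand) not in gc.stop_codons:
                        _write_codon(seq, r, ci, "".join(cand))
                        touched = True
                        break
            if not touched:
                raise GenerationError(
                    f"cannot scrub incidental repeat at {rec.start}: every "
                    "position is protected")
    raise GenerationError(
        f"scrub loop exceeded {cap} iterations for {spec.identifier}; "
        "spec may be adversarial (highly repetitive composition)")


# --------------------------------------------------------------------------
# mutated CDS pairs / alignments with known substitution truth
# --------------------------------------------------------------------------

def _one_step_options(codon: str, gc: GeneticCode):
    syn, nonsyn = [], []
    aa = gc.aa[codon]
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if mut in gc.stop_codons:
                continue
            (syn if gc.aa[mut] == aa else nonsyn).append((pos, alt))
    return syn, nonsyn


def mutate_cds_pair(cds: str, n_syn: int, n_nonsyn: int, seed: int = 0,
                    code: int = 5) -> tuple[str, str, list[dict]]:
    """Derive a partner CDS differing by exact substitution counts.

    Returns ``(copy_a, copy_b, truth)`` where copy_b carries exactly
    ``n_syn`` synonymous and ``n_nonsyn`` nonsynonymous single-nucleotide
    changes, at most one per codon, never creating a stop codon; the start
    and stop codons are left untouched.  ``truth`` lists each change with
    its codon index, position, bases and classification.
    """
    rng = np.random.default_rng(seed)
    gc = GeneticCode.get(code)
    cds = cds.upper()
    if len(cds) % 3 or len(cds) < 9:
        raise ValueError("CDS must be in-frame with >= 3 codons")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons[:-1]):
        if c in gc.stop_codons:
            raise ValueError(f"internal stop codon {c} at codon {i + 1}")
    eligible = list(range(1, len(codons) - 1))
    syn_ok = [i for i in eligible if _one_step_options(codons[i], gc)[0]]
    nonsyn_ok = [i for i in eligible if _one_step_options(codons[i], gc)[1]]
    if len(syn_ok) < n_syn:
        raise ValueError(f"only {len(syn_ok)} codons admit a synonymous "
                         f"change; {n_syn} requested")
    chosen_syn = set(rng.choice(syn_ok, size=n_syn, replace=False)) if n_syn else set()
    nonsyn_pool = [i for i in nonsyn_ok if i not in chosen_syn]
    if len(nonsyn_pool) < n_nonsyn:
        raise ValueError(f"only {len(nonsyn_pool)} codons admit a "
                         f"nonsynonymous change; {n_nonsyn} requested")
    chosen_nonsyn = (set(rng.choice(nonsyn_pool, size=n_nonsyn, replace=False))
                     if n_nonsyn else set())
    out = list(codons)
    truth = []
    for i in sorted(chosen_syn | chosen_nonsyn):
        kind = "syn" if i in chosen_syn else "nonsyn"
        options = _one_step_options(codons[i], gc)[0 if kind == "syn" else 1]
        pos, alt = options[int(rng.integers(len(options)))]
        ref = codons[i][pos]
        out[i] = codons[i][:pos] + alt + codons[i][pos + 1:]
        truth.append({"codon_index": i, "position": pos, "ref": ref,
                      "alt": alt, "kind": kind})
    return cds, "".join(out), truth


def make_gene_alignment(base_cds: str, n_taxa: int, n_syn: int, n_nonsyn: int,
                        seed: int = 0, code: int = 5
                        ) -> tuple[dict[str, str], dict[str, list[dict]]]:
    """Star-shaped alignment: each taxon mutated independently from a base."""
    if n_taxa < 2:
        raise ValueError("need >= 2 taxa")
    rng = np.random.default_rng(seed)
    aln, truths = {}, {}
    for i in range(n_taxa):
        sub = int(rng.integers(2 ** 31))
        name = f"taxon{i + 1:02d}"
        _, variant, truth = mutate_cds_pair(base_cds, n_syn, n_nonsyn, sub, code)
        aln[name] = variant
        truths[name] = truth
    return aln, truths


def random_orf(length: int, seed: int = 0,
               base_pct: dict[str, float] | None = None) -> str:
    """Standalone valid table-5 ORF, for building test alignments."""
    rng = np.random.default_rng(seed)
    return _random_orf(rng, length, _probs(base_pct or DEFAULT_BASE_PCT),
                       GeneticCode.get(5))


# --------------------------------------------------------------------------
# multi-genome panels
# --------------------------------------------------------------------------

#: pooled motif-class frequencies used when drawing random repeats
PANEL_CLASS_PROBS = {1: 0.014, 2: 0.045, 3: 0.404, 4: 0.431, 5: 0.090, 6: 0.016}

#: host-gene weights for coding-region repeats
PANEL_HOST_WEIGHTS = {"nad6": 0.18, "nad4": 0.14, "nad2": 0.11, "rrnL": 0.13,
                      "nad5": 0.12, "cox1": 0.10, "cytb": 0.08, "nad1": 0.08,
                      "cox3": 0.06}


def cds_motif_compatible(motif: str, strand: str) -> bool:
    """Can a tandem run of this genome-strand motif avoid in-frame stops?

    A repeat inside a CDS is read in the gene's direction; some AT-rich
    motifs (e.g. TAAA on a plus-strand gene) contain a stop codon in every
    reading frame and can only be hosted by genes on the other strand.
    """
    gc = GeneticCode.get(5)
    read = motif if strand == "+" else reverse_complement(motif)
    rep = read * 9
    for phase in range(3):
        codons = [rep[i:i + 3] for i in range(phase, phase + 3 * len(read), 3)]
        if all(c not in gc.stop_codons for c in codons):
            return True
    return False


def _random_motif(rng: np.random.Generator, period: int, at_only: bool) -> str:
    alphabet = ("A", "T") if at_only else _BASES
    for _ in range(100):
        motif = "".join(alphabet[int(rng.integers(len(alphabet)))]
                        for _ in range(period))
        if not at_only and set(motif) <= {"A", "T"}:
            continue
        if smallest_period(motif * 2) == period:
            return motif
    raise GenerationError(f"could not draw a primitive period-{period} motif")


@dataclass
class PanelModel:
    """Linear SSR-count model: count ≈ slope·size_kb + intercept + noise."""

    slope: float = 5.3          # repeats per kb of genome size
    intercept: float = -75.0
    noise_sd: float = 2.2
    coding_fraction: float = 0.7
    at_only_prob: float = 0.988


def generate_panel(n_species: int = 56,
                   size_range: tuple[int, int] = (14800, 18000),
                   model: PanelModel | None = None, seed: int = 0
                   ) -> tuple[list[MitoGenome], list[dict]]:
    """A panel of synthetic genomes with a known count-vs-size relation.

    Genome sizes are uniform over ``size_range``; the number of embedded
    repeats per genome follows the panel's linear model with seeded
    Gaussian noise (clipped at zero).  Per-species truth records include
    every embedded repeat and the realized model draw.
    """
    if n_species < 3:
        raise ValueError("need >= 3 species for a panel")
    model = model or PanelModel()
    rng = np.random.default_rng(seed)
    thresholds = DEFAULT_THRESHOLDS
    genomes, truths = [], []
    class_ids = sorted(PANEL_CLASS_PROBS)
    class_p = np.array([PANEL_CLASS_PROBS[k] for k in class_ids])
    class_p = class_p / class_p.sum()
    layout_info = {name: (kind, strand) for name, kind, _, strand in DEFAULT_LAYOUT}
    for i in range(n_species):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        expected = model.slope * size / 1000.0 + model.intercept
        count = max(0, int(round(expected + rng.normal(0.0, model.noise_sd))))
        inserts = []
        for _ in range(count):
            period = class_ids[int(rng.choice(len(class_ids), p=class_p))]
            at_only = bool(rng.random() < model.at_only_prob)
            motif = _random_motif(rng, period, at_only)
            units = thresholds.min_units[period] + int(rng.integers(0, 3))
            if rng.random() < model.coding_fraction:
                ok = [h for h in sorted(PANEL_HOST_WEIGHTS)
                      if layout_info[h][0] == "rRNA"
                      or cds_motif_compatible(motif, layout_info[h][1])]
                if not ok:
                    ok = ["rrnL"]
                host_p = np.array([PANEL_HOST_WEIGHTS[h] for h in ok])
                location = ok[int(rng.choice(len(ok), p=host_p / host_p.sum()))]
            else:
                location = ("intergenic_or_cr" if rng.random() < 0.5
                            else "control_region")
            inserts.append(SSRInsert(motif, units, location))
        spec = SyntheticSpec(length=size, ssrs=tuple(inserts),
                             seed=int(rng.integers(2 ** 31)),
                             identifier=f"panel{i + 1:02d}")
        genome, truth = generate_genome(spec)
        truth["model_expected_count"] = expected
        truth["n_ssrs"] = count
        genomes.append(genome)
        truths.append(truth)
    return genomes, truths
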