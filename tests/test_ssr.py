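"""Perfect-repeat scanner, compound merging, location classes, RA/RD."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp import (
    DEFAULT_THRESHOLDS, Feature, MitoGenome, SSRThresholds, classify_locations,
    cross_species_summary, merge_compound, scan_ssrs, smallest_period,
    ssr_stats,
)
from mitocomp.ssr import CONTROL_REGION_LABEL, INTERGENIC_LABEL, coding_fraction

# flanks verified free of threshold-passing repeats
FLANK_A = "GATCCGTACGTCAGTCCATGGACTGCATCGGATACGCTAGCATGCGATC"
FLANK_B = "CGATGCTAGCGTATCCGGATGCATCAGTCCATGACGTACGGATCGCATG"


def oracle_scan(seq, thresholds=DEFAULT_THRESHOLDS):
    """Independent all-substrings enumerator of maximal primitive repeats."""
    n = len(seq)
    out = set()
    for p in range(1, 7):
        for s in range(n - p):
            if s > 0 and seq[s - 1] == seq[s - 1 + p] and seq[s - 1] != "N":
                continue  # not the leftmost start of this run
            motif = seq[s:s + p]
            if "N" in motif or len(motif) < p:
                continue
            if smallest_period(motif * 2) != p:
                continue  # non-primitive motif
            u = 1
            while seq[s + u * p:s + (u + 1) * p] == motif:
                u += 1
            if u < thresholds.min_units[p]:
                continue
            # the run (incl. partial tail) must not have a smaller period
            m = 0
            while s + m + p < n and seq[s + m] == seq[s + m + p] != "N":
                m += 1
            if smallest_period(seq[s:s + m + p]) != p:
                continue
            out.add((motif, u, s + 1, s + u * p))
    return sorted(out, key=lambda r: (r[2], len(r[0])))


def as_tuples(records):
    return [(r.motif, r.n_units, r.start, r.end) for r in records]


class TestScanner:
    def test_tat_times_six_is_one_18bp_record(self):
        seq = FLANK_A + "TAT" * 6 + FLANK_B
        recs = scan_ssrs(seq)
        assert len(recs) == 1
        r = recs[0]
        assert (r.motif, r.n_units, r.size) == ("TAT", 6, 18)
        assert r.start == len(FLANK_A) + 1
        assert r.end == len(FLANK_A) + 18

    def test_mononucleotide_threshold_boundary(self):
        assert scan_ssrs(FLANK_A + "A" * 11 + FLANK_B) == []
        recs = scan_ssrs(FLANK_A + "A" * 12 + FLANK_B)
        assert as_tuples(recs) == [("A", 12, len(FLANK_A) + 1, len(FLANK_A) + 12)]

    def test_partial_trailing_unit_excluded(self):
        seq = FLANK_A + "AAAT" * 3 + "AA" + FLANK_B
        recs = scan_ssrs(seq)
        assert len(recs) == 1
        assert recs[0].n_units == 3 and recs[0].size == 12

    def test_non_primitive_period_reexpressed(self):
        # AT x 7 is a dinucleotide run; it must never surface as ATATAT etc.
        seq = FLANK_A + "AT" * 7 + FLANK_B
        recs = scan_ssrs(seq)
        assert as_tuples(recs) == [("AT", 7, len(FLANK_A) + 1, len(FLANK_A) + 14)]

    def test_below_threshold_after_primitive_reduction(self):
        # (ATATAT)x1.5 = AT x 4.5 -> only 4 complete units, below 6: nothing
        seq = FLANK_A + "AT" * 4 + FLANK_B
        assert scan_ssrs(seq) == []

    def test_n_breaks_runs(self):
        seq = FLANK_A + "A" * 7 + "N" + "A" * 7 + FLANK_B
        assert scan_ssrs(seq) == []

    def test_invalid_characters_rejected_empty_ok(self):
        assert scan_ssrs("") == []
        with pytest.raises(ValueError):
            scan_ssrs("ACGTX")

    def test_matches_brute_force_oracle_random(self):
        rnd = random.Random(7)
        for _ in range(60):
            # AT-rich with planted repeats to exercise every period
            parts = []
            for _ in range(rnd.randint(3, 8)):
                parts.append("".join(rnd.choices("AATCG", k=rnd.randint(5, 40))))
                motif = "".join(rnd.choices("AT", k=rnd.randint(1, 6)))
                parts.append(motif * rnd.randint(2, 14))
            seq = "".join(parts)[:500]
            assert as_tuples(scan_ssrs(seq)) == oracle_scan(seq), seq

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=len(FLANK_A)),
           st.sampled_from(["TAT", "AAAT", "AT", "A", "AATCG", "ATTTAT"]))
    def test_shift_equivariance(self, k, motif):
        # "GC" spacer keeps the prepended bases from extending the run
        thr = DEFAULT_THRESHOLDS.min_units[len(motif)]
        body = "GC" + motif * (thr + 1)
        base = scan_ssrs(body + FLANK_B)
        shifted = scan_ssrs(FLANK_A[:k] + body + FLANK_B)
        assert [(r.motif, r.start - k, r.end - k) for r in shifted] == \
               [(r.motif, r.start, r.end) for r in base]


class TestThresholds:
    def test_default_values(self):
        assert DEFAULT_THRESHOLDS.min_units == {1: 12, 2: 6, 3: 4, 4: 3,
                                                5: 3, 6: 3}
        assert DEFAULT_THRESHOLDS.max_interruption == 0

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            SSRThresholds({1: 12})
        with pytest.raises(ValueError):
            SSRThresholds({1: 0, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3})


class TestCompound:
    def test_adjacent_repeats_merge(self):
        seq = FLANK_A + "AAT" * 4 + "TG" * 6 + FLANK_B
        merged = merge_compound(scan_ssrs(seq))
        assert len(merged) == 1
        c = merged[0]
        assert c.compound and len(c.components) == 2
        assert c.size == 12 + 12
        assert c.start == len(FLANK_A) + 1 and c.end == len(FLANK_A) + 24

    def test_one_bp_gap_stays_separate(self):
        seq = FLANK_A + "AAAT" * 3 + "C" + "TG" * 6 + FLANK_B
        merged = merge_compound(scan_ssrs(seq))
        assert len(merged) == 2 and not any(r.compound for r in merged)

    def test_single_record_identity(self):
        recs = scan_ssrs(FLANK_A + "TAT" * 6 + FLANK_B)
        assert merge_compound(recs) == recs


class TestLocations:
    def _genome(self):
        seq = "A" * 100
        return MitoGenome("x", seq, features=[
            Feature("nad4", "CDS", 11, 40, "-"),
            Feature("rrnL", "rRNA", 41, 60, "-"),
            Feature("control_region", "control_region", 81, 100, "+")])

    def test_gene_control_and_intergenic_classes(self):
        from mitocomp.ssr import SSRecord
        g = self._genome()
        recs = [SSRecord("AAAT", 3, 12, 15, 26),
                SSRecord("AT", 6, 12, 45, 56),
                SSRecord("TAT", 4, 12, 65, 76),
                SSRecord("A", 12, 12, 85, 96)]
        located = classify_locations(recs, g)
        assert [r.location for r in located] == \
            ["nad4", "rrnL", INTERGENIC_LABEL, CONTROL_REGION_LABEL]
        assert coding_fraction(located) == pytest.approx(0.5)


class TestStats:
    def test_relative_abundance_printed_case(self):
        """3 repeats in a 17,197-bp genome give RA = 0.17/kb."""
        from mitocomp.ssr import SSRecord
        recs = [SSRecord("AAAT", 3, 12, 100, 111),
                SSRecord("TAT", 6, 18, 200, 217),
                SSRecord("AATT", 3, 12, 300, 311)]
        st_ = ssr_stats(recs, 17197)
        assert st_.rounded()["RA"] == 0.17
        assert st_.rounded()["RD"] == 2.44  # 42 bp over 17.197 kb
        assert st_.at_only_fraction == 1.0

    def test_no_records(self):
        st_ = ssr_stats([], 15000)
        assert st_.ra == 0.0 and st_.rd == 0.0 and st_.gc_pct is None

    def test_class_percentages_sum_to_100(self):
        from mitocomp.ssr import SSRecord
        recs = [SSRecord("A", 12, 12, 1, 12), SSRecord("AT", 6, 12, 20, 31),
                SSRecord("TAT", 4, 12, 40, 51)]
        st_ = ssr_stats(recs, 1000)
        assert sum(st_.class_pct.values()) == pytest.approx(100.0)
        assert st_.class_counts[1] == st_.class_counts[2] == 1


class TestCrossSpecies:
    def test_degenerate_panel_has_no_correlation(self):
        from mitocomp.ssr import SSRecord
        rec = [SSRecord("TAT", 6, 18, 10, 27)]
        panel = [(("s%d" % i, 15000), list(rec)) for i in range(5)]
        cs = cross_species_summary(panel)
        assert cs.r2 is None and cs.p_value is None

    def test_fewer_than_three_genomes_skips_correlation(self):
        panel = [(("a", 15000), []), (("b", 16000), [])]
        assert cross_species_summary(panel).r2 is None

    def test_linear_panel_recovers_r2(self):
        """count = a·size + noise: r² matches a closed-form computation."""
        from mitocomp.ssr import SSRecord
        rnd = random.Random(5)
        sizes = [14000 + 300 * i for i in range(20)]
        counts = [max(0, round(0.004 * s - 50 + rnd.gauss(0, 2)))
                  for s in sizes]
        panel = []
        for i, (sz, ct) in enumerate(zip(sizes, counts)):
            recs = [SSRecord("TAT", 4, 12, 20 * j + 1, 20 * j + 12)
                    for j in range(ct)]
            panel.append((("sp%02d" % i, sz), recs))
        cs = cross_species_summary(panel)
        n = len(sizes)
        mx, my = sum(sizes) / n, sum(counts) / n
        sxy = sum((x - mx) * (y - my) for x, y in zip(sizes, counts))
        sxx = sum((x - mx) ** 2 for x in sizes)
        syy = sum((y - my) ** 2 for y in counts)
        assert cs.r2 == pytest.approx(sxy * sxy / (sxx * syy), abs=1e-9)
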