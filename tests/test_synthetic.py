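"""Generator ground truth: determinism, embedded repeats, composition."""

import pytest

from mitocomp import base_composition, scan_ssrs
from mitocomp.codon_usage import GeneticCode
from mitocomp.mito_io import coding_sequences
from mitocomp.ssr import classify_locations
from mitocomp.synthetic import (
    GenerationError, PanelModel, SSRInsert, SyntheticSpec, cds_motif_compatible,
    demo_genome_spec, generate_genome, generate_panel, mutate_cds_pair,
    random_orf,
)


class TestGenerateGenome:
    def test_same_seed_bit_identical(self):
        g1, t1 = generate_genome(SyntheticSpec(seed=5))
        g2, t2 = generate_genome(SyntheticSpec(seed=5))
        assert g1.sequence == g2.sequence
        assert t1 == t2
        g3, _ = generate_genome(SyntheticSpec(seed=6))
        assert g3.sequence != g1.sequence

    def test_structure_matches_layout(self):
        genome, truth = generate_genome(SyntheticSpec(seed=1))
        kinds = {}
        for f in genome.features:
            kinds[f.kind] = kinds.get(f.kind, 0) + 1
        assert kinds == {"CDS": 13, "tRNA": 22, "rRNA": 2, "control_region": 1}
        assert genome.length == 15500

    def test_cds_are_valid_orfs(self):
        genome, _ = generate_genome(SyntheticSpec(seed=2))
        gc = GeneticCode.get(5)
        for name, cds in coding_sequences(genome).items():
            assert cds[:3] in ("ATA", "ATT", "ATG", "TTG"), name
            assert cds[-3:] == "TAA", name
            internal = [cds[i:i + 3] for i in range(3, len(cds) - 3, 3)]
            assert not any(c in gc.stop_codons for c in internal), name

    def test_composition_within_one_percent(self):
        spec = SyntheticSpec(seed=3)
        genome, truth = generate_genome(spec)
        for b, target in spec.base_pct.items():
            realized = 100.0 * truth["base_counts"][b] / genome.length
            assert abs(realized - target) <= 1.0, b

    def test_scan_recovers_exactly_the_embedded_truth(self, demo_genome):
        genome, truth = demo_genome
        recs = classify_locations(scan_ssrs(genome.sequence), genome)
        got = [(r.motif, r.n_units, r.start, r.end, r.location) for r in recs]
        want = [(t["motif"], t["n_units"], t["start"], t["end"], t["location"])
                for t in truth["ssrs"]]
        assert got == want
        assert len(got) == 3

    def test_demo_composition_hits_target_skews(self, demo_genome):
        genome, _ = demo_genome
        bs = base_composition(genome.sequence)
        assert bs.at_skew == pytest.approx(0.149, abs=0.01)
        assert bs.gc_skew == pytest.approx(-0.154, abs=0.01)

    def test_infeasible_ssr_rejected(self):
        with pytest.raises(GenerationError):
            generate_genome(SyntheticSpec(
                seed=1, ssrs=(SSRInsert("AATCGG", 60, "trnI"),)))
        with pytest.raises(ValueError, match="primitive"):
            generate_genome(SyntheticSpec(seed=1, ssrs=(SSRInsert("ATAT", 3,
                                                                  "nad2"),)))
        with pytest.raises(ValueError, match="threshold"):
            generate_genome(SyntheticSpec(seed=1, ssrs=(SSRInsert("TAT", 2,
                                                                  "nad2"),)))

    def test_bad_base_pct_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SyntheticSpec(base_pct={"A": 50.0, "C": 10.0, "G": 10.0, "T": 10.0})


class TestMotifCompatibility:
    def test_taaa_needs_minus_strand_host(self):
        assert not cds_motif_compatible("TAAA", "+")
        assert cds_motif_compatible("TAAA", "-")

    def test_tat_fits_either_strand(self):
        assert cds_motif_compatible("TAT", "+")
        assert cds_motif_compatible("TAT", "-")


class TestMutateCdsPair:
    def test_zero_changes_identical(self):
        orf = random_orf(300, seed=1)
        a, b, truth = mutate_cds_pair(orf, 0, 0, seed=2)
        assert a == b == orf and truth == []

    def test_exact_counts_and_classification(self):
        orf = random_orf(600, seed=1)
        gc = GeneticCode.get(5)
        a, b, truth = mutate_cds_pair(orf, 7, 4, seed=3)
        diffs = [i for i in range(len(a)) if a[i] != b[i]]
        assert len(diffs) == 11
        assert sum(1 for t in truth if t["kind"] == "syn") == 7
        by_codon = {}
        for i in diffs:
            by_codon.setdefault(i // 3, []).append(i)
        assert all(len(v) == 1 for v in by_codon.values())  # one per codon
        for t in truth:
            ca = a[3 * t["codon_index"]:3 * t["codon_index"] + 3]
            cb = b[3 * t["codon_index"]:3 * t["codon_index"] + 3]
            same = gc.aa[ca] == gc.aa[cb]
            assert same == (t["kind"] == "syn")
            assert cb not in gc.stop_codons

    def test_infeasible_request_errors(self):
        with pytest.raises(ValueError, match="codons admit"):
            mutate_cds_pair("ATGAAATAA", 5, 0, seed=1)

    def test_start_and_stop_untouched(self):
        orf = random_orf(300, seed=4)
        _, b, _ = mutate_cds_pair(orf, 10, 10, seed=5)
        assert b[:3] == orf[:3] and b[-3:] == orf[-3:]


class TestPanel:
    def test_panel_reproducible_and_truth_joins(self):
        genomes, truths = generate_panel(6, seed=7)
        genomes2, _ = generate_panel(6, seed=7)
        assert [g.sequence for g in genomes] == [g.sequence for g in genomes2]
        for g, t in zip(genomes, truths):
            found = {(r.motif, r.n_units, r.start, r.end)
                     for r in scan_ssrs(g.sequence)}
            want = {(s["motif"], s["n_units"], s["start"], s["end"])
                    for s in t["ssrs"]}
            assert found == want  # 1:1 join against the truth record

    def test_flat_model_gives_near_zero_r2(self):
        from mitocomp import cross_species_summary
        model = PanelModel(slope=0.0, intercept=8.0, noise_sd=2.0)
        genomes, truths = generate_panel(20, model=model, seed=11)
        panel = [(g, scan_ssrs(g.sequence)) for g in genomes]
        cs = cross_species_summary(panel)
        assert cs.r2 is not None and cs.r2 < 0.25

    def test_study_scale_panel_summaries_match_construction(self):
        """A 56-genome panel reproduces its construction: r² equals the
        closed-form Pearson on the truth records, ~70% of repeats fall in
        genes, and motifs are overwhelmingly A/T-only."""
        from mitocomp import cross_species_summary
        from mitocomp.ssr import classify_locations
        genomes, truths = generate_panel(56, seed=13)
        panel = [(g, classify_locations(scan_ssrs(g.sequence), g))
                 for g in genomes]
        cs = cross_species_summary(panel)
        sizes = [t["length"] for t in truths]
        counts = [len(t["ssrs"]) for t in truths]
        n = len(sizes)
        mx, my = sum(sizes) / n, sum(counts) / n
        sxy = sum((x - mx) * (y - my) for x, y in zip(sizes, counts))
        sxx = sum((x - mx) ** 2 for x in sizes)
        syy = sum((y - my) ** 2 for y in counts)
        assert cs.r2 == pytest.approx(sxy * sxy / (sxx * syy), abs=0.05)
        assert cs.coding_fraction == pytest.approx(0.70, abs=0.08)
        assert cs.at_only_fraction > 0.95
        assert cs.pooled_class_pct[4] == pytest.approx(43.1, abs=8.0)
        assert cs.pooled_class_pct[3] == pytest.approx(40.4, abs=8.0)

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            generate_panel(2, seed=1)
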