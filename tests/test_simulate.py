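import numpy as np
import pytest
from scipy.stats import chisquare

from maexp.errors import DegenerateExperimentError, InvalidSpecError
from maexp.genome import translate_codon
from maexp.ingest import apply_consensus_filter, apply_site_filters, read_callsets
from maexp.rates import site_generations
from maexp.simulate import (
    DEFAULT_SPECTRUM_WEIGHTS,
    ExperimentConfig,
    GenomeSpec,
    generate_genome,
    simulate_ma_experiment,
    write_fixtures,
)
from maexp.spectrum import SubstitutionClass, classify_substitution
from maexp.ssr import find_ssrs, ssr_genome_fraction


class TestGenerateGenome:
    def test_study_composition_recovered(self, small_genome):
        assert small_genome.gc_fraction == pytest.approx(0.605, abs=0.01)
        assert small_genome.coding_fraction == pytest.approx(0.883, abs=0.01)

    def test_noncoding_genome(self):
        g = generate_genome(GenomeSpec(length=20_000, gc_content=0.5, coding_fraction=0.0, seed=4))
        assert g.cds == [] and g.coding_fraction == 0.0
        assert g.gc_fraction == pytest.approx(0.5, abs=0.02)

    def test_same_seed_identical_output(self):
        spec = GenomeSpec(length=30_000, seed=9)
        g1, g2 = generate_genome(spec), generate_genome(spec)
        assert g1.seq == g2.seq and g1.cds == g2.cds

    def test_cds_are_translatable_orfs(self, small_genome):
        for cds in small_genome.cds:
            s = small_genome.coding_sequence(cds)
            assert len(s) % 3 == 0
            assert s.startswith("ATG")
            aas = [translate_codon(s[i : i + 3]) for i in range(0, len(s), 3)]
            assert "*" not in aas[:-1]
            assert aas[-1] == "*"

    def test_cds_non_overlapping(self, small_genome):
        prev_end = 0
        for cds in small_genome.cds:
            assert cds.start >= prev_end
            prev_end = cds.end

    def test_planted_ssrs_detected_at_default_thresholds(self, small_genome):
        found = find_ssrs(small_genome)
        starts = np.array([s.start for s in found])
        ends = np.array([s.end for s in found])
        for p_start, p_end, _motif in small_genome.planted_ssrs:
            assert np.any((starts < p_end) & (ends > p_start))

    def test_ssr_coverage_near_target(self, small_genome):
        frac = ssr_genome_fraction(find_ssrs(small_genome), small_genome.length)
        assert 0.008 <= frac <= 0.02  # target 0.98% plus incidental repeats

    def test_infeasible_spec_rejected(self):
        with pytest.raises(InvalidSpecError):
            GenomeSpec(length=0)
        with pytest.raises(InvalidSpecError):
            GenomeSpec(gc_content=1.5)
        with pytest.raises(InvalidSpecError):
            GenomeSpec(ssr_target_fraction=0.9)


class TestSimulateExperiment:
    def test_zero_rates_give_empty_truth(self, small_genome):
        truth, lines = simulate_ma_experiment(
            small_genome, ExperimentConfig(n_lines=3, sub_rate=0.0, indel_rate=0.0, seed=1)
        )
        assert all(len(v) == 0 for v in truth.values())
        assert len(lines) == 3

    def test_line_metadata_carries_exposure(self, small_genome):
        cfg = ExperimentConfig(n_lines=2, transfers_per_line=100, generations_per_transfer=20.0, seed=1)
        _, lines = simulate_ma_experiment(small_genome, cfg)
        assert all(l.generations == 2000.0 for l in lines)
        assert all(l.callable_sites == small_genome.length for l in lines)

    def test_truth_alleles_match_genome(self, small_genome):
        cfg = ExperimentConfig(n_lines=3, sub_rate=3e-8, indel_rate=1e-8, seed=12)
        truth, _ = simulate_ma_experiment(small_genome, cfg)
        for muts in truth.values():
            positions = [m.position for m in muts]
            assert len(set(positions)) == len(positions)
            for m in muts:
                assert small_genome.seq[m.position : m.position + len(m.ref)] == m.ref

    def test_determinism(self, small_genome):
        cfg = ExperimentConfig(n_lines=3, sub_rate=3e-8, indel_rate=1e-8, seed=12)
        t1, l1 = simulate_ma_experiment(small_genome, cfg)
        t2, l2 = simulate_ma_experiment(small_genome, cfg)
        assert t1 == t2 and l1 == l2

    def test_degenerate_experiment_rejected(self):
        from maexp.genome import AnnotatedGenome

        with pytest.raises(DegenerateExperimentError):
            simulate_ma_experiment(AnnotatedGenome(""), ExperimentConfig(n_lines=1))

    def test_poisson_mean_matches_closed_form(self, study_genome):
        """Mean total substitution count over 200 replicates agrees with
        rate x sum(N_i T_i) at study scale (69 lines, 3.5 Mb, ~2900 gen)."""
        counts = []
        for rep in range(200):
            cfg = ExperimentConfig(sub_rate=1.22e-10, indel_rate=0.0, seed=3000 + rep)
            truth, lines = simulate_ma_experiment(study_genome, cfg)
            counts.append(sum(len(v) for v in truth.values()))
        counts = np.array(counts)
        expected = 1.22e-10 * site_generations(lines)
        assert expected == pytest.approx(87, abs=2)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_spectrum_class_frequencies_recover_weights(self, small_genome):
        observed = {cls: 0 for cls in SubstitutionClass}
        for seed in range(8, 13):
            cfg = ExperimentConfig(n_lines=5, sub_rate=1.2e-6, indel_rate=0.0, seed=seed)
            truth, _ = simulate_ma_experiment(small_genome, cfg)
            for muts in truth.values():
                for m in muts:
                    observed[classify_substitution(m.ref, m.alt)] += 1
        total = sum(observed.values())
        assert total > 10_000
        w = np.array([DEFAULT_SPECTRUM_WEIGHTS[c] for c in SubstitutionClass], dtype=float)
        f_exp = total * w / w.sum()
        stat, p = chisquare([observed[c] for c in SubstitutionClass], f_exp=f_exp)
        assert p > 0.01

    def test_no_hotspot_means_ssr_overlap_at_genome_fraction(self, small_genome):
        cfg = ExperimentConfig(
            n_lines=4, sub_rate=0.0, indel_rate=1.2e-7, ssr_hotspot_multiplier=1.0, seed=21
        )
        truth, _ = simulate_ma_experiment(small_genome, cfg)
        flags = [m.inside_ssr for v in truth.values() for m in v]
        n = len(flags)
        p = ssr_genome_fraction(find_ssrs(small_genome), small_genome.length)
        sd = np.sqrt(n * p * (1 - p))
        assert abs(sum(flags) - n * p) < 4 * sd

    def test_hotspot_multiplier_recovered_from_rate_ratio(self, small_genome):
        k = 20.0
        cfg = ExperimentConfig(
            n_lines=4, sub_rate=0.0, indel_rate=2.5e-7, ssr_hotspot_multiplier=k, seed=22
        )
        truth, _ = simulate_ma_experiment(small_genome, cfg)
        flags = [m.inside_ssr for v in truth.values() for m in v]
        n_in = sum(flags)
        n_out = len(flags) - n_in
        S = ssr_genome_fraction(find_ssrs(small_genome), small_genome.length) * small_genome.length
        L = small_genome.length
        ratio = (n_in / S) / (n_out / (L - S))
        assert ratio == pytest.approx(k, rel=0.30)


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory, small_genome):
    cfg = ExperimentConfig(n_lines=5, sub_rate=2e-8, indel_rate=1e-8, seed=33)
    truth, lines = simulate_ma_experiment(small_genome, cfg)
    out = tmp_path_factory.mktemp("fixtures")
    paths = write_fixtures(small_genome, truth, lines, out)
    return truth, lines, paths


class TestWriteFixtures:
    def test_file_cardinality(self, fixture_dir):
        truth, lines, paths = fixture_dir
        vcfs = [paths[l.line_id] for l in lines]
        assert len(vcfs) == 5
        assert all(p.exists() for p in vcfs)
        assert paths["fasta"].exists() and paths["gff"].exists() and paths["metadata"].exists()

    def test_round_trip_recovers_truth_exactly(self, fixture_dir):
        truth, lines, paths = fixture_dir
        calls, meta = read_callsets([paths[l.line_id] for l in lines], paths["metadata"])
        calls = apply_consensus_filter(apply_site_filters(calls))
        got = {(c.line_id, c.position, c.ref, c.alt) for c in calls}
        want = {m.key for v in truth.values() for m in v}
        assert got == want
        assert len(meta) == len(lines)

    def test_deletion_uses_left_anchored_convention(self, fixture_dir):
        truth, lines, paths = fixture_dir
        dels = [m for v in truth.values() for m in v if m.mclass == "deletion"]
        assert dels, "fixture should contain deletions"
        for m in dels:
            # a k-bp deletion is REF of length k+1 vs the 1-base padding ALT
            assert m.ref[0] == m.alt[0] and len(m.ref) > len(m.alt) == 1

    def test_genome_round_trips_through_fasta_gff(self, fixture_dir, small_genome):
        from maexp.genome import read_genome

        _, _, paths = fixture_dir
        g = read_genome(paths["fasta"], paths["gff"])
        assert g.seq == small_genome.seq
        assert [(c.start, c.end, c.strand) for c in g.cds] == [
            (c.start, c.end, c.strand) for c in small_genome.cds
        ]
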