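"""Generator behaviour: determinism, pool logic, library weights, decay."""

import math
from dataclasses import replace

import numpy as np
import pytest

from tddseq.constants import ISOFORM_CATEGORIES, RRNA_2S
from tddseq.simulate import (
    DecaySimParams,
    SampleDesign,
    SimConfig,
    build_ground_truth,
    expected_isoform_weights,
    expected_pool_abundance,
    graded_loading_truth,
    simulate_counts,
    simulate_decay_course,
    simulate_fastq,
)

from conftest import make_designs


class TestGroundTruth:
    def test_seed_determinism(self):
        cfg = SimConfig(seed=1, n_mirna=10, n_sirna=5)
        a, b = build_ground_truth(cfg), build_ground_truth(cfg)
        assert [s.name for s in a] == [s.name for s in b]
        assert [s.sequence for s in a] == [s.sequence for s in b]
        for sa, sb in zip(a, b):
            for key in sa.isoform_probs:
                np.testing.assert_array_equal(sa.isoform_probs[key],
                                              sb.isoform_probs[key])

    def test_no_sirnas_when_disabled(self):
        truth = build_ground_truth(SimConfig(seed=2, n_mirna=6, n_sirna=0))
        assert all(s.rna_class == "miRNA" for s in truth)

    def test_unique_prefixes_by_default(self, small_truth):
        prefixes = [s.sequence[:19] for s in small_truth]
        assert len(prefixes) == len(set(prefixes))

    def test_forced_collision_creates_exactly_one_pair(self):
        truth = build_ground_truth(SimConfig(seed=3, n_mirna=8, n_sirna=4,
                                             force_prefix_collision=True))
        # brute-force scan of every prefix pair
        collisions = [(a.name, b.name)
                      for i, a in enumerate(truth) for b in truth[i + 1:]
                      if a.sequence[:19] == b.sequence[:19]]
        assert len(collisions) == 1

    def test_designated_subsets_present(self, small_truth):
        tags = {t for s in small_truth for t in s.tags}
        assert {"ago1_cohort", "ago2_enriched", "dora_sensitive"} <= tags
        sensitive = [s for s in small_truth if "dora_sensitive" in s.tags]
        assert all(s.dora_fold > 1 for s in sensitive)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            build_ground_truth(SimConfig(seed=1, n_mirna=1, n_sirna=0))
        with pytest.raises(ValueError):
            SimConfig(seed=1, n_mirna=-1)


class TestPoolAbundance:
    def test_hand_computed_dora_fold(self, small_truth):
        spec = replace(small_truth[0], baseline_abundance=100.0,
                       ago1_fraction=0.2, ago2_fraction=0.8, dora_fold=3.0)
        assert expected_pool_abundance(spec, "dora", "ago1") == pytest.approx(60.0)
        assert expected_pool_abundance(spec, "WT", "ago1") == pytest.approx(20.0)

    def test_ago2_pool_never_responds_to_dora(self, small_truth):
        for spec in small_truth:
            assert (expected_pool_abundance(spec, "WT", "ago2")
                    == expected_pool_abundance(spec, "dora", "ago2"))

    def test_fold_one_is_identity(self, small_truth):
        spec = replace(small_truth[0], dora_fold=1.0)
        for g in ("WT", "dora"):
            assert expected_pool_abundance(spec, g, "ago1") == pytest.approx(
                spec.baseline_abundance * spec.ago1_fraction)

    def test_unknown_genotype_errors(self, small_truth):
        with pytest.raises(ValueError):
            expected_pool_abundance(small_truth[0], "zswim8", "ago1")


class TestSimulateCounts:
    def test_periodate_zero_for_ago1_only_species(self, small_truth):
        cfg = SimConfig(seed=5, periodate_leak=0.0, methylation_rate_ago2=1.0)
        truth = [replace(small_truth[0], ago1_fraction=1.0, ago2_fraction=0.0),
                 small_truth[1]]
        designs = make_designs(["WT"], ["periodate"], depth=50_000)
        table = simulate_counts(truth, designs, cfg)
        assert table.counts.loc[truth[0].name].to_numpy().sum() == 0

    def test_no_contamination_keeps_ip_pure(self, small_truth):
        cfg = SimConfig(seed=5, ip_contamination=0.0)
        truth = [replace(small_truth[0], ago1_fraction=0.0, ago2_fraction=1.0),
                 small_truth[1]]
        designs = make_designs(["WT"], ["ago1_ip"], depth=50_000)
        table = simulate_counts(truth, designs, cfg)
        assert table.counts.loc[truth[0].name].to_numpy().sum() == 0

    def test_expected_weights_match_hand_mixture(self, small_truth):
        # independent evaluation of the capture-mixture formula
        cfg = SimConfig(seed=5, periodate_leak=0.07, overdispersion=0.0)
        spec = small_truth[0]
        design = SampleDesign("hen1", "periodate", "hen1_c1", depth=1000)
        weights = expected_isoform_weights([spec], design, cfg)
        # hen1 genotype: Ago2 pool unmethylated, everything survives at leak
        a1 = spec.baseline_abundance * spec.ago1_fraction * 0.07
        a2 = (spec.baseline_abundance * spec.ago2_fraction * spec.hen1_destab
              * 0.07)
        expected = (a1 * spec.isoform_probs[("ago1", "hen1")]
                    + a2 * spec.isoform_probs[("ago2", "hen1")])
        np.testing.assert_allclose(weights.to_numpy(), expected, rtol=1e-12)

    def test_multinomial_mode_conserves_depth(self, small_truth, small_config):
        designs = make_designs(["WT"], ["total"], depth=12_345, efficiency=1.0)
        table = simulate_counts(small_truth, designs, small_config,
                                mode="multinomial")
        assert (table.counts.sum(axis=0) == 12_345).all()

    def test_count_determinism(self, small_truth, small_config):
        designs = make_designs(["WT"], ["total"], depth=5_000)
        a = simulate_counts(small_truth, designs, small_config)
        b = simulate_counts(small_truth, designs, small_config)
        assert a.counts.equals(b.counts)

    @pytest.mark.parametrize("leak_pair", [(0.0, 0.05), (0.05, 0.2), (0.2, 1.0)])
    def test_periodate_weights_monotone_in_leak(self, small_truth, leak_pair):
        lo, hi = leak_pair
        design = SampleDesign("WT", "periodate", "WT_c1", depth=1000)
        w_lo = expected_isoform_weights(
            small_truth, design, SimConfig(seed=5, periodate_leak=lo))
        w_hi = expected_isoform_weights(
            small_truth, design, SimConfig(seed=5, periodate_leak=hi))
        assert (w_hi.to_numpy() >= w_lo.to_numpy() - 1e-12).all()

    def test_periodate_total_ratio_monotone_in_ago2_fraction(self):
        truth = graded_loading_truth(20, seed=9)
        cfg = SimConfig(seed=9, periodate_leak=0.05, overdispersion=0.0)
        total = expected_isoform_weights(
            truth, SampleDesign("WT", "total", "WT_c1"), cfg)
        peri = expected_isoform_weights(
            truth, SampleDesign("WT", "periodate", "WT_c1"), cfg)
        ratio = (peri.groupby(level=0).sum()
                 / total.groupby(level=0).sum())
        ordered = ratio.reindex([s.name for s in truth]).to_numpy()
        assert (np.diff(ordered) > -1e-12).all()

    def test_empty_inputs_error(self, small_truth, small_config):
        with pytest.raises(ValueError):
            simulate_counts([], make_designs(["WT"], ["total"]), small_config)
        with pytest.raises(ValueError):
            simulate_counts(small_truth, [], small_config)


class TestSimulateFastq:
    def test_contaminant_reads_injected_exactly(self, small_truth, small_config,
                                                tmp_path):
        designs = make_designs(["WT"], ["total"], n_clones=1, depth=500)
        counts = simulate_counts(small_truth, designs, small_config)
        sequences = {s.name: s.dna_sequence for s in small_truth}
        paths = simulate_fastq(counts, sequences, small_config, tmp_path,
                               n_contaminant_reads=100)
        text = next(iter(paths.values())).read_text().splitlines()
        seqs = text[1::4]
        n_2s = sum(RRNA_2S in s for s in seqs)
        assert n_2s == 100
        assert len(seqs) == int(counts.counts.sum().iloc[0]) + 100

    def test_read_layout(self, small_truth, small_config, tmp_path):
        designs = make_designs(["WT"], ["total"], n_clones=1, depth=200)
        counts = simulate_counts(small_truth, designs, small_config)
        sequences = {s.name: s.dna_sequence for s in small_truth}
        paths = simulate_fastq(counts, sequences, small_config, tmp_path,
                               adapter3="TGGAATTCTC")
        lines = next(iter(paths.values())).read_text().splitlines()
        for seq, qual in zip(lines[1::4], lines[3::4]):
            assert seq.endswith("TGGAATTCTC")
            assert len(seq) == len(qual)


class TestDecaySimulation:
    def test_half_life_identity_noiseless(self):
        params = DecaySimParams(rate_k=math.log(2) / 24, amplitude_A=1.0,
                                baseline_B=0.0, times_h=(24.0,), noise_sigma=0.0)
        course = simulate_decay_course(params)
        assert course.ratios[0] == pytest.approx(0.5, rel=1e-12)

    def test_time_zero_is_amplitude_plus_baseline(self):
        params = DecaySimParams(rate_k=0.1, amplitude_A=2.0, baseline_B=0.25,
                                times_h=(0.0, 1.0), noise_sigma=0.0)
        course = simulate_decay_course(params)
        assert course.ratios[0] == pytest.approx(2.25)

    def test_seeded_repeatability(self):
        params = DecaySimParams(rate_k=0.05, amplitude_A=1.0, baseline_B=0.1,
                                noise_sigma=0.2, seed=42)
        a, b = simulate_decay_course(params), simulate_decay_course(params)
        np.testing.assert_array_equal(a.ratios, b.ratios)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DecaySimParams(rate_k=-1.0, amplitude_A=1.0)
        with pytest.raises(ValueError):
            DecaySimParams(rate_k=0.1, amplitude_A=1.0, times_h=(2.0, 1.0))
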