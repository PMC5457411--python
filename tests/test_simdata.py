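"""Simulator unit and property tests: branching process, errors, sequencing."""

import math

import numpy as np
import pytest

from umifid import simdata as sd
from umifid.simdata import (
    ConfigError,
    ExperimentConfig,
    PolymeraseModel,
    TruthRecord,
    UNIFORM_SPECTRUM,
    amplification_fold,
    bottleneck_survivors,
    run_experiment,
    sample_lineage,
    simulate_dilution,
    simulate_first_pcr,
    simulate_linear_amplification,
    simulate_pcr_population,
    simulate_sequencing,
)

from conftest import make_spectrum


class TestAmplificationFold:
    def test_twenty_cycles_at_published_efficiency(self):
        # 1.8^20 ~ 1.27e5, i.e. ~1.3e5-fold amplification
        fold = amplification_fold(1.8, 20)
        assert fold == pytest.approx(1.27482e5, rel=1e-4)
        assert round(fold / 1e5, 1) == 1.3

    @pytest.mark.parametrize(
        "efficiency,cycles,expected", [(2.0, 0, 1.0), (2.0, 10, 1024.0), (1.0, 50, 1.0)]
    )
    def test_degenerate_cases(self, efficiency, cycles, expected):
        assert amplification_fold(efficiency, cycles) == expected

    @pytest.mark.parametrize("efficiency", [0.9, 2.1, -1.0])
    def test_out_of_range_efficiency_rejected(self, efficiency):
        with pytest.raises(ConfigError):
            amplification_fold(efficiency, 5)


class TestPolymeraseModel:
    def test_spectrum_must_normalize(self):
        with pytest.raises(ConfigError):
            PolymeraseModel("bad", 1e-4, np.full(12, 0.1))

    def test_rate_bounds(self):
        with pytest.raises(ConfigError):
            PolymeraseModel("bad", 0.5, UNIFORM_SPECTRUM)

    def test_efficiency_bounds(self):
        with pytest.raises(ConfigError):
            PolymeraseModel("bad", 1e-4, UNIFORM_SPECTRUM, efficiency=2.5)


class TestLinearAmplification:
    def test_zero_rate_yields_template_copies(self, template, rng):
        config = ExperimentConfig(la_error_rate=0.0, n_templates=50)
        pol = PolymeraseModel("p", 1e-4, UNIFORM_SPECTRUM)
        mols = simulate_linear_amplification(config, pol, 50, rng)
        assert len(mols) == 50
        assert all(m.molecule_sequence == template for m in mols)
        assert all(m.la_errors == [] for m in mols)
        assert len({m.umi for m in mols}) == 50  # fresh random UMIs

    def test_error_count_matches_binomial_mean(self, template, rng):
        # closed-form Binomial(L, rate) mean vs simulation, 3 SE band
        n, rate = 100_000, 1e-4
        config = ExperimentConfig(la_error_rate=rate, n_templates=n)
        pol = PolymeraseModel("p", rate, UNIFORM_SPECTRUM)
        mols = simulate_linear_amplification(config, pol, n, rng)
        counts = np.array([len(m.la_errors) for m in mols])
        expected = len(template) * rate  # 0.015
        se = math.sqrt(expected / n)
        assert abs(counts.mean() - expected) < 3 * se

    def test_degenerate_spectrum_only_mutates_c_to_a(self, rng):
        config = ExperimentConfig(la_error_rate=5e-3, n_templates=2000)
        pol = PolymeraseModel("ca", 5e-3, make_spectrum(**{"C>A": 1.0}))
        mols = simulate_linear_amplification(config, pol, 2000, rng)
        errors = [e for m in mols for e in m.la_errors]
        assert len(errors) > 100
        assert all(ref == "C" and alt == "A" for _pos, ref, alt in errors)
        for m in mols:
            for pos, ref, _alt in m.la_errors:
                assert config.template[pos - 1] == ref

    def test_truth_sequence_differs_exactly_at_error_positions(self, template, rng):
        config = ExperimentConfig(la_error_rate=2e-3, n_templates=3000)
        pol = PolymeraseModel("p", 2e-3, UNIFORM_SPECTRUM)
        mols = simulate_linear_amplification(config, pol, 3000, rng)
        for m in mols:
            diff = {
                i + 1 for i, (a, b) in enumerate(zip(template, m.molecule_sequence))
                if a != b
            }
            assert diff == m.error_positions()


class TestPcrPopulation:
    def test_perfect_doubling_is_deterministic(self, template, rng):
        pol = PolymeraseModel("p", 0.0, UNIFORM_SPECTRUM, efficiency=2.0)
        founder = TruthRecord("A" * 14, template)
        pop = simulate_pcr_population(founder, pol, 3, rng)
        assert len(pop) == 8
        assert all(m.molecule_sequence == template for m in pop)

    def test_population_guard_directs_to_lineage_sampling(self, template, rng):
        pol = PolymeraseModel("p", 0.0, UNIFORM_SPECTRUM, efficiency=2.0)
        founder = TruthRecord("A" * 14, template)
        with pytest.raises(ConfigError, match="sample_lineage"):
            simulate_pcr_population(founder, pol, 30, rng)

    def test_mean_population_matches_branching_expectation(self, template, rng):
        # E[N] = efficiency^cycles for a Galton-Watson process
        pol = PolymeraseModel("p", 0.0, UNIFORM_SPECTRUM, efficiency=1.8)
        founder = TruthRecord("A" * 14, template)
        reps = 1000
        sizes = np.array(
            [len(simulate_pcr_population(founder, pol, 10, rng)) for _ in range(reps)]
        )
        expected = 1.8 ** 10
        assert abs(sizes.mean() - expected) < 3 * sizes.std(ddof=1) / math.sqrt(reps)

    def test_zero_rate_descendants_identical_to_founder(self, template, rng):
        pol = PolymeraseModel("p", 0.0, UNIFORM_SPECTRUM, efficiency=1.9)
        founder = TruthRecord("A" * 14, template)
        pop = simulate_pcr_population(founder, pol, 6, rng)
        assert all(m.molecule_sequence == founder.molecule_sequence for m in pop)
        assert all(m.pcr1_errors == [] for m in pop)


class TestSampleLineage:
    def test_no_amplification_means_no_synthesis(self, template, rng):
        pol = PolymeraseModel("p", 1e-3, UNIFORM_SPECTRUM, efficiency=1.0)
        founder = TruthRecord("A" * 14, template)
        out = sample_lineage(founder, pol, 10, rng)
        assert out.lineage_depth == 0
        assert out.molecule_sequence == template

    def test_mean_depth_matches_enumerated_tree(self, template, rng):
        # Perfect doubling over 3 cycles yields 8 lineages with depths
        # {0,1,1,1,2,2,2,3}: mean 1.5.
        pol = PolymeraseModel("p", 0.0, UNIFORM_SPECTRUM, efficiency=2.0)
        founder = TruthRecord("A" * 14, template)
        depths = np.array(
            [sample_lineage(founder, pol, 3, rng).lineage_depth for _ in range(4000)]
        )
        # depth ~ Binomial(3, 1/2): mean 1.5, sd sqrt(3)/2
        se = math.sqrt(3) / 2 / math.sqrt(len(depths))
        assert abs(depths.mean() - 1.5) < 3 * se

    def test_depth_zero_with_error_rate_keeps_sequence(self, template, rng):
        pol = PolymeraseModel("p", 5e-3, UNIFORM_SPECTRUM, efficiency=1.0)
        founder = TruthRecord("A" * 14, template)
        out = sample_lineage(founder, pol, 20, rng)
        assert out.molecule_sequence == template and out.pcr1_errors == []


class TestDilution:
    def test_at_most_one_molecule_per_umi(self, template, rng):
        pop = {"AAAA": [TruthRecord("AAAA", template) for _ in range(50)]}
        out = simulate_dilution(pop, 0.9, rng)
        assert list(out) == ["AAAA"]
        assert isinstance(out["AAAA"], TruthRecord)

    def test_single_molecule_survival_is_bernoulli(self, template, rng):
        hits = 0
        reps = 2000
        for _ in range(reps):
            pop = {"AAAA": [TruthRecord("AAAA", template)]}
            hits += "AAAA" in simulate_dilution(pop, 0.5, rng)
        se = math.sqrt(0.25 / reps)
        assert abs(hits / reps - 0.5) < 4 * se

    def test_empty_population(self, rng):
        assert simulate_dilution({}, 0.5, rng) == {}

    def test_lineage_bottleneck_survival_probability(self, template, rng):
        # survival = 1-(1-f)^N for a UMI whose first PCR made N molecules
        mols = [TruthRecord(f"U{i:05d}", template) for i in range(4000)]
        sizes = np.full(4000, 100)
        out = bottleneck_survivors(mols, sizes, 0.01, rng)
        expected = -math.expm1(100 * math.log1p(-0.01))  # ~0.634
        se = math.sqrt(expected * (1 - expected) / 4000)
        assert abs(len(out) / 4000 - expected) < 4 * se


class TestSequencing:
    def test_infinite_quality_reads_equal_molecules(self, template, rng):
        config = ExperimentConfig(
            phred_quality=math.inf, n_templates=20,
            reads_per_umi_distribution={"kind": "constant", "value": 3},
        )
        mols = [TruthRecord(f"ACGTACGTACGTA{b}", template) for b in "ACGT"]
        result = simulate_sequencing(mols, config, rng)
        assert len(result.reads) == 12
        for read in result.reads:
            mol = mols[read.molecule_index]
            assert read.sequence == mol.umi + mol.molecule_sequence

    def test_phred30_mismatch_rate_close_to_1e3(self, template, rng):
        config = ExperimentConfig(
            phred_quality=30.0, n_templates=100,
            reads_per_umi_distribution={"kind": "constant", "value": 20},
        )
        mols = [TruthRecord("A" * 14, template) for _ in range(100)]
        result = simulate_sequencing(mols, config, rng)
        mm = total = 0
        for read in result.reads:
            insert = read.sequence[14:]
            mm += sum(a != b for a, b in zip(insert, template))
            total += len(insert)
        rate = mm / total
        se = math.sqrt(1e-3 / total)
        assert abs(rate - 1e-3) < 4 * se

    def test_zero_molecules_gives_valid_empty_fastq(self, tmp_path, rng):
        config = ExperimentConfig(n_templates=10)
        out = tmp_path / "empty.fastq"
        result = simulate_sequencing([], config, rng, fastq_path=out)
        assert result.reads == []
        assert out.read_text() == ""

    def test_quality_string_matches_configured_score(self, template, rng):
        config = ExperimentConfig(
            phred_quality=30.0, n_templates=5,
            reads_per_umi_distribution={"kind": "constant", "value": 2},
        )
        mols = [TruthRecord("C" * 14, template)]
        result = simulate_sequencing(mols, config, rng)
        assert set(result.reads[0].quality) == {chr(30 + 33)}


class TestEndToEnd:
    def test_seed_determinism_byte_identical_outputs(self, tmp_path):
        from umifid import io as uio
        from umifid.published import polymerase_presets

        pol = polymerase_presets()["Encyclo"]
        outputs = []
        for tag in ("a", "b"):
            config = ExperimentConfig(n_templates=200, dilution_fraction=1e-4, seed=42)
            run = run_experiment(config, pol)
            fastq = tmp_path / f"{tag}.fastq"
            truth = tmp_path / f"{tag}.tsv"
            uio.write_fastq(fastq, run.reads)
            uio.write_truth_table(truth, run.sequenced, config)
            outputs.append((fastq.read_bytes(), truth.read_bytes()))
        assert outputs[0] == outputs[1]

    def test_zero_rate_purity_all_reads_equal_template(self, template):
        # every stage error-free and Q -> inf => reads are UMI + template
        config = ExperimentConfig(
            la_error_rate=0.0, phred_quality=math.inf,
            n_templates=100, dilution_fraction=1e-3,
        )
        pol = PolymeraseModel("pure", 0.0, UNIFORM_SPECTRUM)
        run = run_experiment(config, pol)
        assert len(run.reads) > 0
        assert all(r.sequence[14:] == template for r in run.reads)

    def test_non_bottlenecked_reads_vary_within_umi(self, template):
        # without the bottleneck, reads of one UMI come from different
        # first-PCR lineages, so per-read PCR errors differ within a group
        config = ExperimentConfig(
            la_error_rate=0.0, phred_quality=math.inf, bottlenecked=False,
            n_templates=60, seed=3,
            reads_per_umi_distribution={"kind": "constant", "value": 10},
        )
        pol = PolymeraseModel("hot", 2e-3, UNIFORM_SPECTRUM, efficiency=1.8)
        run = run_experiment(config, pol)
        by_umi = {}
        for read in run.reads:
            by_umi.setdefault(read.sequence[:14], set()).add(read.sequence[14:])
        assert any(len(variants) > 1 for variants in by_umi.values())
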