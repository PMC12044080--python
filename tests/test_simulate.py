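"""Generator: marker maps, F2 mosaics, low-coverage counts, phenotypes."""

import numpy as np
import pytest

import heartqtl as hq
from heartqtl.errors import InvalidSpecError
from heartqtl.simulate import (
    QTL,
    GenomeSpec,
    allele_a_probability,
    simulate_allele_counts,
    simulate_f2_cohort,
    simulate_marker_map,
    simulate_phenotypes,
)


def spec_1mb(**kw) -> GenomeSpec:
    base = dict(
        chromosomes=(("chr1", 1_000_000),),
        marker_density=1e-3,
        coverage=0.78,
        read_error=0.0,
        crossover_rate=1.0,
    )
    base.update(kw)
    return GenomeSpec(**base)


class TestMarkerMap:
    def test_positions_sorted_unique_and_count_near_poisson_mean(self):
        mk = simulate_marker_map(spec_1mb(), seed=7)
        pos = mk.positions["chr1"]
        assert (np.diff(pos) > 0).all()
        # Poisson(1000): count within 4 standard deviations of the mean
        assert abs(len(pos) - 1000) <= 4 * np.sqrt(1000)

    def test_invalid_density_rejected(self):
        with pytest.raises(InvalidSpecError):
            spec_1mb(marker_density=0.0)

    def test_same_seed_reproduces_map_exactly(self):
        a = simulate_marker_map(spec_1mb(), seed=7)
        b = simulate_marker_map(spec_1mb(), seed=7)
        assert np.array_equal(a.positions["chr1"], b.positions["chr1"])
        assert np.array_equal(a.allele_a["chr1"], b.allele_a["chr1"])
        assert np.array_equal(a.allele_b["chr1"], b.allele_b["chr1"])

    def test_markers_are_homozygous_divergent(self):
        mk = simulate_marker_map(spec_1mb(), seed=3)
        assert (mk.allele_a["chr1"] != mk.allele_b["chr1"]).all()


class TestF2Cohort:
    def test_no_recombination_gives_constant_chromosomes_with_f2_ratios(self):
        spec = spec_1mb(crossover_rate=0.0)
        mk = simulate_marker_map(spec, seed=1)
        truth = simulate_f2_cohort(mk, 2000, spec, seed=2)
        dos = truth.dosage["chr1"]
        # each individual constant across the chromosome
        assert (dos == dos[:, :1]).all()
        frac = np.mean(dos[:, 0] == 1)
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / 2000)

    def test_genomewide_ab_fraction_matches_mendelian_expectation(self):
        spec = spec_1mb(marker_density=1e-4)
        mk = simulate_marker_map(spec, seed=5)
        truth = simulate_f2_cohort(mk, 10_000, spec, seed=6)
        ab = (truth.dosage["chr1"] == 1).mean()
        assert abs(ab - 0.5) <= 3 * np.sqrt(0.25 / 10_000)

    def test_mendelian_marginals_per_marker(self):
        spec = spec_1mb(marker_density=2e-5)
        mk = simulate_marker_map(spec, seed=8)
        truth = simulate_f2_cohort(mk, 5000, spec, seed=9)
        dos = truth.dosage["chr1"]
        n = truth.n
        for k, expected in ((2, 0.25), (1, 0.5), (0, 0.25)):
            frac = (dos == k).mean(axis=0)
            se = np.sqrt(expected * (1 - expected) / n)
            assert (np.abs(frac - expected) <= 3 * se).all()

    def test_breakpoints_sorted_and_in_bounds(self):
        spec = spec_1mb(crossover_rate=3.0)
        mk = simulate_marker_map(spec, seed=1)
        truth = simulate_f2_cohort(mk, 50, spec, seed=2)
        for i in range(truth.n):
            for g in range(2):
                bps = truth.gamete_breakpoints["chr1"][i][g]
                assert (np.diff(bps) >= 0).all()
                assert ((bps >= 0) & (bps < 1_000_000)).all()

    def test_cohort_size_must_be_positive(self):
        spec = spec_1mb()
        mk = simulate_marker_map(spec, seed=1)
        with pytest.raises(InvalidSpecError):
            simulate_f2_cohort(mk, 0, spec, seed=2)

    def test_truth_consistency_gametes_reproduce_genotypes(self):
        """Recombining the two stored gamete mosaics gives the stored dosage."""
        spec = spec_1mb(crossover_rate=2.0)
        mk = simulate_marker_map(spec, seed=4)
        truth = simulate_f2_cohort(mk, 30, spec, seed=5)
        pos = mk.positions["chr1"]
        check = np.linspace(0, len(pos) - 1, 25).astype(int)
        for j in check:
            assert np.array_equal(
                truth.dosage_at("chr1", int(pos[j])), truth.dosage["chr1"][:, j]
            )


class TestAlleleCounts:
    def test_zero_coverage_means_zero_counts(self):
        spec = spec_1mb(coverage=0.0)
        mk = simulate_marker_map(spec, seed=1)
        truth = simulate_f2_cohort(mk, 10, spec, seed=2)
        counts = simulate_allele_counts(truth, mk, spec, seed=3)
        assert counts.total_reads() == 0

    def test_error_free_reads_match_homozygous_genotype(self):
        spec = spec_1mb(coverage=2.0, read_error=0.0)
        mk = simulate_marker_map(spec, seed=1)
        truth = simulate_f2_cohort(mk, 20, spec, seed=2)
        counts = simulate_allele_counts(truth, mk, spec, seed=3)
        dos = truth.dosage["chr1"]
        assert (counts.n_b["chr1"][dos == 2] == 0).all()
        assert (counts.n_a["chr1"][dos == 0] == 0).all()

    def test_mean_depth_matches_poisson_coverage(self):
        spec = GenomeSpec(
            chromosomes=(("chr1", 10_000_000),), marker_density=1e-3, coverage=0.78
        )
        mk = simulate_marker_map(spec, seed=1)
        truth = simulate_f2_cohort(mk, 1, spec, seed=2)
        counts = simulate_allele_counts(truth, mk, spec, seed=3)
        depth = counts.n_a["chr1"] + counts.n_b["chr1"]
        m = depth.size
        assert m >= 9000
        assert abs(depth.mean() - 0.78) <= 3 * np.sqrt(0.78 / m)

    def test_reference_bias_shifts_het_reads_monotonically(self):
        het = np.ones((1, 1), dtype=np.int8)
        probs = [float(allele_a_probability(het, 0.01, d)[0, 0]) for d in (0.0, 0.1, 0.2)]
        assert probs[0] < probs[1] < probs[2]
        # and empirically in sampled counts at AB markers
        spec0 = spec_1mb(coverage=3.0, read_error=0.01)
        mk = simulate_marker_map(spec0, seed=1)
        truth = simulate_f2_cohort(mk, 200, spec0, seed=2)
        fracs = []
        for delta in (0.0, 0.1, 0.2):
            spec = spec_1mb(coverage=3.0, read_error=0.01, ref_bias=delta)
            counts = simulate_allele_counts(truth, mk, spec, seed=3)
            ab = truth.dosage["chr1"] == 1
            tot = counts.n_a["chr1"][ab] + counts.n_b["chr1"][ab]
            fracs.append(counts.n_a["chr1"][ab].sum() / tot.sum())
        assert fracs[0] < fracs[1] < fracs[2]

    def test_same_seed_reproduces_counts(self):
        spec = spec_1mb(coverage=1.0)
        mk = simulate_marker_map(spec, seed=1)
        truth = simulate_f2_cohort(mk, 5, spec, seed=2)
        a = simulate_allele_counts(truth, mk, spec, seed=9)
        b = simulate_allele_counts(truth, mk, spec, seed=9)
        assert np.array_equal(a.n_a["chr1"], b.n_a["chr1"])
        assert np.array_equal(a.n_b["chr1"], b.n_b["chr1"])


class TestPhenotypes:
    @pytest.fixture
    def cohort(self):
        spec = spec_1mb()
        mk = simulate_marker_map(spec, seed=1)
        return simulate_f2_cohort(mk, 400, spec, seed=2)

    def test_degenerate_model_returns_exact_baselines(self, cohort):
        table = simulate_phenotypes(cohort, [], (120, 160, 210), 0.0, 0.0, seed=3)
        assert (table["hr21"] == 120).all()
        assert (table["hr28"] == 160).all()
        assert (table["hr35"] == 210).all()

    def test_additive_qtl_separates_homozygotes_by_twice_the_effect(self, cohort):
        qtl = QTL("chr1", 500_000, additive=(10.0, 10.0, 10.0))
        table = simulate_phenotypes(cohort, [qtl], (120, 160, 210), 0.0, 0.0, seed=3)
        dos = cohort.qtl_dosage[:, 0]
        diff = table["hr28"][dos == 2].mean() - table["hr28"][dos == 0].mean()
        assert diff == pytest.approx(20.0)

    def test_arrhythmia_halves_every_recorded_rate(self, cohort):
        table = simulate_phenotypes(cohort, [], (120, 160, 210), 5.0, 1.0, seed=3)
        assert cohort.arrhythmia.all()
        assert np.allclose(table[["hr21", "hr28", "hr35"]], cohort.latent_rates / 2)

    def test_negative_noise_rejected(self, cohort):
        with pytest.raises(InvalidSpecError):
            simulate_phenotypes(cohort, [], (120, 160, 210), -1.0, 0.0, seed=3)

    def test_qtl_outside_genome_rejected(self, cohort):
        with pytest.raises(InvalidSpecError):
            simulate_phenotypes(
                cohort, [QTL("chr1", 2_000_000, (1, 1, 1))], (120, 160, 210), 0, 0, 3
            )
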