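"""The simulator must reproduce its own configuration: SNP counts, cross
expectations (closed-form backcross ancestry), pooled-sequencing moments,
and the planted haplogroup structure of the balanced locus."""

import numpy as np
import pytest

from flcdmap import haplotype_popgen as hp
from flcdmap import synthetic_data as sd
from flcdmap.errors import ParameterError


class TestParentalGenomes:
    def test_zero_density_gives_no_snps(self):
        parents = sd.simulate_parental_genomes(1_000_000, 0.0, 0.5, seed=1)
        assert parents.n_snps == 0

    def test_full_fixed_fraction(self):
        parents = sd.simulate_parental_genomes(100_000, 0.01, 1.0, seed=2)
        assert parents.n_snps > 0
        assert parents.fixed_diff_mask.all()
        assert (parents.dark_allele != parents.light_allele).all()

    def test_recount_against_emitted_table(self):
        """SNP and fixed-difference counts match an independent recount."""
        parents = sd.simulate_parental_genomes(1_000_000, 0.005, 0.5, seed=1)
        n = parents.n_snps
        n_fixed = int((parents.dark_allele != parents.light_allele).sum())
        assert n_fixed == int(parents.fixed_diff_mask.sum())
        # binomial sampling bands (4 sigma)
        assert abs(n - 5000) < 4 * np.sqrt(1_000_000 * 0.005)
        assert abs(n_fixed - n / 2) < 4 * np.sqrt(n * 0.25)
        assert np.all(np.diff(parents.positions) > 0)
        a1, a2 = parents.site_alleles()
        assert (a1 != a2).all()

    def test_causal_snp_always_planted(self):
        parents = sd.simulate_parental_genomes(
            100_000, 0.001, 0.2, seed=3, causal_position=50_000
        )
        j = np.searchsorted(parents.positions, 50_000)
        assert parents.positions[j] == 50_000
        assert parents.fixed_diff_mask[j]

    @pytest.mark.parametrize(
        "kwargs",
        [dict(chrom_length=0), dict(snp_density=-0.1), dict(snp_density=1.5)],
    )
    def test_parameter_errors(self, kwargs):
        args = dict(chrom_length=1000, snp_density=0.01, fixed_diff_fraction=0.5)
        args.update(kwargs)
        with pytest.raises(ParameterError):
            sd.simulate_parental_genomes(seed=1, **args)


class TestBackcross:
    def test_no_recombination_gives_half_everywhere(self):
        parents = sd.simulate_parental_genomes(
            200_000, 0.005, 0.5, seed=4, causal_position=100_000
        )
        design = sd.CrossDesign(causal_position=100_000, recombination_rate=0.0,
                                pool_size=10)
        truth = sd.simulate_backcross(parents, design, seed=5)
        assert np.all(truth.fraction == 0.5)
        assert np.all(truth.carrier_fraction() == 1.0)

    def test_homozygous_line_fixed_at_causal(self):
        parents = sd.simulate_parental_genomes(
            500_000, 0.005, 0.5, seed=6, causal_position=250_000
        )
        design = sd.CrossDesign(causal_position=250_000,
                                n_backcross_generations=12,
                                homozygous_line=True, pool_size=10)
        truth = sd.simulate_backcross(parents, design, seed=7)
        j = np.searchsorted(parents.positions, 250_000)
        assert truth.fraction[j] == 1.0
        assert truth.n_light_copies == 0

    def test_closed_form_carrier_expectation(self):
        """Simulated carrier ancestry follows (1-r)^n with Haldane r,
        from complete linkage (r=0 -> 1, pool 0.5) to free recombination
        (r=1/2 -> 0.5^n)."""
        L, causal, rate, n_gens = 2_000_000, 1_000_000, 5.0, 7
        parents = sd.simulate_parental_genomes(L, 0.0005, 1.0, seed=8,
                                               causal_position=causal)
        design = sd.CrossDesign(causal_position=causal,
                                n_backcross_generations=n_gens,
                                recombination_rate=rate, pool_size=400)
        truth = sd.simulate_backcross(parents, design, seed=9)
        dists = np.array([0, 50_000, 200_000, 900_000])
        probe = causal + dists
        sim = truth.carrier_fraction(probe)
        theory = sd.expected_carrier_ancestry(dists, rate, n_gens)
        se = np.sqrt(np.maximum(theory * (1 - theory), 1e-4) / 400)
        assert np.all(np.abs(sim - theory) < 4 * se)
        # pool fraction at the causal site is exactly 0.5 (het pool)
        j = np.searchsorted(parents.positions, causal)
        assert truth.fraction[j] == 0.5
        # unlinked limit of the closed form itself
        assert sd.expected_carrier_ancestry(1e12, 2.0, 7) == pytest.approx(0.5**7)

    def test_zero_retained_raises(self):
        parents = sd.simulate_parental_genomes(100_000, 0.001, 0.5, seed=10,
                                               causal_position=50_000)
        design = sd.CrossDesign(causal_position=50_000, pool_size=2, max_tries=1,
                                recombination_rate=50.0)
        with pytest.raises(sd.SimulationError):
            for s in range(50):  # rejection with one try per meiosis fails fast
                sd.simulate_backcross(parents, design, seed=s)


class TestPoolseq:
    def test_count_conservation(self, rng):
        parents = sd.simulate_parental_genomes(100_000, 0.01, 0.5, seed=11)
        truth = rng.random(parents.n_snps)
        dark, depth = sd.simulate_poolseq(truth, 30.0, 0.01, rng)
        arr = sd.counts_from_reads(parents, dark, depth)
        assert np.array_equal(arr.sum(axis=1), depth)

    def test_pure_pool_all_dark_reads(self, rng):
        truth = np.ones(1000)
        dark, depth = sd.simulate_poolseq(truth, 20.0, 0.0, rng)
        assert np.array_equal(dark, depth)

    def test_moments_match_binomial_poisson_mixture(self):
        truth = np.full(10_000, 0.5)
        dark, depth = sd.simulate_poolseq(truth, 50.0, 0.0, seed=7)
        ok = depth > 0
        freq = dark[ok] / depth[ok]
        assert freq.mean() == pytest.approx(0.5, abs=4 * 0.071 / np.sqrt(ok.sum()))
        expected_var = np.mean(0.25 / depth[ok])
        assert freq.var() == pytest.approx(expected_var, rel=0.10)

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            sd.simulate_poolseq(np.array([0.5]), 0.0, 0.0, seed=1)
        with pytest.raises(ParameterError):
            sd.simulate_poolseq(np.array([0.5]), 10.0, 0.6, seed=1)


class TestBalancedLocus:
    def test_zero_within_diversity_identical_within_groups(self):
        cfg = sd.BalancedLocusConfig(within_diversity=0.0)
        aln = sd.simulate_balanced_locus(cfg, seed=1)
        n = cfg.n_per_haplogroup
        for block in (aln.seqs[:n], aln.seqs[n:2 * n]):
            assert (block == block[0]).all()

    def test_exchangeable_when_between_equals_within(self):
        cfg = sd.BalancedLocusConfig(between_divergence=0.005,
                                     within_diversity=0.005,
                                     outgroup_divergence=0.05)
        aln = sd.simulate_balanced_locus(cfg, seed=2)
        truth = aln.site_truth["group_of"]
        assign = hp.HaplogroupAssignment(group_of=truth, branch_length=1.0)
        fst = hp.per_snp_fst(aln, assign)
        assert abs(np.nanmean(fst)) < 0.08

    def test_config_recovery_from_pairwise_counts(self):
        """Core Dxy, within diversity and outgroup distances recover the
        configuration, averaged over seeds (direct pairwise-difference
        counting via the popgen module)."""
        cfg = sd.BalancedLocusConfig()
        dab, dwithin, dao, dbo = [], [], [], []
        for seed in range(12):
            aln = sd.simulate_balanced_locus(cfg, seed=seed)
            core = aln.slice(*cfg.core_interval)
            a = [i for i in aln.ingroup_ids if i.startswith("dark")]
            b = [i for i in aln.ingroup_ids if i.startswith("light")]
            dab.append(hp.group_dxy(core, a, b))
            dao.append(hp.group_dxy(core, a, ["outgroup"]))
            dbo.append(hp.group_dxy(core, b, ["outgroup"]))
            dwithin.append(np.mean([
                hp.p_distance(core.row(a[0]), core.row(a[1])),
                hp.p_distance(core.row(b[0]), core.row(b[1])),
            ]))
        assert np.mean(dab) == pytest.approx(cfg.between_divergence, rel=0.10)
        assert np.mean(dao) == pytest.approx(cfg.outgroup_divergence, rel=0.15)
        assert np.mean(dwithin) == pytest.approx(cfg.within_diversity, rel=0.5)
        # ILS signature: outgroup closer to group A than the groups are
        # to each other; group B clearly further from the outgroup
        assert np.mean(dao) < np.mean(dab) < np.mean(dbo)

    def test_haplogroup_structure_decays_into_flanks(self):
        """Fixed-difference density in the far flanks is a small fraction
        of the core density (exponential decay of the group stems)."""
        cfg = sd.BalancedLocusConfig()
        core_fixed = flank_fixed = 0
        core_len = flank_len = 0
        for seed in range(5):
            aln = sd.simulate_balanced_locus(cfg, seed=100 + seed)
            assign = hp.HaplogroupAssignment(
                group_of=aln.site_truth["group_of"], branch_length=1.0
            )
            _, nc, _, _ = hp.site_counts(aln, assign, cfg.core_interval)
            _, nl, _, _ = hp.site_counts(aln, assign, (0, 200))
            _, nr, _, _ = hp.site_counts(aln, assign, (2800, 3000))
            core_fixed += nc
            flank_fixed += nl + nr
            core_len += cfg.core_interval[1] - cfg.core_interval[0]
            flank_len += 400
        assert core_fixed / core_len > 0.04  # strong structure in the core
        assert flank_fixed / flank_len < 0.2 * core_fixed / core_len

    def test_invalid_core_interval(self):
        with pytest.raises(ParameterError):
            sd.simulate_balanced_locus(
                sd.BalancedLocusConfig(core_interval=(2500, 3500)), seed=1
            )
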