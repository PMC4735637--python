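"""Distances, neighbour joining on additive matrices, haplogroup
assignment, Hudson FST, site counts, group Dxy and the ILS scan."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from flcdmap import haplotype_popgen as hp
from flcdmap import synthetic_data as sd
from flcdmap.errors import InputError


def aln_from_strings(pairs, **kwargs):
    ids = [i for i, _ in pairs]
    seqs = np.array([list(s) for _, s in pairs], dtype="<U1")
    return hp.HaplotypeAlignment(ids=ids, seqs=seqs, **kwargs)


def tip_distances(tree, ids):
    """Patristic tip-to-tip distances (independent check of NJ output)."""
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tree.find(ids[i]).distance(tree.find(ids[j]))
    return d


class TestDistances:
    def test_identical_and_simple(self):
        a = np.array(list("ACGT"))
        assert hp.p_distance(a, a) == 0.0
        assert hp.p_distance(a, np.array(list("ACGA"))) == 0.25

    def test_pairwise_deletion(self):
        assert hp.p_distance(np.array(list("AC-T")), np.array(list("ACGT"))) == 0.0

    def test_no_comparable_sites_raises(self):
        with pytest.raises(InputError):
            hp.p_distance(np.array(list("--")), np.array(list("AC")))

    def test_matrix_symmetric_zero_diagonal(self):
        aln = aln_from_strings([("a", "ACGT"), ("b", "ACGA"), ("c", "TCGA")])
        dm = hp.pairwise_distances(aln)
        assert np.allclose(dm.data, dm.data.T)
        assert np.all(np.diag(dm.data) == 0)
        assert dm["a", "b"] == 0.25


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
                            ["a", "b", "c"])
        tree = hp.nj_tree(dm)
        d = tip_distances(tree, ["a", "b", "c"])
        assert np.allclose(d, dm.data)

    def test_four_taxa_additive_recovery(self):
        # distances generated from tree ((a:2,b:3):1,(c:4,d:5):1)
        dm = DistanceMatrix(
            np.array(
                [[0, 5, 8, 9], [5, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float
            ),
            ["a", "b", "c", "d"],
        )
        tree = hp.nj_tree(dm)
        assert np.allclose(tip_distances(tree, ["a", "b", "c", "d"]), dm.data)
        # topology: {a,b} vs {c,d}
        assign = hp.assign_haplogroups(tree)
        assert set(assign.members("A")) == {"a", "b"}

    def test_too_few_taxa(self):
        with pytest.raises(InputError):
            hp.nj_tree(DistanceMatrix(np.array([[0, 1], [1, 0]], float), ["a", "b"]))


class TestAssignHaplogroups:
    def test_two_cluster_matrix(self):
        ids = ["a1", "a2", "a3", "b1", "b2", "b3"]
        d = np.full((6, 6), 1.0)
        d[:3, :3] = 0.05
        d[3:, 3:] = 0.05
        np.fill_diagonal(d, 0.0)
        tree = hp.nj_tree(DistanceMatrix(d, ids))
        assign = hp.assign_haplogroups(tree, ids)
        assert set(assign.members("A")) == {"a1", "a2", "a3"}
        assert set(assign.members("B")) == {"b1", "b2", "b3"}

    def test_identical_sequences_error(self):
        aln = aln_from_strings([(f"s{i}", "ACGTACGT") for i in range(5)])
        tree = hp.nj_tree(hp.pairwise_distances(aln))
        with pytest.raises(InputError):
            hp.assign_haplogroups(tree)

    def test_simulated_recovery_across_seeds(self):
        cfg = sd.BalancedLocusConfig()
        errors = 0
        for seed in range(15):
            aln = sd.simulate_balanced_locus(cfg, seed=200 + seed)
            ingroup = aln.ingroup_ids
            tree = hp.nj_tree(hp.pairwise_distances(aln, ingroup))
            assign = hp.assign_haplogroups(tree, ingroup)
            truth = aln.site_truth["group_of"]
            a = set(assign.members("A"))
            ta = {s for s, g in truth.items() if g == "A"}
            tb = {s for s, g in truth.items() if g == "B"}
            if a not in (ta, tb):
                errors += 1
        assert errors == 0


class TestFst:
    def _assign(self, a_ids, b_ids):
        g = {s: "A" for s in a_ids}
        g.update({s: "B" for s in b_ids})
        return hp.HaplogroupAssignment(group_of=g, branch_length=1.0)

    def test_fixed_difference_is_one(self):
        aln = aln_from_strings(
            [("a1", "A"), ("a2", "A"), ("b1", "T"), ("b2", "T")]
        )
        fst = hp.per_snp_fst(aln, self._assign(["a1", "a2"], ["b1", "b2"]))
        assert fst[0] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        """p1=0.9, p2=0.1, n=10 per group: FST = 1 - 0.2/0.82."""
        a = [(f"a{i}", "A" if i < 9 else "T") for i in range(10)]
        b = [(f"b{i}", "A" if i < 1 else "T") for i in range(10)]
        aln = aln_from_strings(a + b)
        fst = hp.per_snp_fst(
            aln, self._assign([i for i, _ in a], [i for i, _ in b])
        )
        assert fst[0] == pytest.approx(1 - 0.2 / 0.82)

    def test_monomorphic_site_missing(self):
        aln = aln_from_strings(
            [("a1", "A"), ("a2", "A"), ("b1", "A"), ("b2", "A")]
        )
        fst = hp.per_snp_fst(aln, self._assign(["a1", "a2"], ["b1", "b2"]))
        assert np.isnan(fst[0])

    def test_panmictic_mean_near_zero(self, rng):
        """Random split of one panmictic pool: mean FST ~ 0 (can be < 0)."""
        n, L = 20, 400
        seqs = np.where(rng.random((n, L)) < 0.3, "T", "A").astype("<U1")
        aln = hp.HaplotypeAlignment(ids=[f"s{i}" for i in range(n)], seqs=seqs)
        means = []
        for _ in range(10):
            perm = rng.permutation(n)
            fst = hp.per_snp_fst(
                aln,
                self._assign([f"s{i}" for i in perm[:10]],
                             [f"s{i}" for i in perm[10:]]),
            )
            means.append(np.nanmean(fst))
        assert abs(np.mean(means)) < 0.03


class TestSiteCounts:
    def _assign(self, a_ids, b_ids):
        g = {s: "A" for s in a_ids}
        g.update({s: "B" for s in b_ids})
        return hp.HaplogroupAssignment(group_of=g, branch_length=1.0)

    def test_all_identical(self):
        aln = aln_from_strings([("a1", "AAA"), ("a2", "AAA"),
                                ("b1", "AAA"), ("b2", "AAA")])
        n_seg, n_fix, _, _ = hp.site_counts(
            aln, self._assign(["a1", "a2"], ["b1", "b2"])
        )
        assert (n_seg, n_fix) == (0, 0)

    def test_toy_enumeration(self):
        aln = aln_from_strings([("a1", "AAA"), ("a2", "AAA"),
                                ("b1", "TAT"), ("b2", "TAT")])
        n_seg, n_fix, seg_cols, fix_cols = hp.site_counts(
            aln, self._assign(["a1", "a2"], ["b1", "b2"])
        )
        assert (n_seg, n_fix) == (2, 2)
        assert seg_cols.tolist() == [0, 2] and fix_cols.tolist() == [0, 2]

    def test_fixed_subset_of_segregating(self, rng):
        """Every between-group fixed difference is a segregating site of
        the pooled ingroup."""
        for _ in range(20):
            n, L = 12, 60
            seqs = rng.choice(list("ACGT-N"), size=(n, L),
                              p=[0.3, 0.3, 0.15, 0.15, 0.05, 0.05]).astype("<U1")
            aln = hp.HaplotypeAlignment(ids=[f"s{i}" for i in range(n)], seqs=seqs)
            assign = self._assign([f"s{i}" for i in range(6)],
                                  [f"s{i}" for i in range(6, 12)])
            n_seg, n_fix, seg_cols, fix_cols = hp.site_counts(aln, assign)
            assert set(fix_cols) <= set(seg_cols)
            assert n_fix <= n_seg

    def test_simulated_counts_match_planted_mutations(self):
        cfg = sd.BalancedLocusConfig()
        aln = sd.simulate_balanced_locus(cfg, seed=77)
        truth = aln.site_truth
        assign = hp.HaplogroupAssignment(group_of=truth["group_of"],
                                         branch_length=1.0)
        n_seg, n_fix, _, _ = hp.site_counts(aln, assign)
        cat = truth["category"]
        # AO_shared mutations are fixed in group A relative to B (the
        # outgroup plays no role in ingroup site counts)
        expected_fixed = int(np.isin(cat, ["fixed_A", "fixed_B", "AO_shared"]).sum())
        expected_seg = expected_fixed + int((cat == "singleton").sum())
        assert n_fix == expected_fixed
        assert n_seg == expected_seg


class TestGroupDxy:
    def test_self_pair_zero(self):
        aln = aln_from_strings([("a", "ACGT")])
        assert hp.group_dxy(aln, ["a"], ["a"]) == 0.0

    def test_mean_of_pairwise(self):
        aln = aln_from_strings([
            ("s1", "AAAAAAAAAA"),
            ("s2", "TTTAAAAAAA"),
            ("t1", "AAAAAAAAAC"),
            ("t2", "AAAAAAAACC"),
        ])
        # pair distances: s1-t1 .1, s1-t2 .2, s2-t1 .4, s2-t2 .5
        val = hp.group_dxy(aln, ["s1", "s2"], ["t1", "t2"])
        assert val == pytest.approx((0.1 + 0.2 + 0.4 + 0.5) / 4)

    def test_empty_set_rejected(self):
        aln = aln_from_strings([("a", "ACGT")])
        with pytest.raises(InputError):
            hp.group_dxy(aln, [], ["a"])


class TestIlsScan:
    def _sim(self, seed, **kw):
        cfg = sd.BalancedLocusConfig(**kw)
        aln = sd.simulate_balanced_locus(cfg, seed=seed)
        assign = hp.HaplogroupAssignment(
            group_of=aln.site_truth["group_of"], branch_length=1.0
        )
        return cfg, aln, assign

    def test_distant_outgroup_no_intervals(self):
        """Without the deep-branch signal (exchangeable haplogroups) the
        outgroup is farther than within-species variation everywhere."""
        cfg, aln, assign = self._sim(
            3, between_divergence=0.005, within_diversity=0.005,
            outgroup_divergence=0.05,
        )
        assert hp.ils_scan(aln, assign, "outgroup") == []

    def test_core_interval_recovered(self):
        cfg, aln, assign = self._sim(4)
        ivs = hp.ils_scan(aln, assign, "outgroup")
        s, e = cfg.core_interval
        assert any(a < e and b > s for a, b in ivs)

    def test_full_length_window_single_interval(self):
        # window wider than the alignment collapses to one full-length
        # window; on the core (where ILS holds throughout) it is flagged
        cfg, aln, assign = self._sim(5)
        core = aln.slice(*cfg.core_interval)
        ivs = hp.ils_scan(core, assign, "outgroup", window_bp=10_000)
        assert ivs == [(0, core.length)]
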