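"""Sequence likelihood: pruning, branch-length MLE, quadratic approximation."""

import itertools
import math

import numpy as np
import pytest

from phyloclock.rate_models import BranchRates
from phyloclock.substitution import (
    Alignment,
    ApproxLikelihood,
    SubstitutionModel,
    approx_loglik,
    discrete_gamma_rates,
    encode_sequence,
    exact_loglik,
    exact_loglik_and_gradient,
    fit_approx_surface,
    mle_branch_lengths,
    partition_loglik,
    read_partition_file,
)
from phyloclock.synthetic import (
    SimulationRecipe,
    simulate_alignment,
    simulate_rates,
    simulate_timetree,
)
from phyloclock.trees import TimeTree, read_newick


def _nonroot(top):
    return [v for v in range(top.n_nodes) if top.parent[v] != -1]


def _rand_b(top, rng, lo=0.05, hi=0.6):
    b = np.zeros(top.n_nodes)
    b[_nonroot(top)] = rng.uniform(lo, hi, len(_nonroot(top)))
    return b


class TestSubstitutionModel:
    def test_lg_matrix_properties(self):
        m = SubstitutionModel.lg()
        assert m.freqs.sum() == pytest.approx(1.0)
        assert np.allclose(m.Q.sum(axis=1), 0.0, atol=1e-12)
        assert -(m.freqs * np.diag(m.Q)).sum() == pytest.approx(1.0)
        # detailed balance of the reversible chain
        flux = m.freqs[:, None] * m.Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_pmat_is_stochastic_and_correct_at_zero(self):
        m = SubstitutionModel.lg()
        P = m.pmat(0.37)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert (P >= -1e-12).all()
        assert np.allclose(m.pmat(0.0), np.eye(20), atol=1e-12)

    def test_discrete_gamma_rates_average_to_one(self):
        for alpha in [0.2, 0.7, 2.0]:
            r = discrete_gamma_rates(alpha, 4)
            assert r.mean() == pytest.approx(1.0)
            assert (np.diff(r) > 0).all()
        # smaller shape = more heterogeneous categories
        assert discrete_gamma_rates(0.2, 4).max() > discrete_gamma_rates(2.0, 4).max()


class TestExactLoglik:
    def test_constant_site_zero_lengths_gives_stationary_frequency(self):
        top = read_newick("((A,B),C);")
        m = SubstitutionModel.lg()
        aln = Alignment(["A", "B", "C"], np.zeros((3, 1), dtype=np.int8))  # all Ala
        ll = exact_loglik(aln, top, np.zeros(top.n_nodes), m)
        assert ll == pytest.approx(math.log(m.freqs[0]), abs=1e-5)

    def test_matches_exhaustive_state_enumeration(self, rng):
        """4-taxon, 2-site toy under a 2-category gamma: brute-force sum over
        all internal-state assignments and categories."""
        top = read_newick("((A,B),(C,D));")
        m = SubstitutionModel.poisson(alpha=0.5, ncat=2)
        codes = rng.integers(0, 20, size=(4, 2)).astype(np.int8)
        aln = Alignment(["A", "B", "C", "D"], codes)
        b = _rand_b(top, rng)
        internals = top.internal_nodes
        P = {v: [m.pmat(max(b[v], 1e-8) * r) for r in m.rates] for v in _nonroot(top)}
        tip_of = {top.labels[v]: v for v in range(top.n_nodes) if top.is_tip[v]}
        total = 0.0
        for site in range(2):
            lik = 0.0
            for k in range(m.ncat):
                for assign in itertools.product(range(20), repeat=len(internals)):
                    st = dict(zip(internals, assign))
                    for t, v in tip_of.items():
                        st[v] = codes[aln.taxa.index(t), site]
                    p = m.freqs[st[top.root]]
                    for v in _nonroot(top):
                        p *= P[v][k][st[top.parent[v]], st[v]]
                    lik += p / m.ncat
            total += math.log(lik)
        assert exact_loglik(aln, top, b, m) == pytest.approx(total, abs=1e-9)

    def test_two_sequence_match_probability_closed_form(self, rng):
        """Poisson model at distance d: P(match) = 1/20 + (19/20) e^{-20d/19}."""
        d = 0.3
        top = read_newick("(A,B);")
        tree = TimeTree(top, np.where(np.arange(top.n_nodes) == top.root, d / 2, 0.0))
        m = SubstitutionModel.poisson()
        rec = SimulationRecipe(n_taxa=2, gene_length=100_000, seed=3)
        aln, _ = simulate_alignment(tree, BranchRates("ir", np.ones(top.n_nodes)), m, rec, rng)
        frac_diff = (aln.codes[0] != aln.codes[1]).mean()
        expected = (19 / 20) * (1 - math.exp(-(20 / 19) * d))
        assert frac_diff == pytest.approx(expected, abs=0.005)

    def test_invariant_under_taxon_and_site_reordering(self, rng):
        top = read_newick("((A,B),(C,D));")
        m = SubstitutionModel.lg(alpha=0.7, ncat=4)
        codes = rng.integers(0, 20, size=(4, 30)).astype(np.int8)
        b = _rand_b(top, rng)
        aln = Alignment(["A", "B", "C", "D"], codes)
        ll = exact_loglik(aln, top, b, m)
        perm_taxa = Alignment(["D", "B", "A", "C"], codes[[3, 1, 0, 2]])
        assert exact_loglik(perm_taxa, top, b, m) == pytest.approx(ll)
        sites = rng.permutation(30)
        perm_sites = Alignment(["A", "B", "C", "D"], codes[:, sites])
        assert exact_loglik(perm_sites, top, b, m) == pytest.approx(ll)

    def test_gamma_with_huge_shape_equals_single_rate(self, rng):
        top = read_newick("((A,B),C);")
        codes = rng.integers(0, 20, size=(3, 50)).astype(np.int8)
        aln = Alignment(["A", "B", "C"], codes)
        b = _rand_b(top, rng)
        ll_g = exact_loglik(aln, top, b, SubstitutionModel.lg(alpha=1e6, ncat=4))
        ll_1 = exact_loglik(aln, top, b, SubstitutionModel.lg())
        assert abs(ll_g - ll_1) < 1e-4

    def test_taxon_mismatch_raises(self, rng):
        top = read_newick("((A,B),C);")
        aln = Alignment(["A", "B", "X"], rng.integers(0, 20, (3, 5)).astype(np.int8))
        with pytest.raises(ValueError, match="mismatch"):
            exact_loglik(aln, top, np.zeros(top.n_nodes), SubstitutionModel.lg())

    def test_analytic_gradient_matches_finite_differences(self, rng):
        top = read_newick("(((A,B),C),(D,E));")
        m = SubstitutionModel.lg(alpha=0.7, ncat=4)
        codes = rng.integers(0, 20, size=(5, 60)).astype(np.int8)
        codes[0, :6] = 20  # missing block
        aln = Alignment(["A", "B", "C", "D", "E"], codes)
        b = _rand_b(top, rng)
        _, g = exact_loglik_and_gradient(aln, top, b, m)
        for v in _nonroot(top):
            eps = 1e-6
            bp, bm = b.copy(), b.copy()
            bp[v] += eps
            bm[v] -= eps
            fd = (exact_loglik(aln, top, bp, m) - exact_loglik(aln, top, bm, m)) / (2 * eps)
            assert g[v] == pytest.approx(fd, abs=1e-4)


class TestMleBranchLengths:
    def test_two_sequence_distance_closed_form(self, rng):
        top = read_newick("(A,B);")
        m = SubstitutionModel.poisson()
        codes = rng.integers(0, 20, size=(2, 5000)).astype(np.int8)
        codes[1, :4000] = codes[0, :4000]  # fix p = 0.2
        aln = Alignment(["A", "B"], codes)
        p = (codes[0] != codes[1]).mean()
        bhat, _ = mle_branch_lengths(aln, top, m)
        expected = -(19 / 20) * math.log(1 - (20 / 19) * p)
        assert bhat.sum() == pytest.approx(expected, rel=1e-3)

    def test_recovers_simulated_branch_lengths(self, rng):
        """6 taxa, 5e4 sites: every identifiable length within 3% of truth.

        Under a reversible model only tip-to-tip path lengths (and the sum
        of the two root-adjacent branches) are identifiable from a rooted
        tree, so the comparison is over all pairwise path lengths plus the
        root-pair sum rather than raw per-branch values near the root.
        """
        import itertools

        m = SubstitutionModel.lg()
        rec = SimulationRecipe(n_taxa=6, gene_length=50_000, seed=7)
        tree = simulate_timetree(rec)
        rates = simulate_rates(tree, "ir", 0.1, 0.2, rng)
        aln, _ = simulate_alignment(tree, rates, m, rec, rng)
        bhat, _ = mle_branch_lengths(aln, tree.topology, m)
        truth = tree.branch_durations() * rates.branch_rates(tree.topology)
        top = tree.topology

        def path_length(b, x, y):
            anc = {x}
            v = x
            while top.parent[v] != -1:
                v = top.parent[v]
                anc.add(v)
            total = 0.0
            v = y
            while v not in anc:
                total += b[v]
                v = top.parent[v]
            stop = v
            v = x
            while v != stop:
                total += b[v]
                v = top.parent[v]
            return total

        tips = [v for v in range(top.n_nodes) if top.is_tip[v]]
        for x, y in itertools.combinations(tips, 2):
            assert path_length(bhat, x, y) == pytest.approx(
                path_length(truth, x, y), rel=0.03
            )
        rk = top.children[top.root]
        assert bhat[rk].sum() == pytest.approx(truth[rk].sum(), rel=0.03)

    def test_zero_branch_estimated_at_boundary(self, rng):
        top = read_newick("((A,B),C);")
        m = SubstitutionModel.poisson()
        codes = rng.integers(0, 20, size=(1, 3000)).astype(np.int8)
        # B identical to A: the A-B cherry branch lengths collapse to zero
        aln = Alignment(["A", "B", "C"], np.vstack([codes, codes, rng.integers(0, 20, (1, 3000))]).astype(np.int8))
        bhat, _ = mle_branch_lengths(aln, top, m)
        assert bhat[top.tip("A")] + bhat[top.tip("B")] < 1e-4


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(42)
    m = SubstitutionModel.lg(alpha=0.7, ncat=4)
    rec = SimulationRecipe(n_taxa=6, gene_length=1000, seed=4, alpha=0.7)
    tree = simulate_timetree(rec)
    rates = simulate_rates(tree, "ir", 0.1, 0.2, rng)
    aln, _ = simulate_alignment(tree, rates, m, rec, rng)
    surf = fit_approx_surface(aln, tree.topology, m)
    return aln, tree.topology, m, surf


class TestApproxSurface:
    def test_exact_at_the_expansion_point(self, toy):
        aln, top, m, surf = toy
        assert surf.loglik(surf.bhat) == pytest.approx(surf.ll0)

    def test_small_displacement_error_bounded(self, toy):
        """1% displacement per branch keeps |approx - exact| < 0.1 log units."""
        aln, top, m, surf = toy
        b1 = surf.bhat * 1.01
        bfull = np.zeros(top.n_nodes)
        bfull[surf.node_order] = b1
        assert abs(surf.loglik(b1) - exact_loglik(aln, top, bfull, m)) < 0.1

    def test_hessian_negative_semidefinite(self, toy):
        _, _, _, surf = toy
        assert np.linalg.eigvalsh(surf.hess).max() <= 1e-6

    def test_error_vanishes_superquadratically(self, toy):
        """The surface matches value, gradient and curvature at bhat, so the
        error must fall at least quadratically in the displacement (the
        observed decay is cubic, the leading neglected Taylor term)."""
        aln, top, m, surf = toy
        errs, steps = [], [0.005, 0.01, 0.02, 0.04]
        for f in steps:
            b1 = surf.bhat * (1 + f)
            bfull = np.zeros(top.n_nodes)
            bfull[surf.node_order] = b1
            errs.append(abs(surf.loglik(b1) - exact_loglik(aln, top, bfull, m)))
        slope = np.polyfit(np.log(steps), np.log(errs), 1)[0]
        assert 1.9 < slope < 3.5

    def test_negative_branch_length_is_minus_inf(self, toy):
        _, _, _, surf = toy
        b = surf.bhat.copy()
        b[0] = -0.01
        assert approx_loglik(surf, b) == -math.inf

    def test_hand_arithmetic_1d(self):
        surf = ApproxLikelihood([1], np.array([1.0]), np.array([0.0]), np.array([[-2.0]]), -5.0)
        assert surf.loglik(np.array([1.5])) == pytest.approx(-5.25)

    def test_json_roundtrip(self, toy):
        _, _, _, surf = toy
        back = ApproxLikelihood.from_json(surf.to_json())
        assert np.allclose(back.hess, surf.hess)
        assert back.loglik(surf.bhat * 1.01) == pytest.approx(surf.loglik(surf.bhat * 1.01))


class TestPartitions:
    def test_partition_file_parsing(self, tmp_path):
        p = tmp_path / "parts.txt"
        p.write_text("gene1 = 1-30\ngene2 = 31-50\n")
        assign = read_partition_file(p, 50)
        assert (assign[:30] == 0).all() and (assign[30:] == 1).all()

    def test_partitioned_likelihood_adds_up(self, rng):
        """k=1 equals the unpartitioned surface value; k=2 equals the sum of
        the two single-partition fits."""
        m = SubstitutionModel.lg(alpha=0.7, ncat=2)
        rec = SimulationRecipe(n_taxa=5, gene_length=200, n_genes=2, seed=5, alpha=0.7)
        tree = simulate_timetree(rec)
        rates = simulate_rates(tree, "ir", 0.1, 0.1, rng)
        aln, _ = simulate_alignment(tree, rates, m, rec, rng)
        top = tree.topology
        s_all = fit_approx_surface(Alignment(aln.taxa, aln.codes), top, m)
        s0 = fit_approx_surface(aln.subset(0), top, m)
        s1 = fit_approx_surface(aln.subset(1), top, m)
        b = s_all.bhat
        assert partition_loglik([s_all], [b]) == pytest.approx(s_all.loglik(b))
        assert partition_loglik([s0, s1], [s0.bhat, s1.bhat]) == pytest.approx(
            s0.ll0 + s1.ll0
        )

    def test_empty_partition_rejected(self, rng):
        aln = Alignment(["A", "B"], rng.integers(0, 20, (2, 10)).astype(np.int8),
                        np.zeros(10, dtype=int))
        with pytest.raises(ValueError, match="partition"):
            aln.subset(1)

    def test_per_partition_rate_ordering_recovered(self, rng):
        """Genes simulated at increasing rates give increasing MLE tree lengths."""
        m = SubstitutionModel.poisson()
        top = read_newick("((A,B),(C,D));")
        ages = np.zeros(top.n_nodes)
        ages[top.root] = 1.0
        for v in top.internal_nodes:
            if v != top.root:
                ages[v] = 0.5
        tree = TimeTree(top, ages)
        mults = [0.3, 0.6, 1.0, 1.7, 2.5]
        lengths = []
        for f in mults:
            rates = BranchRates("ir", np.full(top.n_nodes, 0.2 * f))
            rec = SimulationRecipe(n_taxa=4, gene_length=2000, seed=int(10 * f))
            aln, _ = simulate_alignment(tree, rates, m, rec, rng)
            bhat, _ = mle_branch_lengths(aln, top, m)
            lengths.append(bhat.sum())
        assert (np.diff(lengths) > 0).all()


class TestAlignmentIO:
    def test_fasta_roundtrip(self, tmp_path, rng):
        codes = rng.integers(0, 21, size=(3, 40)).astype(np.int8)
        aln = Alignment(["tax1", "tax2", "tax3"], codes)
        path = tmp_path / "a.fasta"
        aln.to_fasta(path)
        back = Alignment.from_fasta(path)
        assert back.taxa == aln.taxa
        assert np.array_equal(back.codes, aln.codes)

    def test_phylip_roundtrip(self, tmp_path, rng):
        codes = rng.integers(0, 20, size=(3, 25)).astype(np.int8)
        aln = Alignment(["some_long_taxon_name", "t2", "t3"], codes)
        path = tmp_path / "a.phy"
        aln.to_phylip(path)
        back = Alignment.from_phylip(path)
        assert back.taxa == aln.taxa
        assert np.array_equal(back.codes, aln.codes)

    def test_observed_freqs_smoothing(self):
        aln = Alignment(["A", "B"], np.zeros((2, 10), dtype=np.int8))
        f = aln.observed_freqs()
        assert f.sum() == pytest.approx(1.0)
        assert (f > 0).all()  # absent residues smoothed, no zeros

    def test_encode_handles_gaps_and_unknowns(self):
        codes = encode_sequence("AR-X?")
        assert codes[0] == 0 and codes[1] == 1
        assert (codes[2:] == 20).all()
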