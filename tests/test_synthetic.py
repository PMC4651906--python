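"""Synthetic-data generators and the reduced-scale study fixture."""

import math

import numpy as np
import pytest
from scipy import stats

from phyloclock.substitution import MISSING, SubstitutionModel
from phyloclock.synthetic import (
    SimulationRecipe,
    constrained_ages,
    make_study_fixture,
    simulate_alignment,
    simulate_rates,
    simulate_timetree,
)
from phyloclock.rate_models import BranchRates
from phyloclock.time_prior import BirthDeathParams
from phyloclock.trees import TimeTree, read_newick


class TestSimulateTimetree:
    def test_two_taxa_single_age(self):
        tree = simulate_timetree(SimulationRecipe(n_taxa=2, seed=1))
        assert tree.topology.n_tips == 2
        assert tree.root_age > 0

    def test_fixed_seed_reproducible(self):
        t1 = simulate_timetree(SimulationRecipe(n_taxa=10, seed=5))
        t2 = simulate_timetree(SimulationRecipe(n_taxa=10, seed=5))
        assert t1.topology.to_newick() == t2.topology.to_newick()
        assert np.array_equal(t1.ages, t2.ages)

    def test_uniform_kernel_node_ages(self):
        """birth = death, sampling -> 0, fixed root: internal ages uniform."""
        rng = np.random.default_rng(17)
        recipe = SimulationRecipe(
            n_taxa=6, seed=0, root_age_range=(8.0, 8.0), bd=BirthDeathParams(1, 1, 0)
        )
        ages = []
        for _ in range(2500):
            tree = simulate_timetree(recipe, rng=rng)
            top = tree.topology
            inner = [v for v in top.internal_nodes if v != top.root]
            ages.extend(tree.ages[inner] / 8.0)
        assert stats.kstest(np.array(ages), "uniform").statistic < 0.02

    def test_validates_ordering(self):
        tree = simulate_timetree(SimulationRecipe(n_taxa=15, seed=3))
        tree.validate()


class TestSimulateRates:
    def test_zero_variance_strict_clock(self, rng):
        tree = simulate_timetree(SimulationRecipe(n_taxa=6, seed=2))
        for clock in ["ir", "ar"]:
            rates = simulate_rates(tree, clock, 0.089, 0.0, rng)
            assert np.allclose(rates.rates, 0.089)

    def test_ar_star_variance_at_depth_five(self, rng):
        """Tip log-rate variance after 500 Myr equals 5 * nu (= 2.34)."""
        text = "(" + ",".join(f"T{i}" for i in range(400)) + ")r;"
        top = read_newick(text)
        ages = np.zeros(top.n_nodes)
        ages[top.root] = 5.0
        tree = TimeTree(top, ages)
        tips = [v for v in range(top.n_nodes) if top.is_tip[v]]
        draws = np.concatenate(
            [np.log(simulate_rates(tree, "ar", 0.089, 0.468, rng).rates[tips])
             for _ in range(250)]
        )
        assert draws.var() == pytest.approx(5 * 0.468, rel=0.02)

    def test_ir_mean_rate(self, rng):
        tree = simulate_timetree(SimulationRecipe(n_taxa=51, seed=4))
        nonroot = [v for v in range(tree.topology.n_nodes) if v != tree.topology.root]
        draws = np.concatenate(
            [simulate_rates(tree, "ir", 0.089, 0.468, rng).rates[nonroot]
             for _ in range(1000)]
        )
        assert draws.mean() == pytest.approx(0.089, rel=0.01)


class TestSimulateAlignment:
    def test_zero_length_tree_identical_sequences(self, rng):
        top = read_newick("((A,B),C);")
        ages = np.zeros(top.n_nodes)
        ages[top.root] = 1.0
        inner = [v for v in top.internal_nodes if v != top.root][0]
        ages[inner] = 0.5
        tree = TimeTree(top, ages)
        rates = BranchRates("ir", np.zeros(top.n_nodes))  # rate 0 -> b = 0
        m = SubstitutionModel.poisson()
        rec = SimulationRecipe(n_taxa=3, gene_length=200, seed=1)
        aln, _ = simulate_alignment(tree, rates, m, rec, rng)
        assert np.array_equal(aln.codes[0], aln.codes[1])
        assert np.array_equal(aln.codes[0], aln.codes[2])

    def test_site_rate_heterogeneity_ordering(self, rng):
        """Smaller gamma shape gives larger among-site substitution variance."""
        top = read_newick("(A,B);")
        ages = np.zeros(top.n_nodes)
        ages[top.root] = 1.0
        tree = TimeTree(top, ages)
        rates = BranchRates("ir", np.full(top.n_nodes, 0.25))
        rec = SimulationRecipe(n_taxa=2, gene_length=30_000, seed=2)
        spread = []
        for alpha in [0.5, 5.0]:
            m = SubstitutionModel.poisson(alpha=alpha, ncat=8)
            aln, _ = simulate_alignment(tree, rates, m, rec, np.random.default_rng(3))
            # chunk-wise difference fractions: heterogeneity inflates variance
            diff = (aln.codes[0] != aln.codes[1]).astype(float).reshape(-1, 100).mean(1)
            spread.append(diff.var())
        assert spread[0] > spread[1]

    def test_gene_wise_missingness(self, rng):
        rec = SimulationRecipe(n_taxa=6, n_genes=10, gene_length=50,
                               missing_fraction=0.3, seed=5)
        tree = simulate_timetree(rec)
        rates = simulate_rates(tree, "ir", 0.1, 0.1, rng)
        aln, _ = simulate_alignment(tree, rates, SubstitutionModel.poisson(), rec, rng)
        # missingness is whole-gene per taxon
        for tax in range(aln.n_taxa):
            for g in range(10):
                block = aln.codes[tax, aln.partitions == g]
                assert (block == MISSING).all() or (block != MISSING).all()
        assert 0.1 < aln.missing_fraction() < 0.5


def test_clock_model_choice_matters_under_rate_violation():
    """Echo of the clock-model sensitivity analysis: fitting IR vs AR to the
    same data yields nearly identical root ages when the clock is (almost)
    satisfied, but clearly divergent root ages when rate variation is
    severe — the disagreement between the two rate models grows with the
    degree of clock violation."""
    import warnings

    from phyloclock.calibrations import CalibrationBound
    from phyloclock.model import DivergenceTimeModel
    from phyloclock.rate_models import GammaPrior

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = SubstitutionModel.lg(alpha=0.7, ncat=2)
        rec = SimulationRecipe(n_taxa=8, gene_length=1000, seed=333, alpha=0.7,
                               root_age_range=(2.5, 3.5))
        tree = simulate_timetree(rec)
        top = tree.topology
        top.labels[top.root] = "Root"
        top._label_index["Root"] = top.root
        bounds = [CalibrationBound("Root", tree.root_age * 0.7, tree.root_age * 1.4)]
        gaps = {}
        for label, nu in [("near_clock", 0.02), ("violated", 0.8)]:
            rng = np.random.default_rng(334)
            rates = simulate_rates(tree, "ar", 0.1, nu, rng)
            aln, _ = simulate_alignment(tree, rates, m, rec, rng)
            means = {}
            for infer in ["ir", "ar"]:
                model = DivergenceTimeModel(
                    top, bounds, alignment=aln, clock=infer, subst_model=m,
                    mu_prior=GammaPrior(2.0, 20.0),
                )
                res = model.fit(iterations=5000, burnin=1000, thin=2, seed=335)
                means[infer] = res.summary().set_index("label").loc["Root", "mean"]
            gaps[label] = abs(means["ir"] - means["ar"])
    assert gaps["violated"] > gaps["near_clock"]


@pytest.fixture(scope="module")
def fixture():
    return make_study_fixture(seed=0)


class TestStudyFixture:
    def test_all_34_anchors_resolve(self, fixture):
        resolved = fixture.calibrations.resolve(fixture.topology)
        assert len(resolved) == 34

    def test_truth_ages_satisfy_every_hard_bound(self, fixture):
        by_node = fixture.calibrations.resolve(fixture.topology)
        for node, bound in by_node.items():
            age = fixture.tree.ages[node]
            assert age > bound.t_min
            if bound.t_max is not None:
                assert age < bound.t_max

    def test_scale_matches_recipe(self, fixture):
        assert fixture.alignment.n_sites == 4000
        assert fixture.alignment.n_partitions == 20
        assert 0.05 < fixture.alignment.missing_fraction() < 0.35
        assert fixture.topology.n_tips == 54

    def test_reproducible(self, fixture):
        again = make_study_fixture(seed=0)
        assert np.array_equal(again.alignment.codes, fixture.alignment.codes)
        assert np.array_equal(again.tree.ages, fixture.tree.ages)

    def test_write_bundle(self, fixture, tmp_path):
        fixture.write(tmp_path / "fx")
        for name in ["tree.nwk", "alignment.fasta", "calibrations.csv",
                     "partitions.txt", "truth.json", "timetree.nwk"]:
            assert (tmp_path / "fx" / name).exists()

    def test_constrained_ages_always_feasible(self, fixture, rng):
        for _ in range(20):
            ages = constrained_ages(fixture.topology, fixture.calibrations, rng)
            TimeTree(fixture.topology, ages).validate()
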