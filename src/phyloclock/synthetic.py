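"""Synthetic data with known truth, emulating the metazoan study at desk scale.

Generators for birth-death time trees, lognormal branch rates under either
relaxed clock, and multi-gene amino-acid alignments with heterogeneous gene
rates and gene-wise missing data.  ``make_study_fixture`` bundles them into
a reduced-scale analogue of the 54-taxon metazoan analysis: the packaged
54-taxon tree with clade labels, the 34-calibration table, IR branch rates,
and a 20-gene alignment (~4,000 sites, ~15% gene-wise missing data), with
the generating truth recorded for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .calibrations import CalibrationBound, CalibrationSet, build_strategy, load_calibration_table
from .rate_models import BranchRates
from .substitution import MISSING, Alignment, SubstitutionModel
from .time_prior import BirthDeathParams, bd_kernel_ppf
from .trees import TimeTree, Topology, read_newick

__all__ = [
    "SimulationRecipe",
    "simulate_timetree",
    "simulate_rates",
    "simulate_alignment",
    "constrained_ages",
    "prior_consistent_ages",
    "StudyFixture",
    "make_study_fixture",
    "load_packaged_topology",
    "load_packaged_calibrations",
    "load_sweep_topology",
]


@dataclass
class SimulationRecipe:
    """Settings for one synthetic dataset."""

    n_taxa: int = 8
    bd: BirthDeathParams = field(default_factory=BirthDeathParams)
    root_age_range: tuple[float, float] = (5.0, 8.0)  # 100 Myr units
    clock: str = "ir"
    mu: float = 0.05  # substitutions/site/100 Myr
    sigma2: float = 0.1  # log-variance (IR) or drift nu (AR)
    n_genes: int = 1
    gene_length: int = 500
    gene_rate_sd: float = 0.0  # sd of lognormal per-gene rate multipliers
    missing_fraction: float = 0.0
    alpha: float | None = None  # discrete-gamma shape (None = equal rates)
    ncat: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing fraction must be in [0, 1)")
        if self.n_genes < 1 or self.gene_length < 1:
            raise ValueError("gene counts and lengths must be positive")


def simulate_timetree(recipe: SimulationRecipe, rng: np.random.Generator | None = None) -> TimeTree:
    """Random time tree: root age uniform in the recipe's range, the other
    internal ages i.i.d. from the birth-death node-age kernel, tree shape by
    successive random joins (every labeled history equally likely).
    """
    rng = np.random.default_rng(recipe.seed) if rng is None else rng
    n = recipe.n_taxa
    t_root = rng.uniform(*recipe.root_age_range)
    inner = np.sort(
        [bd_kernel_ppf(rng.random(), t_root, recipe.bd) for _ in range(n - 2)]
    )
    node_ages = np.concatenate([inner, [t_root]])  # ascending, root last
    total = 2 * n - 1
    parent = [-1] * total
    labels: list[str | None] = [None] * total
    ages = np.zeros(total)
    for i in range(n):
        labels[i] = f"T{i + 1:02d}"
    active = list(range(n))
    nxt = n
    for t in node_ages:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        ages[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    # built with the root as the last node; Topology wants parent of root -1
    top = Topology(parent, labels)
    tree = TimeTree(top, ages)
    tree.validate()
    return tree


def simulate_rates(
    tree: TimeTree,
    clock: str,
    mu: float,
    sigma2: float,
    rng: np.random.Generator,
) -> BranchRates:
    """Draw branch rates under the IR or AR generative process.

    IR: i.i.d. lognormal branch rates with mean ``mu`` and log-variance
    ``sigma2``.  AR: node log-rates diffuse from ``log(mu)`` at the root
    with variance ``nu * dt`` and drift ``-nu * dt / 2`` (mean-preserving);
    the stored rates are node rates, branch rates being the mean of the
    endpoint rates.
    """
    top = tree.topology
    n = top.n_nodes
    if clock == "ir":
        if sigma2 == 0:
            r = np.full(n, mu)
        else:
            m = np.log(mu) - 0.5 * sigma2
            r = np.exp(rng.normal(m, np.sqrt(sigma2), size=n))
        r[top.root] = mu
        return BranchRates("ir", r)
    if clock != "ar":
        raise ValueError("clock must be 'ir' or 'ar'")
    x = np.zeros(n)
    x[top.root] = np.log(mu)
    for v in top.preorder:
        u = top.parent[v]
        if u == -1:
            continue
        dt = tree.ages[u] - tree.ages[v]
        s2 = sigma2 * dt
        x[v] = x[u] - 0.5 * s2 + (np.sqrt(s2) * rng.standard_normal() if s2 > 0 else 0.0)
    return BranchRates("ar", np.exp(x))


def simulate_alignment(
    tree: TimeTree,
    rates: BranchRates,
    model: SubstitutionModel,
    recipe: SimulationRecipe,
    rng: np.random.Generator,
) -> tuple[Alignment, np.ndarray]:
    """Simulate sites down the tree; returns (alignment, gene rate multipliers).

    Each gene gets a lognormal rate multiplier (mean 1); sites within a gene
    share it and draw a discrete-gamma category.  Missing data is applied
    gene-wise per taxon, mimicking supermatrix missingness.
    """
    top = tree.topology
    n_sites = recipe.n_genes * recipe.gene_length
    if recipe.gene_rate_sd > 0:
        g = rng.normal(-0.5 * recipe.gene_rate_sd**2, recipe.gene_rate_sd, recipe.n_genes)
        gene_mult = np.exp(g)
    else:
        gene_mult = np.ones(recipe.n_genes)
    gene_of_site = np.repeat(np.arange(recipe.n_genes), recipe.gene_length)
    cat_of_site = rng.integers(0, model.ncat, size=n_sites)
    site_rate = gene_mult[gene_of_site] * model.rates[cat_of_site]

    branch_rate = rates.branch_rates(top)
    durations = tree.branch_durations()
    states = np.empty((top.n_nodes, n_sites), dtype=np.int8)
    states[top.root] = rng.choice(20, size=n_sites, p=model.freqs)
    # group sites by (gene, category) so each branch needs few P matrices
    groups: dict[float, np.ndarray] = {}
    for key in np.unique(site_rate):
        groups[key] = np.nonzero(site_rate == key)[0]
    for v in top.preorder:
        u = top.parent[v]
        if u == -1:
            continue
        b = durations[v] * branch_rate[v]
        for r, idx in groups.items():
            P = model.pmat(b * r)
            cum = np.cumsum(P, axis=1)
            ps = states[u][idx]
            udraw = rng.random(len(idx))
            states[v][idx] = (cum[ps] < udraw[:, None]).sum(axis=1)
    tips = [v for v in range(top.n_nodes) if top.is_tip[v]]
    codes = states[tips].copy()
    taxa = [top.labels[v] for v in tips]
    if recipe.missing_fraction > 0:
        mask = rng.random((len(tips), recipe.n_genes)) < recipe.missing_fraction
        for i in range(len(tips)):
            for gidx in np.nonzero(mask[i])[0]:
                codes[i, gene_of_site == gidx] = MISSING
    return Alignment(taxa, codes, gene_of_site), gene_mult


def constrained_ages(
    top: Topology,
    cal: CalibrationSet,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ages satisfying ordering and every hard (min, max) bound pair.

    Top-down: the root uniform within its bounds, each internal node
    uniform between the largest calibration minimum among its descendants
    and the smaller of its own maximum and its parent's age.  The packaged
    metazoan bounds admit such a draw for every node.
    """
    by_node = cal.resolve(top)
    lower = np.zeros(top.n_nodes)
    for v in top.postorder:
        own = by_node[v].t_min if v in by_node and by_node[v].t_min else 0.0
        lower[v] = max([own] + [lower[c] for c in top.children[v]])
    ages = np.zeros(top.n_nodes)
    root = top.root
    rb = by_node.get(root)
    hi = rb.t_max if rb is not None and rb.t_max else lower[root] * 1.5
    ages[root] = rng.uniform(lower[root], hi)
    for v in top.preorder:
        if v == root or top.is_tip[v]:
            continue
        hi = ages[top.parent[v]]
        b = by_node.get(v)
        if b is not None and b.t_max is not None:
            hi = min(hi, b.t_max)
        lo = lower[v]
        if hi <= lo:
            raise ValueError(f"infeasible bounds at node {v}: [{lo}, {hi}]")
        ages[v] = rng.uniform(lo, hi)
    return ages


# ---------------------------------------------------------------------------
# packaged metazoan fixture
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("phyloclock.data").joinpath(name)


def load_packaged_topology() -> Topology:
    """The 54-taxon metazoan consensus topology with 34 labeled clades."""
    return read_newick(_data_path("metazoa_54.nwk").read_text())


def load_packaged_calibrations() -> list[CalibrationBound]:
    """The 34 fossil bounds (Table-style clade, min, max in Ma)."""
    import io

    return load_calibration_table(io.StringIO(_data_path("metazoa_calibrations.csv").read_text()))


def load_sweep_topology() -> tuple[Topology, dict]:
    """The 54-taxon topology with five uncertain nodes and its annotation.

    Four nodes are trichotomies (three local arrangements each) and one is
    annotated with two allowed arrangements, giving 3^4 x 2 = 162 binary
    resolutions.  The specific arrangements are illustrative stand-ins for
    the study's contested placements (Placozoa, Xenacoelomorpha,
    Chaetognatha, Mollusca, Nematoda).
    """
    top = read_newick(_data_path("metazoa_54_sweep.nwk").read_text())
    alts = json.loads(_data_path("metazoa_54_sweep_alternatives.json").read_text())
    alts = {k: [tuple(p) for p in v] for k, v in alts.items()}
    return top, alts


def prior_consistent_ages(
    top: Topology,
    cal: CalibrationSet,
    seed: int,
    bd: BirthDeathParams | None = None,
) -> np.ndarray:
    """A draw from the joint time prior that satisfies every hard bound.

    Runs a short prior-only chain and returns the latest retained state in
    which every calibrated node lies strictly inside its (min, max) pair —
    a rejection step over the soft tails, so the returned ages are
    representative of the prior while respecting the bounds exactly.
    """
    from .mcmc import McmcConfig, PriorModel, run_chain

    model = PriorModel(top, cal, bd or BirthDeathParams(1.0, 1.0, 0.0))
    trace = run_chain(
        model, McmcConfig(iterations=6000, burnin=1500, thin=5, seed=seed)
    )
    by_node = cal.resolve(top)
    for i in range(len(trace) - 1, -1, -1):
        ages = np.zeros(top.n_nodes)
        ages[trace.node_ids] = trace.ages[i]
        ok = True
        for v, b in by_node.items():
            if b.t_min is not None and ages[v] <= b.t_min:
                ok = False
                break
            if b.t_max is not None and ages[v] >= b.t_max:
                ok = False
                break
        if ok:
            return ages
    raise RuntimeError("no prior draw satisfied every hard bound")


@dataclass
class StudyFixture:
    """A reduced-scale synthetic analogue of the metazoan study."""

    topology: Topology
    tree: TimeTree  # truth
    calibrations: CalibrationSet  # strategy S1 on the 34 bounds
    alignment: Alignment
    gene_multipliers: np.ndarray
    rates: BranchRates  # truth
    mu: float
    sigma2: float
    seed: int

    def truth(self) -> dict:
        return {
            "seed": self.seed,
            "mu": self.mu,
            "sigma2": self.sigma2,
            "ages": self.tree.ages.tolist(),
            "gene_multipliers": self.gene_multipliers.tolist(),
        }

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(self.topology.to_newick() + "\n")
        (out / "timetree.nwk").write_text(self.tree.to_newick() + "\n")
        self.alignment.to_fasta(out / "alignment.fasta")
        with open(out / "partitions.txt", "w") as fh:
            parts = self.alignment.partitions
            for g in range(int(parts.max()) + 1):
                sites = np.nonzero(parts == g)[0]
                fh.write(f"gene{g + 1} = {sites.min() + 1}-{sites.max() + 1}\n")
        import shutil

        (out / "calibrations.csv").write_text(_data_path("metazoa_calibrations.csv").read_text())
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth(), fh, indent=1)


def make_study_fixture(
    seed: int = 0,
    n_genes: int = 20,
    gene_length: int = 200,
    mu: float = 0.089,
    sigma2: float = 0.468,
    missing_fraction: float = 0.15,
    alpha: float = 0.7,
    ncat: int = 4,
    gene_rate_sd: float = 0.7,
) -> StudyFixture:
    """Simulate the study-like bundle on the packaged 54-taxon topology.

    Truth ages are drawn to satisfy every strategy-S1 hard bound pair; IR
    branch rates use the study-scale mean rate and log-variance; the
    alignment is LG + discrete-gamma with per-gene rate multipliers and
    gene-wise missing data.
    """
    rng = np.random.default_rng(seed)
    top = load_packaged_topology()
    bounds = load_packaged_calibrations()
    cal = build_strategy(bounds, "S1")
    ages = prior_consistent_ages(top, cal, seed=seed + 1)
    tree = TimeTree(top, ages)
    tree.validate()
    rates = simulate_rates(tree, "ir", mu, sigma2, rng)
    model = SubstitutionModel.lg(alpha=alpha, ncat=ncat)
    recipe = SimulationRecipe(
        n_taxa=top.n_tips,
        n_genes=n_genes,
        gene_length=gene_length,
        gene_rate_sd=gene_rate_sd,
        missing_fraction=missing_fraction,
        alpha=alpha,
        ncat=ncat,
        seed=seed,
        mu=mu,
        sigma2=sigma2,
    )
    aln, gene_mult = simulate_alignment(tree, rates, model, recipe, rng)
    return StudyFixture(
        topology=top,
        tree=tree,
        calibrations=cal,
        alignment=aln,
        gene_multipliers=gene_mult,
        rates=rates,
        mu=mu,
        sigma2=sigma2,
        seed=seed,
    )
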