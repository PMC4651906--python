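"""Amino-acid sequence likelihood and its quadratic approximation.

The exact likelihood is the standard pruning algorithm over sites under an
empirical exchangeability matrix (LG shipped as package data; a Poisson
equal-rates matrix is included for closed-form checks) with discrete-gamma
rate variation and "+F" observed frequencies.  For dating, the likelihood
is replaced by its second-order Taylor expansion around the maximum
likelihood branch lengths: ``l(b) ~ l(bhat) + g'(b - bhat) + (b - bhat)'H(b -
bhat)/2``, where the gradient g is computed analytically by a two-pass
(post-order/pre-order) sweep and the Hessian H by central finite
differences of that gradient.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio import AlignIO, SeqIO
from scipy import optimize
from scipy.special import gammainc, logsumexp

from .trees import Topology

__all__ = [
    "AA_ORDER",
    "SubstitutionModel",
    "Alignment",
    "ApproxLikelihood",
    "exact_loglik",
    "exact_loglik_and_gradient",
    "mle_branch_lengths",
    "fit_approx_surface",
    "approx_loglik",
    "partition_loglik",
    "read_partition_file",
]

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_CODE = {a: i for i, a in enumerate(AA_ORDER)}
MISSING = 20


def _load_lg():
    text = resources.files("phyloclock.data").joinpath("lg.tsv").read_text()
    rows, freqs = [], None
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#freq"):
            freqs = np.array([float(x) for x in line.split("\t")[1:]])
        elif not line.startswith("#"):
            rows.append([float(x) for x in line.split("\t")])
    S = np.zeros((20, 20))
    for i, row in enumerate(rows, start=1):
        S[i, : len(row)] = row
    S = S + S.T
    return S, freqs / freqs.sum()


def discrete_gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability discrete-gamma categories.

    The gamma has shape ``alpha`` and mean 1; each category's rate is the
    conditional mean within its probability bin, so the rates average to 1.
    """
    if ncat == 1:
        return np.ones(1)
    from scipy.stats import gamma as gamma_dist

    edges = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), alpha, scale=1.0 / alpha)
    # E[X; X in bin] for Gamma(shape a, rate a) uses the shape a+1 CDF
    upper = gammainc(alpha + 1.0, alpha * edges[1:])
    upper[-1] = 1.0
    lower = gammainc(alpha + 1.0, alpha * edges[:-1])
    rates = ncat * (upper - lower)
    return rates / rates.mean()


class SubstitutionModel:
    """Time-reversible amino-acid model: exchangeabilities + frequencies + gamma.

    The rate matrix is ``Q_ij = s_ij * pi_j`` (i != j), normalized so the
    expected rate at stationarity is one substitution per site per unit
    branch length.
    """

    def __init__(self, exchangeabilities, freqs, alpha: float | None = None, ncat: int = 4):
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(freqs, dtype=float)
        pi = pi / pi.sum()
        if (pi <= 0).any():
            raise ValueError("stationary frequencies must be positive")
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -(pi * np.diag(Q)).sum()
        Q /= mean_rate
        self.exchangeabilities = S
        self.freqs = pi
        self.Q = Q
        self.alpha = alpha
        self.ncat = ncat if alpha is not None else 1
        self.rates = (
            discrete_gamma_rates(alpha, self.ncat) if alpha is not None else np.ones(1)
        )
        # symmetric decomposition: B = D^1/2 Q D^-1/2 = V L V'
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2.0)
        self.eigval = lam
        self._left = V * d[:, None]  # D^1/2 V ; P(t) = D^-1/2 V e^{Lt} V' D^1/2
        self._right = (V / d[:, None]).T  # rows: V' D^... so P = right.T? see pmat

    def pmat(self, t: float) -> np.ndarray:
        """Transition matrix P(t) = exp(Qt)."""
        e = np.exp(self.eigval * max(t, 0.0))
        # P = D^-1/2 V e V' D^1/2
        return (self._right.T * e[None, :]) @ self._left.T

    def pmats(self, ts: np.ndarray) -> np.ndarray:
        """Batch of transition matrices for an array of branch lengths."""
        ts = np.maximum(np.asarray(ts, dtype=float), 0.0)
        e = np.exp(np.multiply.outer(ts, self.eigval))  # (..., 20)
        return np.einsum("ik,...k,jk->...ij", self._right.T, e, self._left)

    def dpmat(self, t: float) -> np.ndarray:
        """dP/dt = Q P(t)."""
        e = self.eigval * np.exp(self.eigval * max(t, 0.0))
        return (self._right.T * e[None, :]) @ self._left.T

    @classmethod
    def lg(cls, freqs=None, alpha: float | None = None, ncat: int = 4) -> "SubstitutionModel":
        """LG model; pass observed frequencies for "+F"."""
        S, pi = _load_lg()
        return cls(S, pi if freqs is None else freqs, alpha=alpha, ncat=ncat)

    @classmethod
    def poisson(cls, alpha: float | None = None, ncat: int = 4) -> "SubstitutionModel":
        """Equal exchangeabilities, equal frequencies (analytic test model)."""
        S = np.ones((20, 20)) - np.eye(20)
        return cls(S, np.full(20, 0.05), alpha=alpha, ncat=ncat)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def encode_sequence(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, MISSING) for c in seq.upper()], dtype=np.int8)


def decode_sequence(codes) -> str:
    return "".join(AA_ORDER[c] if c < MISSING else "-" for c in codes)


@dataclass
class Alignment:
    """Amino-acid alignment with optional per-site partition assignment."""

    taxa: list[str]
    codes: np.ndarray  # (n_taxa, n_sites) int8, 20 = missing/gap
    partitions: np.ndarray | None = None  # (n_sites,) int partition ids

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise ValueError("codes must be (n_taxa, n_sites)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if self.partitions is not None:
            self.partitions = np.asarray(self.partitions, dtype=int)
            if self.partitions.shape != (self.codes.shape[1],):
                raise ValueError("partition assignment length mismatch")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @property
    def n_partitions(self) -> int:
        return 1 if self.partitions is None else int(self.partitions.max()) + 1

    def subset(self, part: int) -> "Alignment":
        if self.partitions is None:
            if part != 0:
                raise ValueError("alignment has a single partition")
            return Alignment(self.taxa, self.codes)
        mask = self.partitions == part
        if not mask.any():
            raise ValueError(f"partition {part} is empty")
        return Alignment(self.taxa, self.codes[:, mask])

    def observed_freqs(self, smoothing: float = 1.0) -> np.ndarray:
        """Observed residue frequencies with add-``smoothing`` counts."""
        counts = np.bincount(self.codes[self.codes < MISSING].ravel(), minlength=20)
        counts = counts.astype(float) + smoothing
        return counts / counts.sum()

    def missing_fraction(self) -> float:
        return float((self.codes == MISSING).mean())

    @classmethod
    def from_fasta(cls, path, partitions=None) -> "Alignment":
        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(encode_sequence(str(rec.seq)))
        if not taxa:
            raise ValueError(f"no sequences in {path}")
        if len({len(r) for r in rows}) != 1:
            raise ValueError("sequences have unequal lengths")
        return cls(taxa, np.vstack(rows), partitions)

    @classmethod
    def from_phylip(cls, path, partitions=None) -> "Alignment":
        aln = AlignIO.read(str(path), "phylip-relaxed")
        taxa = [rec.id for rec in aln]
        rows = [encode_sequence(str(rec.seq)) for rec in aln]
        return cls(taxa, np.vstack(rows), partitions)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, row in zip(self.taxa, self.codes):
                fh.write(f">{t}\n{decode_sequence(row)}\n")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f" {self.n_taxa} {self.n_sites}\n")
            for t, row in zip(self.taxa, self.codes):
                fh.write(f"{t}  {decode_sequence(row)}\n")


def read_partition_file(path, n_sites: int) -> np.ndarray:
    """Parse ``name = start-end`` lines (1-based inclusive) into site ids."""
    assignment = np.full(n_sites, -1, dtype=int)
    names = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, rng = line.partition("=")
            lo, _, hi = rng.strip().partition("-")
            i, j = int(lo), int(hi)
            if not (1 <= i <= j <= n_sites):
                raise ValueError(f"partition range {i}-{j} outside 1..{n_sites}")
            assignment[i - 1 : j] = len(names)
            names.append(name.strip())
    if (assignment < 0).any():
        raise ValueError("partition file leaves sites unassigned")
    return assignment


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------


def _check_taxa(aln: Alignment, top: Topology) -> list[int]:
    """Tip node id for each alignment row."""
    tips = set(top.tip_labels)
    if set(aln.taxa) != tips:
        missing = tips - set(aln.taxa)
        extra = set(aln.taxa) - tips
        raise ValueError(
            f"alignment/tree taxa mismatch (missing: {sorted(missing)[:5]}, "
            f"extra: {sorted(extra)[:5]})"
        )
    return [top.tip(t) for t in aln.taxa]


class _PatternData:
    """Site-pattern-compressed alignment columns for one partition."""

    def __init__(self, aln: Alignment, top: Topology):
        order = _check_taxa(aln, top)
        cols = aln.codes.T  # (n_sites, n_taxa)
        patterns, inverse, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True
        )
        self.weights = counts.astype(float)
        self.inverse = inverse
        # per tree-tip node id -> pattern codes
        self.tip_codes = {}
        for row_idx, node in enumerate(order):
            self.tip_codes[node] = patterns[:, row_idx].astype(np.intp)
        self.n_patterns = patterns.shape[0]


def _tip_message(P: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Message from a tip through branch matrix P: (npat, 20)."""
    # P has shape (K, 20, 20); result (npat, K, 20)
    msg = P[:, :, :].transpose(0, 2, 1)  # (K, 20state_child, 20state_parent)
    out = msg[:, np.minimum(codes, 19), :]  # (K, npat, 20)
    out = out.transpose(1, 0, 2).copy()
    out[codes == MISSING] = 1.0
    return out


class _Pruner:
    """Reusable pruning workspace for one partition on a fixed topology.

    Partials are stored per node id; transition matrices for all branches
    and gamma categories are built in one batched pass.  The gradient uses
    the standard two-sweep scheme: a post-order pass storing the scaled
    below-branch partials, then a pre-order pass propagating the flow from
    the root and contracting each edge with dP/db = Q P.
    """

    #: numerical floor on branch lengths inside the pruning pass; avoids
    #: exactly-zero partials (and undefined gradients) when a zero-length
    #: branch separates conflicting residues
    BL_FLOOR = 1e-8

    def __init__(self, aln: Alignment, top: Topology, model: SubstitutionModel):
        self.top = top
        self.model = model
        self.data = _PatternData(aln, top)
        self.nonroot = [v for v in range(top.n_nodes) if top.parent[v] != -1]
        self.node_index = {v: i for i, v in enumerate(self.nonroot)}
        npat = self.data.n_patterns
        # tip partials are category-independent one-hot rows (missing = all 1)
        self._tip_partial: dict[int, np.ndarray] = {}
        for v, codes in self.data.tip_codes.items():
            L = np.zeros((npat, 20))
            ok = codes < MISSING
            rows = np.nonzero(ok)[0]
            L[rows, codes[rows]] = 1.0
            L[~ok] = 1.0
            self._tip_partial[v] = L

    def _pmats(self, b: np.ndarray, derivative: bool = False):
        """Batched transition matrices: arrays (n_nodes, K, 20, 20)."""
        m = self.model
        n = self.top.n_nodes
        ts = np.maximum(b, self.BL_FLOOR)[:, None] * m.rates[None, :]  # (n, K)
        e = np.exp(ts[:, :, None] * m.eigval[None, None, :])  # (n, K, 20)
        A = m._right.T  # (20, 20); P = (A * e) @ left.T
        P = (A[None, None] * e[:, :, None, :]) @ m._left.T
        if not derivative:
            return P, None
        ed = e * (m.eigval[None, None, :] * m.rates[None, :, None])
        dP = (A[None, None] * ed[:, :, None, :]) @ m._left.T
        return P, dP

    def _msg(self, v: int, P: np.ndarray, part, scal):
        """Message through the branch above v: (K, npat, 20) plus scaler."""
        if self.top.is_tip[v]:
            # (1, npat, 20) @ (K, 20, 20) broadcasts over categories
            return np.matmul(self._tip_partial[v][None], P[v].transpose(0, 2, 1)), None
        return np.matmul(part[v], P[v].transpose(0, 2, 1)), scal[v]

    def _down(self, b: np.ndarray, P: np.ndarray, keep: bool):
        """Post-order pass; returns (loglik, site_ll, partials, scalers).

        Partials and messages are laid out (K, npat, 20); scalers (K, npat)
        accumulate per-pattern log rescaling factors.
        """
        top, m, data = self.top, self.model, self.data
        part: dict[int, np.ndarray] = {}
        scal: dict[int, np.ndarray] = {}
        for v in top.postorder:
            if top.is_tip[v]:
                continue
            L = None
            c = None
            for w in top.children[v]:
                msg, cw = self._msg(w, P, part, scal)
                L = msg if L is None else L * msg
                if cw is not None:
                    c = cw if c is None else c + cw
                if not keep and not top.is_tip[w]:
                    part.pop(w, None)
                    scal.pop(w, None)
            mx = np.maximum(L.max(axis=2), 1e-300)
            L = L / mx[:, :, None]
            c = np.log(mx) if c is None else c + np.log(mx)
            part[v] = L
            scal[v] = c
        root_L, root_c = part[top.root], scal[top.root]
        lik = root_L @ m.freqs  # (K, npat)
        site_ll = logsumexp(np.log(np.maximum(lik, 1e-300)) + root_c, axis=0) - np.log(
            m.ncat
        )
        ll = float(site_ll @ data.weights)
        return ll, site_ll, part, scal

    def loglik(self, b: np.ndarray) -> float:
        P, _ = self._pmats(b)
        ll, _, _, _ = self._down(b, P, keep=False)
        return ll

    def loglik_and_gradient(self, b: np.ndarray) -> tuple[float, np.ndarray]:
        """Analytic gradient by a pre-order pass over the scaled partials."""
        top, m, data = self.top, self.model, self.data
        K = m.ncat
        npat = data.n_patterns
        P, dP = self._pmats(b, derivative=True)
        ll, site_ll, part, scal = self._down(b, P, keep=True)
        logK = np.log(K)
        grad = np.zeros(top.n_nodes)
        w8 = data.weights
        U = {top.root: np.broadcast_to(m.freqs, (K, npat, 20))}
        uc = {top.root: np.zeros((K, npat))}
        for v in top.preorder:
            if top.is_tip[v]:
                continue
            kids = top.children[v]
            msgs_k = {w: self._msg(w, P, part, scal) for w in kids}
            for w in kids:
                A = U[v]
                ac = uc[v]
                for s in kids:
                    if s is not w:
                        ms, cs = msgs_k[s]
                        A = A * ms
                        if cs is not None:
                            ac = ac + cs
                AdP = np.matmul(A, dP[w])  # (K, npat, 20)
                if top.is_tip[w]:
                    inner = (AdP * self._tip_partial[w][None]).sum(axis=2)
                    cw = 0.0
                else:
                    inner = (AdP * part[w]).sum(axis=2)
                    cw = scal[w]
                lw = ac + cw - site_ll[None, :] - logK
                grad[w] = float((np.exp(lw) * inner).sum(axis=0) @ w8)
                if not top.is_tip[w]:
                    Unew = np.matmul(A, P[w])
                    mx = np.maximum(np.abs(Unew).max(axis=2), 1e-300)
                    U[w] = Unew / mx[:, :, None]
                    uc[w] = ac + np.log(mx)
            U.pop(v, None)
            uc.pop(v, None)
        return ll, grad


def exact_loglik(aln: Alignment, top: Topology, b: np.ndarray, m: SubstitutionModel) -> float:
    """Pruning log-likelihood; ``b`` indexed by node id (root entry ignored).

    Gaps and unknown residues are fully ambiguous; sites are weighted by
    pattern multiplicity.
    """
    b = np.asarray(b, dtype=float)
    if (b[[v for v in range(top.n_nodes) if top.parent[v] != -1]] < 0).any():
        raise ValueError("negative branch length")
    return _Pruner(aln, top, m).loglik(b)


def exact_loglik_and_gradient(aln, top, b, m):
    return _Pruner(aln, top, m).loglik_and_gradient(np.asarray(b, dtype=float))


# ---------------------------------------------------------------------------
# branch-length MLE and the quadratic surface
# ---------------------------------------------------------------------------


def mle_branch_lengths(
    aln: Alignment,
    top: Topology,
    m: SubstitutionModel,
    b0: np.ndarray | None = None,
    gtol: float = 1e-6,
    maxiter: int = 500,
) -> tuple[np.ndarray, float]:
    """Maximize the pruning likelihood over branch lengths (b >= 0).

    Returns the per-node branch length vector (root entry 0) and the
    log-likelihood at the optimum.  Warns if the projected gradient norm
    exceeds ``gtol`` after ``maxiter`` iterations.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    pruner = _Pruner(aln, top, m)
    nonroot = pruner.nonroot
    x0 = np.full(len(nonroot), 0.1) if b0 is None else np.asarray(b0, float)[nonroot]

    def negf(x):
        b = np.zeros(top.n_nodes)
        b[nonroot] = x
        ll, grad = pruner.loglik_and_gradient(b)
        return -ll, -grad[nonroot]

    res = optimize.minimize(
        negf,
        np.maximum(x0, 1e-6),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * len(nonroot),
        options={"maxiter": maxiter, "ftol": 1e-14, "gtol": gtol},
    )
    b = np.zeros(top.n_nodes)
    b[nonroot] = res.x
    _, g = negf(res.x)
    pg = _projected_gradient(res.x, -g)
    if not res.success or np.abs(pg).max() > 1e-2:
        warnings.warn(
            f"branch-length MLE not fully converged after {res.nit} iterations: "
            f"max projected gradient {np.abs(pg).max():.2e}",
            RuntimeWarning,
        )
    return b, float(-res.fun)


def _projected_gradient(x, g):
    """Gradient with components pointing outside b >= 0 removed."""
    pg = g.copy()
    pg[(x <= 1e-10) & (g < 0)] = 0.0
    return pg


@dataclass
class ApproxLikelihood:
    """Quadratic log-likelihood surface around the branch-length MLE."""

    node_order: list[int]  # non-root node ids, fixing the branch order
    bhat: np.ndarray
    grad: np.ndarray
    hess: np.ndarray
    ll0: float

    def __post_init__(self):
        n = len(self.node_order)
        self.bhat = np.asarray(self.bhat, float)
        self.grad = np.asarray(self.grad, float)
        self.hess = np.asarray(self.hess, float)
        if self.grad.shape != (n,) or self.hess.shape != (n, n):
            raise ValueError("gradient/Hessian dimensions do not match branches")
        if not np.allclose(self.hess, self.hess.T, atol=1e-8):
            raise ValueError("Hessian must be symmetric")

    def loglik(self, b: np.ndarray) -> float:
        """Quadratic approximation at branch lengths ``b`` (branch order)."""
        b = np.asarray(b, dtype=float)
        if (b < 0).any():
            return -np.inf
        d = b - self.bhat
        return float(self.ll0 + self.grad @ d + 0.5 * d @ self.hess @ d)

    def to_json(self) -> str:
        return json.dumps(
            {
                "node_order": list(map(int, self.node_order)),
                "bhat": self.bhat.tolist(),
                "grad": self.grad.tolist(),
                "hess": self.hess.tolist(),
                "ll0": self.ll0,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ApproxLikelihood":
        d = json.loads(text)
        return cls(
            d["node_order"],
            np.array(d["bhat"]),
            np.array(d["grad"]),
            np.array(d["hess"]),
            float(d["ll0"]),
        )


def fit_approx_surface(
    aln: Alignment,
    top: Topology,
    m: SubstitutionModel,
    b0: np.ndarray | None = None,
    rel_step: float = 1e-4,
    abs_floor: float = 1e-6,
) -> ApproxLikelihood:
    """MLE branch lengths plus gradient/Hessian of the log-likelihood there.

    The gradient is analytic; the Hessian uses central finite differences of
    the gradient with per-branch step ``max(rel_step * bhat_i, abs_floor)``.
    Branches estimated at the zero boundary fall back to one-sided (forward)
    differences, with a warning.
    """
    bhat, ll0 = mle_branch_lengths(aln, top, m, b0=b0)
    pruner = _Pruner(aln, top, m)
    nonroot = pruner.nonroot
    n = len(nonroot)

    def grad_at(x):
        b = np.zeros(top.n_nodes)
        b[nonroot] = x
        return pruner.loglik_and_gradient(b)[1][nonroot]

    x = bhat[nonroot]
    g = grad_at(x)
    H = np.zeros((n, n))
    boundary = x <= abs_floor
    if boundary.any():
        warnings.warn(
            f"{int(boundary.sum())} branch length(s) at the zero boundary; "
            "using one-sided differences for those rows",
            RuntimeWarning,
        )
    for i in range(n):
        h = max(rel_step * x[i], abs_floor)
        if boundary[i]:
            gp = grad_at(_bump(x, i, h))
            H[i] = (gp - g) / h
        else:
            h = min(h, x[i])  # keep b >= 0
            gp = grad_at(_bump(x, i, h))
            gm = grad_at(_bump(x, i, -h))
            H[i] = (gp - gm) / (2.0 * h)
    H = (H + H.T) / 2.0
    return ApproxLikelihood(nonroot, x, g, H, ll0)


def _bump(x, i, h):
    y = x.copy()
    y[i] += h
    return y


def approx_loglik(al: ApproxLikelihood, b: np.ndarray) -> float:
    """Evaluate the quadratic surface; -inf for any negative branch length."""
    return al.loglik(b)


def partition_loglik(surfaces: list[ApproxLikelihood], bs: list[np.ndarray]) -> float:
    """Sum of independent per-partition approximate log-likelihoods."""
    if len(surfaces) != len(bs):
        raise ValueError("one branch-length vector per partition required")
    return float(sum(s.loglik(b) for s, b in zip(surfaces, bs)))
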