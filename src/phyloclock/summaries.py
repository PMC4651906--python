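"""Posterior/prior summarization and cross-analysis statistics.

Provides the 95% HPD interval (shortest interval by a sorted-sample sweep),
per-node summary tables, the infinite-sites regression of HPD width on
posterior mean (whose slope measures the calibration-driven uncertainty no
amount of sequence data can remove), composite intervals across analyses,
and rate-ordered gene partitioning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .substitution import Alignment, SubstitutionModel, mle_branch_lengths
from .trees import Topology

__all__ = [
    "NodeSummary",
    "hpd_interval",
    "summarize_trace",
    "infinite_sites_regression",
    "composite_interval",
    "partition_genes_by_rate",
    "poisson_distance",
]


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the samples.

    Computed by sweeping a fixed-count window over the sorted sample
    (deterministic; no density estimation).
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2:
        return (float(x[0]), float(x[0])) if n else (math.nan, math.nan)
    m = max(1, int(math.ceil(mass * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


@dataclass
class NodeSummary:
    """Posterior (or prior) summary of one node age."""

    node: int
    label: str
    mean: float
    hpd_lower: float
    hpd_upper: float

    @property
    def width(self) -> float:
        return self.hpd_upper - self.hpd_lower


def summarize_trace(trace, mass: float = 0.95, unit: float = 100.0) -> pd.DataFrame:
    """Per-node mean and HPD table from an McmcTrace (ages reported in Ma)."""
    rows = []
    for i, (node, label) in enumerate(zip(trace.node_ids, trace.labels)):
        col = trace.ages[:, i] * unit
        lo, hi = hpd_interval(col, mass)
        rows.append(
            {
                "node": node,
                "label": label,
                "mean": col.mean(),
                "hpd_lower": lo,
                "hpd_upper": hi,
                "width": hi - lo,
            }
        )
    return pd.DataFrame(rows)


def summaries_from_frame(df: pd.DataFrame) -> list[NodeSummary]:
    return [
        NodeSummary(int(r.node), str(r.label), float(r.mean), float(r.hpd_lower), float(r.hpd_upper))
        for r in df.itertuples()
    ]


def infinite_sites_regression(summaries) -> tuple[float, float]:
    """Through-origin regression of 95% HPD width on posterior mean age.

    Returns (slope, R^2).  The slope is the "regression coefficient" of the
    infinite-sites plot: the proportionality between age and irreducible
    uncertainty left by the calibrations.  R^2 is computed about the
    through-origin fit (1 - SS_res / SS_uncentered).
    """
    if isinstance(summaries, pd.DataFrame):
        means = summaries["mean"].to_numpy(dtype=float)
        widths = summaries["width"].to_numpy(dtype=float)
    else:
        means = np.array([s.mean for s in summaries], dtype=float)
        widths = np.array([s.width for s in summaries], dtype=float)
    if len(means) < 3:
        raise ValueError("need at least 3 nodes")
    denom = float(means @ means)
    if denom == 0:
        raise ValueError("all posterior means are zero")
    slope = float(widths @ means) / denom
    resid = widths - slope * means
    ss_tot = float(widths @ widths)
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else math.nan
    return slope, r2


def composite_interval(intervals) -> tuple[float, float]:
    """Envelope of HPD intervals across analyses: (min lower, max upper)."""
    intervals = list(intervals)
    if not intervals:
        raise ValueError("empty interval list")
    return (
        min(lo for lo, _ in intervals),
        max(hi for _, hi in intervals),
    )


def composite_table(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-node composite intervals across several summary tables."""
    base = frames[0][["node", "label"]].copy()
    lowers = np.min([f["hpd_lower"].to_numpy() for f in frames], axis=0)
    uppers = np.max([f["hpd_upper"].to_numpy() for f in frames], axis=0)
    base["hpd_lower"] = lowers
    base["hpd_upper"] = uppers
    base["width"] = uppers - lowers
    return base


# ---------------------------------------------------------------------------
# rate-ordered gene partitioning
# ---------------------------------------------------------------------------


def poisson_distance(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """Pairwise ML distance under the Poisson (equal-rates) model.

    With p the differing fraction over shared non-missing sites,
    ``d = -(19/20) ln(1 - (20/19) p)``; saturated pairs get +inf.
    """
    ok = (codes_a < 20) & (codes_b < 20)
    n = int(ok.sum())
    if n == 0:
        return math.nan
    p = float((codes_a[ok] != codes_b[ok]).mean())
    if p >= 19.0 / 20.0:
        return math.inf
    return -(19.0 / 20.0) * math.log(1.0 - (20.0 / 19.0) * p)


def partition_genes_by_rate(
    genes: list[Alignment],
    taxon_a: str,
    taxon_b: str,
    k: int,
) -> np.ndarray:
    """Assign genes to ``k`` rate classes by the pairwise distance between
    two reference taxa (slow genes first), in near-equal-count groups.

    Genes lacking either taxon are ranked by their mean pairwise distance
    instead (with a warning).  Returns the partition id per gene.
    """
    import warnings

    if k < 1 or k > len(genes):
        raise ValueError(f"k must be in 1..{len(genes)}")
    dists = np.empty(len(genes))
    for g, aln in enumerate(genes):
        if taxon_a in aln.taxa and taxon_b in aln.taxa:
            ia, ib = aln.taxa.index(taxon_a), aln.taxa.index(taxon_b)
            dists[g] = poisson_distance(aln.codes[ia], aln.codes[ib])
        else:
            warnings.warn(
                f"gene {g} lacks {taxon_a!r} or {taxon_b!r}; using mean "
                "pairwise distance for ranking",
                RuntimeWarning,
            )
            pairs = [
                poisson_distance(aln.codes[i], aln.codes[j])
                for i in range(aln.n_taxa)
                for j in range(i + 1, aln.n_taxa)
            ]
            dists[g] = float(np.nanmean(pairs))
    order = np.argsort(dists, kind="stable")
    assignment = np.empty(len(genes), dtype=int)
    sizes = [len(chunk) for chunk in np.array_split(order, k)]
    start = 0
    for part, size in enumerate(sizes):
        assignment[order[start : start + size]] = part
        start += size
    return assignment
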