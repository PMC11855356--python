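"""Triplet internal-branch mixture analysis (ILS vs introgression).

For a three-taxon subset of a gene-tree sample, the internal branch of
each gene tree's triplet restriction is informative about process: under
pure ILS the internal branches of a *discordant* triplet topology are
exponentially distributed, while introgression (or, on the concordant
topology, speciation) adds a sub-population of branches displaced by a
fixed waiting time delta.  Per topology class we therefore fit

    f(x) = pi1 * Exp(x; theta) + pi2 * Exp(x - delta; theta),  pi1 + pi2 = 1

by EM (both components share the scale theta; component 2 has support
x >= delta) and compare it against the single-exponential ILS-only model
with BIC.  Strongly negative delta-BIC (default threshold -30) on a
discordant class is called as introgression, and pi2 measures how much of
that class the second process explains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .treekit import TreeError, bipartitions, leaf_labels, restrict_tree

__all__ = [
    "TripletBranchData",
    "MixtureFit",
    "TripletFit",
    "extract_triplet_branches",
    "fit_ils_only",
    "fit_mixture_em",
    "fit_triplet_classes",
    "call_introgression",
    "pi2_heatmap",
    "fits_table",
]

logger = logging.getLogger(__name__)

DELTA_BIC_THRESHOLD = -30.0
EM_NUMSTEPS = 50
EM_LIKELIHOODTHRESH = 0.01
EM_GRADASCENTSCALAR = 0.5
MIN_CLASS_SIZE = 5


@dataclass
class TripletBranchData:
    """Per-topology-class internal branch lengths for one triplet.

    Classes are keyed by the sister pair (frozenset of two labels); the
    third taxon is the odd one out.  Zero-length and unresolved
    restrictions are tallied but excluded from the length lists.
    """

    triplet: tuple[str, str, str]
    lengths: dict[frozenset, list[float]] = field(default_factory=dict)
    n_unresolved: int = 0
    n_zero: int = 0
    n_skipped: int = 0

    def counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.lengths.items()}

    @staticmethod
    def class_label(pair: frozenset, triplet: Sequence[str]) -> str:
        a, b = sorted(pair)
        (c,) = set(triplet) - pair
        return f"{a},{b}|{c}"


def _quartet_internal_branch(
    tree: dendropy.Tree, trio: Sequence[str], outgroup: str
) -> tuple[frozenset | None, float | None]:
    """Sister pair and internal branch length of the triplet restriction,
    rooted by the outgroup.  Returns (None, None) when unresolved."""
    taxa = set(trio) | {outgroup}
    sub = restrict_tree(tree, taxa)
    splits = bipartitions(sub)
    if not splits:
        return None, None
    (split,) = splits
    pair = split.side_b if outgroup in split.side_a else split.side_a
    # patristic identity: 2e = d(Y,X) + d(Z,O) - d(Y,Z) - d(X,O)
    depth: dict[str, float] = {}
    node_depth: dict[dendropy.Node, float] = {sub.seed_node: 0.0}
    anc: dict[str, list[dendropy.Node]] = {}
    for node in sub.preorder_node_iter():
        if node.parent_node is not None:
            node_depth[node] = node_depth[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            chain, p = [], node
            while p is not None:
                chain.append(p)
                p = p.parent_node
            anc[node.taxon.label] = chain
            depth[node.taxon.label] = node_depth[node]

    def dist(u: str, v: str) -> float:
        mrca = next(n for n in anc[u] if n in set(anc[v]))
        return depth[u] + depth[v] - 2.0 * node_depth[mrca]

    y, z = sorted(pair)
    (x,) = set(trio) - pair
    e = 0.5 * (dist(y, x) + dist(z, outgroup) - dist(y, z) - dist(x, outgroup))
    return frozenset(pair), e


def extract_triplet_branches(
    gene_trees: Sequence[dendropy.Tree],
    triplet: tuple[str, str, str],
    outgroup: str,
) -> TripletBranchData:
    """Collect per-topology internal branch lengths for a triplet.

    Each gene tree is restricted to the triplet plus the outgroup (used
    only to orient the quartet); the sister pair defines the topology
    class and the quartet's internal edge length is recorded.  Trees
    missing any of the four taxa are skipped; unresolved restrictions and
    non-positive internal branches are tallied separately.
    """
    if len(set(triplet)) != 3 or outgroup in triplet:
        raise ValueError("triplet must be three distinct non-outgroup taxa")
    data = TripletBranchData(triplet=tuple(triplet))
    needed = set(triplet) | {outgroup}
    for tree in gene_trees:
        if not needed <= set(leaf_labels(tree)):
            data.n_skipped += 1
            continue
        pair, e = _quartet_internal_branch(tree, triplet, outgroup)
        if pair is None:
            data.n_unresolved += 1
        elif e is None or e <= 0.0:
            data.n_zero += 1
        else:
            data.lengths.setdefault(pair, []).append(float(e))
    return data


# ---------------------------------------------------------------------------
# model fits


def fit_ils_only(lengths: Sequence[float]) -> tuple[float, float, float]:
    """ML fit of a single exponential: returns (theta_hat, loglik, BIC).

    theta_hat is the sample mean; BIC = -2 loglik + k log n with k = 1.
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 branch lengths")
    if np.any(x <= 0):
        raise ValueError("branch lengths must be strictly positive")
    theta = float(x.mean())
    loglik = float(-x.size * (math.log(theta) + 1.0))
    bic = -2.0 * loglik + math.log(x.size)
    return theta, loglik, bic


@dataclass
class MixtureFit:
    """Joint record of the 1- and 2-component exponential fits."""

    pi1: float
    pi2: float
    theta: float
    delta: float
    loglik1: float
    loglik2: float
    bic1: float
    bic2: float
    delta_bic: float
    n: int
    n_iter: int
    converged: bool


def _mix_loglik(x: np.ndarray, pi2: float, theta: float, delta: float) -> float:
    f1 = np.exp(-x / theta) / theta
    f2 = np.where(x >= delta, np.exp(-np.maximum(x - delta, 0.0) / theta) / theta, 0.0)
    dens = (1.0 - pi2) * f1 + pi2 * f2
    if np.any(dens <= 0.0):
        return -math.inf
    return float(np.log(dens).sum())


def fit_mixture_em(
    lengths: Sequence[float],
    numsteps: int = EM_NUMSTEPS,
    likelihoodthresh: float = EM_LIKELIHOODTHRESH,
    gradascentscalar: float = EM_GRADASCENTSCALAR,
    seed: int = 0,
) -> MixtureFit:
    """EM fit of the shared-scale shifted-exponential mixture.

    Initialization is fixed (pi2 = 0.5, delta = median, theta = mean/2),
    so the fit is deterministic; ``seed`` is accepted for interface
    symmetry but unused by the default single-start schedule.  Each
    iteration runs the closed-form E/M updates for pi2 and theta and a
    damped ascent step for delta: the proposal moves a ``gradascentscalar``
    fraction toward the observed-likelihood argmax on a data-quantile
    grid, and is only accepted if the log-likelihood does not decrease —
    hence the likelihood is monotone across iterations.  Iteration stops
    after ``numsteps`` or when the improvement falls below
    ``likelihoodthresh``.  If the mixture ends below the single-exponential
    likelihood (a failed search), the null-equivalent point (pi2 = 0,
    delta = 0) is returned flagged as non-converged.
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < MIN_CLASS_SIZE:
        raise ValueError(f"need at least {MIN_CLASS_SIZE} branch lengths, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("branch lengths must be strictly positive")
    n = x.size
    theta1, loglik1, bic1 = fit_ils_only(x)

    # delta candidates: 0 plus the data quantiles (the likelihood's only
    # breakpoints are at data values)
    qs = np.unique(np.quantile(x, np.linspace(0.0, 0.98, 257)))
    candidates = np.concatenate([[0.0], qs])

    pi2 = 0.5
    delta = float(np.median(x))
    theta = float(x.mean() / 2.0)
    loglik = _mix_loglik(x, pi2, theta, delta)
    converged = False
    it = 0
    for it in range(1, numsteps + 1):
        # E-step
        f1 = np.exp(-x / theta) / theta
        f2 = np.where(x >= delta, np.exp(-np.maximum(x - delta, 0.0) / theta) / theta, 0.0)
        dens = (1.0 - pi2) * f1 + pi2 * f2
        r2 = pi2 * f2 / dens
        # M-step: closed forms for pi2 and theta given delta
        pi2_new = float(r2.mean())
        theta_of = lambda d, p: max(float(x.mean() - p * d), 1e-12)
        # delta: damped ascent toward the profile-likelihood argmax
        lls = np.array([_mix_loglik(x, pi2_new, theta_of(d, pi2_new), d) for d in candidates])
        d_star = float(candidates[int(np.argmax(lls))])
        proposal = delta + gradascentscalar * (d_star - delta)
        best = (loglik, pi2, theta, delta)
        for d_try in (proposal, d_star, delta):
            p_try, t_try = pi2_new, theta_of(d_try, pi2_new)
            ll_try = _mix_loglik(x, p_try, t_try, d_try)
            if ll_try > best[0]:
                best = (ll_try, p_try, t_try, d_try)
                break
        new_loglik, pi2, theta, delta = best
        if new_loglik - loglik < likelihoodthresh:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    if loglik < loglik1:  # failed search: fall back to the nested null point
        pi2, delta, theta, loglik, converged = 0.0, 0.0, theta1, loglik1, False
    bic2 = -2.0 * loglik + 3.0 * math.log(n)
    return MixtureFit(
        pi1=1.0 - pi2,
        pi2=pi2,
        theta=theta,
        delta=delta,
        loglik1=loglik1,
        loglik2=loglik,
        bic1=bic1,
        bic2=bic2,
        delta_bic=bic2 - bic1,
        n=n,
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# calling


@dataclass
class TripletFit:
    """One (triplet, topology class) mixture fit with its discordance flag."""

    triplet: tuple[str, str, str]
    sister_pair: frozenset
    discordant: bool
    fit: MixtureFit

    @property
    def class_label(self) -> str:
        return TripletBranchData.class_label(self.sister_pair, self.triplet)


def concordant_pair(species_tree: dendropy.Tree, triplet: Sequence[str]) -> frozenset:
    """The species-tree sister pair of a triplet (the concordant class)."""
    sub = restrict_tree(species_tree, set(triplet))
    for node in sub.preorder_internal_node_iter():
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if len(below) == 2:
            return frozenset(below)
    raise TreeError(f"species tree is unresolved for triplet {tuple(triplet)}")


def fit_triplet_classes(
    data: TripletBranchData,
    species_pair: frozenset | None,
    min_class_size: int = MIN_CLASS_SIZE,
    **em_kwargs,
) -> list[TripletFit]:
    """Fit the mixture to every usable topology class of a triplet.

    ``species_pair`` marks the concordant class (None = treat every class
    as discordant).  Classes with fewer than ``min_class_size`` usable
    branch lengths are skipped with a log note.
    """
    fits = []
    for pair, lens in sorted(data.lengths.items(), key=lambda kv: sorted(kv[0])):
        if len(lens) < min_class_size:
            logger.info(
                "triplet %s class %s skipped: only %d usable branch lengths",
                data.triplet, TripletBranchData.class_label(pair, data.triplet), len(lens),
            )
            continue
        fits.append(
            TripletFit(
                triplet=data.triplet,
                sister_pair=pair,
                discordant=(species_pair is not None and pair != species_pair),
                fit=fit_mixture_em(lens, **em_kwargs),
            )
        )
    return fits


def call_introgression(
    fits: Iterable[TripletFit], threshold: float = DELTA_BIC_THRESHOLD
) -> list[TripletFit]:
    """Retain discordant-class fits whose delta-BIC falls below the
    threshold (default -30): the entries called as gene flow.  Shifts on
    the concordant class are read as speciation, not introgression."""
    return [f for f in fits if f.discordant and f.fit.delta_bic < threshold]


def mean_pi2(calls: Sequence[TripletFit]) -> float:
    """Mean pi2 across called discordant classes — the headline
    'introgression contribution' summary (NaN when nothing is called)."""
    if not calls:
        return float("nan")
    return float(np.mean([c.fit.pi2 for c in calls]))


def pi2_heatmap(calls: Sequence[TripletFit], leaf_order: Sequence[str]) -> pd.DataFrame:
    """Symmetric pi2 matrix over taxa: cells (Y, Z) and (Z, Y) hold the
    largest called pi2 whose discordant sister pair is {Y, Z}."""
    mat = pd.DataFrame(np.nan, index=list(leaf_order), columns=list(leaf_order))
    for c in calls:
        y, z = sorted(c.sister_pair)
        cur = mat.loc[y, z]
        val = c.fit.pi2 if math.isnan(cur) else max(cur, c.fit.pi2)
        mat.loc[y, z] = mat.loc[z, y] = val
    return mat


def fits_table(fits: Sequence[TripletFit], threshold: float = DELTA_BIC_THRESHOLD) -> pd.DataFrame:
    """Flat TSV-ready table of triplet mixture fits."""
    rows = []
    for f in fits:
        rows.append(
            {
                "triplet": ",".join(f.triplet),
                "class": f.class_label,
                "discordant": f.discordant,
                "n": f.fit.n,
                "theta": f.fit.theta,
                "delta": f.fit.delta,
                "pi1": f.fit.pi1,
                "pi2": f.fit.pi2,
                "loglik1": f.fit.loglik1,
                "loglik2": f.fit.loglik2,
                "BIC1": f.fit.bic1,
                "BIC2": f.fit.bic2,
                "dBIC": f.fit.delta_bic,
                "call": f.discordant and f.fit.delta_bic < threshold,
            }
        )
    return pd.DataFrame(rows)
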