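"""Multispecies-coalescent gene-tree simulation and sequence evolution.

This is the package's synthetic-data engine.  Gene trees are drawn under
the multispecies coalescent (MSC) on a species tree whose branch lengths
are in coalescent units (time scaled by 2N generations, so k lineages in
a population coalesce at rate k(k-1)/2).  A species *network* adds
instantaneous hybridization pulses: at the event time every lineage
surviving on the recipient edge independently routes to the donor edge
with the inheritance probability gamma.  Sequences evolve along simulated
gene trees under Jukes–Cantor (JC69).

Time runs from the tips toward the root.  Node ages are fixed by the
species-tree branch lengths top-down (root age = longest root-to-leaf
path), so non-contemporaneous tips are permitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .treekit import Alignment, leaf_labels, parse_newick

__all__ = [
    "HybridEvent",
    "SpeciesNetwork",
    "GeneTreeSample",
    "simulate_gene_trees",
    "simulate_alignment",
    "xanthoceras_scenario",
    "XANTHOCERAS_QUARTET_NEWICK",
]

_NUC = np.array([b"A", b"C", b"G", b"T"])


class ModelError(ValueError):
    """Invalid simulation model (bad gamma, negative branch length, ...)."""


@dataclass(frozen=True)
class HybridEvent:
    """An introgression pulse.

    Edges are identified by the leaf set (clade) below their child node.
    At ``time`` each lineage on the recipient edge moves to the donor
    edge independently with probability ``gamma``.
    """

    recipient: frozenset[str]
    donor: frozenset[str]
    time: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ModelError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.time < 0:
            raise ModelError(f"event time must be >= 0, got {self.time}")


@dataclass
class SpeciesNetwork:
    """A coalescent species tree plus zero or more hybridization events."""

    tree: dendropy.Tree
    events: list[HybridEvent] = field(default_factory=list)


@dataclass
class GeneTreeSample:
    """A batch of simulated gene trees with provenance."""

    trees: list[dendropy.Tree]
    seed: int
    model: str


class _Lin:
    """A gene-tree lineage during simulation (lightweight; converted to
    dendropy only at the end)."""

    __slots__ = ("label", "age", "children")

    def __init__(self, label, age, children=()):
        self.label = label
        self.age = age
        self.children = children


def _node_ages(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Ages from branch lengths, top-down: root age = longest root-to-leaf
    path; child age = parent age - edge length."""
    depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise ModelError("species tree branch lengths are required for simulation")
        if node.edge.length < 0:
            raise ModelError(f"negative branch length: {node.edge.length}")
        depth[node] = depth[node.parent_node] + node.edge.length
    root_age = max(depth[lf] for lf in tree.leaf_node_iter())
    ages = {n: root_age - d for n, d in depth.items()}
    for n, a in ages.items():
        if a < -1e-9:
            raise ModelError("node age below zero; branch lengths inconsistent")
        ages[n] = max(a, 0.0)
    return ages


def _clade(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


class _MSCModel:
    """Preprocessed simulation schedule shared by all replicates."""

    def __init__(self, network: SpeciesNetwork, samples_per_species: dict[str, int]):
        tree = network.tree
        self.ages = _node_ages(tree)
        self.clades = {node: _clade(node) for node in tree.preorder_node_iter()}
        by_clade = {c: n for n, c in self.clades.items()}
        self.root = tree.seed_node
        self.leaves = list(tree.leaf_node_iter())
        self.samples = samples_per_species

        # events: (time, priority, kind, payload); hybrids fire before merges
        # at equal times so routing sees lineages still on the recipient edge
        events: list[tuple[float, int, str, object]] = []
        for leaf in self.leaves:
            events.append((self.ages[leaf], 0, "start", leaf))
        for ev in network.events:
            for role, clade in (("recipient", ev.recipient), ("donor", ev.donor)):
                node = by_clade.get(clade)
                if node is None:
                    raise ModelError(f"{role} clade {sorted(clade)} is not an edge of the tree")
                lo = self.ages[node]
                hi = self.ages[node.parent_node] if node.parent_node else math.inf
                if not lo <= ev.time <= hi + 1e-12:
                    raise ModelError(
                        f"event time {ev.time} outside {role} edge span [{lo}, {hi}]"
                    )
            events.append((ev.time, 1, "hybrid", (by_clade[ev.recipient], by_clade[ev.donor], ev.gamma)))
        for node in tree.preorder_node_iter():
            if not node.is_leaf():
                events.append((self.ages[node], 2, "merge", node))
        events.sort(key=lambda e: (e[0], e[1]))
        self.events = events

    def simulate(self, rng: np.random.Generator) -> _Lin:
        pops: dict[dendropy.Node, list[_Lin]] = {}
        t_prev = 0.0
        for time, _, kind, payload in self.events:
            if time > t_prev:
                for lins in pops.values():
                    self._coalesce(lins, t_prev, time, rng)
                t_prev = time
            if kind == "start":
                leaf = payload
                lab = leaf.taxon.label
                k = self.samples.get(lab, 1)
                pops.setdefault(leaf, []).extend(
                    _Lin(lab if k == 1 else f"{lab}_{i + 1}", time) for i in range(k)
                )
            elif kind == "hybrid":
                recipient, donor, gamma = payload
                stay: list[_Lin] = []
                moved: list[_Lin] = []
                for lin in pops.get(recipient, []):
                    (moved if rng.random() < gamma else stay).append(lin)
                if recipient in pops:
                    pops[recipient] = stay
                if moved:
                    pops.setdefault(donor, []).extend(moved)
            else:  # merge: children's survivors continue up the parent edge
                node = payload
                dest = pops.setdefault(node, [])
                for child in node.child_nodes():
                    dest.extend(pops.pop(child, []))
        root_lins = pops.get(self.root, [])
        self._coalesce(root_lins, t_prev, math.inf, rng)
        if len(root_lins) != 1:
            raise RuntimeError("simulation did not end with a single lineage")
        return root_lins[0]

    @staticmethod
    def _coalesce(lins: list[_Lin], t0: float, t1: float, rng: np.random.Generator) -> None:
        t = t0
        while len(lins) >= 2:
            k = len(lins)
            t += rng.exponential(2.0 / (k * (k - 1)))
            if t >= t1:
                return
            i = rng.integers(k)
            j = rng.integers(k - 1)
            if j >= i:
                j += 1
            a = lins.pop(max(i, j))
            b = lins.pop(min(i, j))
            lins.append(_Lin(None, t, (a, b)))


def _to_dendropy(root: _Lin, tns: dendropy.TaxonNamespace) -> dendropy.Tree:
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True

    def build(lin: _Lin, parent_age: float | None) -> dendropy.Node:
        node = dendropy.Node()
        if parent_age is not None:
            node.edge.length = parent_age - lin.age
        node.age = lin.age
        if lin.children:
            for ch in lin.children:
                node.add_child(build(ch, lin.age))
        else:
            node.taxon = tns.require_taxon(label=lin.label)
        return node

    tree.seed_node = build(root, None)
    return tree


def _as_network(model: dendropy.Tree | SpeciesNetwork) -> SpeciesNetwork:
    if isinstance(model, SpeciesNetwork):
        return model
    return SpeciesNetwork(tree=model, events=[])


def simulate_gene_trees(
    model: dendropy.Tree | SpeciesNetwork,
    n: int,
    seed: int,
    samples_per_species: dict[str, int] | None = None,
) -> GeneTreeSample:
    """Draw ``n`` independent MSC gene trees from a species tree or network.

    Within each species-tree interval holding k lineages the next
    coalescence waits an Exponential(k(k-1)/2) time; survivors pass to the
    parent edge; hybridization pulses route lineages as described in
    :class:`HybridEvent`; above the root, coalescence continues until one
    lineage remains.  Gene-tree branch lengths are in coalescent units.

    The same seed reproduces the sample bit-for-bit.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    network = _as_network(model)
    msc = _MSCModel(network, samples_per_species or {})
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    trees = [_to_dendropy(msc.simulate(rng), tns) for _ in range(n)]
    desc = (
        f"MSC{'+network' if network.events else ''}; time in coalescent units "
        f"(tips=0, 1 unit = 2N generations); n={n}; seed={seed}"
    )
    return GeneTreeSample(trees=trees, seed=seed, model=desc)


def simulate_alignment(
    gene_tree: dendropy.Tree, n_sites: int, mut_rate: float, seed: int
) -> Alignment:
    """Evolve a JC69 alignment along a gene tree.

    The root sequence is uniform over {A,C,G,T}; along an edge of length t
    (coalescent units) each site substitutes with total probability
    (3/4)(1 - exp(-4*mut_rate*t/3)), landing uniformly on the other three
    states.  ``mut_rate`` is in substitutions/site per coalescent unit.
    """
    if n_sites <= 0:
        raise ValueError(f"n_sites must be positive, got {n_sites}")
    if mut_rate <= 0:
        raise ValueError(f"mut_rate must be positive, got {mut_rate}")
    rng = np.random.default_rng(seed)
    seqs: dict[dendropy.Node, np.ndarray] = {}
    rows: list[tuple[str, np.ndarray]] = []
    for node in gene_tree.preorder_node_iter():
        if node.parent_node is None:
            seq = rng.integers(0, 4, n_sites, dtype=np.int8)
        else:
            t = node.edge.length or 0.0
            seq = seqs[node.parent_node]
            if t > 0:
                p = 0.75 * (1.0 - math.exp(-4.0 * mut_rate * t / 3.0))
                mask = rng.random(n_sites) < p
                seq = seq.copy()
                seq[mask] = (seq[mask] + rng.integers(1, 4, int(mask.sum()), dtype=np.int8)) % 4
        if node.is_leaf():
            rows.append((node.taxon.label, seq))
        else:
            seqs[node] = seq
    rows.sort(key=lambda r: r[0])
    taxa = [lab for lab, _ in rows]
    return Alignment(taxa, _NUC[np.stack([s for _, s in rows])])


# ---------------------------------------------------------------------------
# the hybrid-quartet scenario

#: Symmetric quartet: P1/P2 diverge at 2.0 coalescent units, the outgroup at
#: 3.0, and the hybrid H attaches at 1.0.  Both parental placements of H
#: leave the same internal branch length, which makes the moment estimator
#: of gamma unbiased.
XANTHOCERAS_QUARTET_NEWICK = "(((P1:1.0,H:1.0):1.0,P2:2.0):1.0,O:3.0);"


def xanthoceras_quartet_network(gamma: float) -> SpeciesNetwork:
    """The rooted quartet (((P1,H),P2),O) with H drawing a fraction gamma
    of its ancestry from the P2 edge at time 1.0 (and 1-gamma from P1)."""
    tree = parse_newick(XANTHOCERAS_QUARTET_NEWICK)
    event = HybridEvent(
        recipient=frozenset({"H"}), donor=frozenset({"P2"}), time=1.0, gamma=gamma
    )
    return SpeciesNetwork(tree=tree, events=[event])


def xanthoceras_scenario(
    gamma: float,
    n_loci: int = 2000,
    sites_per_locus: int = 500,
    seed: int = 0,
    mut_rate: float = 0.02,
) -> tuple[SpeciesNetwork, GeneTreeSample, list[Alignment]]:
    """Simulate the full hybrid-quartet study: network, gene trees, and one
    JC69 alignment per locus.

    Defaults (2000 loci x 500 bp at 0.02 substitutions/site per coalescent
    unit) give roughly a megabase of sequence, enough for the downstream
    site-pattern estimator to recover gamma to a couple of percent.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ModelError(f"gamma must be in [0, 1], got {gamma}")
    network = xanthoceras_quartet_network(gamma)
    state = np.random.SeedSequence(seed).generate_state(1 + n_loci)
    sample = simulate_gene_trees(network, n_loci, seed=int(state[0]) % 2**31)
    alignments = [
        simulate_alignment(tree, sites_per_locus, mut_rate, seed=int(state[1 + i]) % 2**31)
        for i, tree in enumerate(sample.trees)
    ]
    return network, sample, alignments


def scenario_metadata(
    network: SpeciesNetwork, gamma: float, seed: int, n_loci: int, sites_per_locus: int, mut_rate: float
) -> dict:
    """JSON-ready provenance sidecar for a simulated scenario."""
    from .treekit import write_newick

    return {
        "model": "MSC on quartet network (((P1,H),P2),O), single introgression pulse",
        "species_tree": write_newick(network.tree),
        "events": [
            {
                "recipient": sorted(ev.recipient),
                "donor": sorted(ev.donor),
                "time": ev.time,
                "gamma": ev.gamma,
            }
            for ev in network.events
        ],
        "gamma": gamma,
        "seed": seed,
        "n_loci": n_loci,
        "sites_per_locus": sites_per_locus,
        "mut_rate": mut_rate,
        "units": "coalescent units (tips at 0; 1 unit = 2N generations)",
    }
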