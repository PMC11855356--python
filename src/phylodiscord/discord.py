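"""Gene-tree / species-tree and plastid / nuclear discordance statistics.

Quantifies how well a set of gene trees agrees with a reference tree:
topology spectra, the fraction of gene trees concordant with a reference
topology (or with one focal split, e.g. the placement of a single
lineage), Robinson–Foulds distance distributions with a Mann–Whitney rank
test between empirical and simulated distributions, and per-node
concordance/conflict counts in the style of PhyParts pie charts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy import stats

from .coalsim import GeneTreeSample
from .treekit import (
    Bipartition,
    TreeError,
    bipartitions,
    leaf_labels,
    restrict_tree,
    rf_distance,
    topology_key,
)

__all__ = [
    "TopologySpectrum",
    "DistanceDistribution",
    "ConcordanceSummary",
    "topology_spectrum",
    "concordance_fraction",
    "distance_distribution",
    "mann_whitney_u",
    "node_concordance",
]

logger = logging.getLogger(__name__)


def _tree_list(sample: GeneTreeSample | Sequence[dendropy.Tree]) -> list[dendropy.Tree]:
    return list(sample.trees) if isinstance(sample, GeneTreeSample) else list(sample)


@dataclass
class TopologySpectrum:
    """Topology-frequency tally over a gene-tree sample."""

    counts: Counter
    total: int

    def frequency(self, key: str) -> float:
        return self.counts.get(key, 0) / self.total


def topology_spectrum(
    sample: GeneTreeSample | Sequence[dendropy.Tree],
    restrict_to: Iterable[str] | None = None,
) -> TopologySpectrum:
    """Tally canonical topology keys, optionally after restricting every
    tree to a taxon subset."""
    trees = _tree_list(sample)
    keys = []
    for t in trees:
        if restrict_to is not None:
            t = restrict_tree(t, restrict_to)
        keys.append(topology_key(t))
    return TopologySpectrum(Counter(keys), len(keys))


def concordance_fraction(
    sample: GeneTreeSample | Sequence[dendropy.Tree],
    reference: dendropy.Tree,
    mode: str = "topology",
    focal_split: Bipartition | None = None,
) -> float:
    """Fraction of gene trees agreeing with a reference tree.

    mode="topology": a gene tree agrees iff, restricted to the reference
    leaf set, it has exactly the reference's rooted topology.
    mode="split": it agrees iff it contains ``focal_split`` (which must be
    a split of the reference) — the laxer reading used when asking where a
    single lineage attaches.
    """
    trees = _tree_list(sample)
    if not trees:
        raise ValueError("empty gene-tree sample")
    ref_taxa = set(leaf_labels(reference))
    if mode == "topology":
        ref_key = topology_key(reference)
        hits = sum(
            1 for t in trees if topology_key(restrict_tree(t, ref_taxa)) == ref_key
        )
    elif mode == "split":
        if focal_split is None:
            raise ValueError("mode='split' requires focal_split")
        if focal_split not in bipartitions(reference, include_trivial=True):
            raise ValueError("focal split is not a bipartition of the reference tree")
        hits = sum(
            1 for t in trees if focal_split in bipartitions(restrict_tree(t, ref_taxa))
        )
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return hits / len(trees)


@dataclass
class DistanceDistribution:
    """RF distances of gene trees from a reference, histogram-ready."""

    values: list[int]
    source: str = "unlabeled"
    n_skipped: int = 0

    def histogram(self) -> dict[int, int]:
        return dict(sorted(Counter(self.values).items()))


def distance_distribution(
    gene_trees: Sequence[dendropy.Tree],
    species_tree: dendropy.Tree,
    source: str = "unlabeled",
) -> DistanceDistribution:
    """One RF distance per gene tree (each gene tree is first restricted to
    the species-tree taxa; trees missing taxa are skipped with a warning)."""
    sp_taxa = set(leaf_labels(species_tree))
    values: list[int] = []
    skipped = 0
    for i, gt in enumerate(gene_trees):
        gt_taxa = set(leaf_labels(gt))
        if not sp_taxa <= gt_taxa:
            logger.warning(
                "gene tree %d skipped: missing taxa %s", i, sorted(sp_taxa - gt_taxa)
            )
            skipped += 1
            continue
        values.append(rf_distance(restrict_tree(gt, sp_taxa), species_tree))
    return DistanceDistribution(values=values, source=source, n_skipped=skipped)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann–Whitney U rank test.

    U counts pairs (x_i, y_j) with x_i > y_j, plus half of the ties.  The
    p-value is exact (full enumeration) when both samples have at most 8
    observations and there are no ties; otherwise it uses the normal
    approximation with midrank tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    tie_free = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ConcordanceSummary:
    """Per-species-tree-node gene-tree support.

    Keys are the leaf sets (clades) below each internal node; each value
    is (concordant, conflicting, uninformative) and the three always sum
    to the number of gene trees examined.
    """

    counts: dict[frozenset, tuple[int, int, int]] = field(default_factory=dict)
    n_trees: int = 0

    def proportions(self) -> dict[frozenset, tuple[float, float, float]]:
        return {
            k: tuple(c / self.n_trees for c in v) for k, v in self.counts.items()
        }

    def concordant_node_fraction(self) -> float:
        """Proportion of concordant counts relative to the combined total of
        concordant and conflicting counts, pooled over nodes."""
        conc = sum(v[0] for v in self.counts.values())
        conf = sum(v[1] for v in self.counts.values())
        return conc / (conc + conf) if conc + conf else float("nan")


def node_concordance(
    species_tree: dendropy.Tree, gene_trees: Sequence[dendropy.Tree]
) -> ConcordanceSummary:
    """Classify every gene tree at every internal species-tree node.

    For each species-tree split, a gene tree restricted to the taxa it
    shares with the species tree is *concordant* if it contains the
    (restricted) split, *conflicting* if it contains an incompatible
    split (all four intersection cells non-empty), and *uninformative*
    if the restriction leaves the split trivial or the gene tree
    unresolved there.  Gene trees may lack species-tree taxa.
    """
    sp_taxa = frozenset(leaf_labels(species_tree))
    sp_splits = bipartitions(species_tree)
    gene_info = []
    for gt in gene_trees:
        shared = frozenset(leaf_labels(gt)) & sp_taxa
        gene_info.append((shared, bipartitions(restrict_tree(gt, shared)) if len(shared) >= 4 else set()))

    counts: dict[frozenset, tuple[int, int, int]] = {}
    for split in sp_splits:
        clade = min(split.side_a, split.side_b, key=lambda s: (len(s), sorted(s)))
        conc = conf = uninf = 0
        for shared, g_splits in gene_info:
            local = split.restrict(shared)
            if local.is_trivial():
                uninf += 1
            elif local in g_splits:
                conc += 1
            elif any(local.conflicts_with(g) for g in g_splits):
                conf += 1
            else:
                uninf += 1
        counts[clade] = (conc, conf, uninf)
    return ConcordanceSummary(counts=counts, n_trees=len(gene_trees))
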