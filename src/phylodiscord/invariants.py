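"""Site-pattern invariants hybridization detection.

Works on a rooted four-taxon assignment (((P1, H), P2), O): the outgroup O
polarizes each biallelic site, and the three ways the ingroup trio can
share a derived allele (BBAA with P1, ABBA with P2, BABA linking the two
parents) carry the signal.  Under a mixture in which a fraction gamma of
H's ancestry follows the P2 (donor) edge and the internal branches of the
two parental placements are equal, the moment estimator

    gamma_hat = (f_ABBA - f_BABA) / (f_BBAA + f_ABBA - 2 f_BABA)

is exactly gamma in expectation.  Significance comes from a multinomial
bootstrap of the classified site counts: Z = gamma_hat / SE with a
one-sided (upper tail) normal p-value, and the operative filter keeps
quartets with 0 < gamma_hat < 1, p < 0.05 and Z > 3.  An all-triples scan
tries every hybrid assignment among the ingroup taxa, and the results can
be pivoted into a donor-by-parent matrix for heatmap display.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .treekit import Alignment

__all__ = [
    "QuartetAssignment",
    "SitePatternCounts",
    "InvariantsResult",
    "count_site_patterns",
    "pool_counts",
    "estimate_gamma",
    "z_test",
    "evaluate_quartet",
    "triple_scan",
    "passes_filter",
    "heatmap_matrix",
    "results_table",
]

logger = logging.getLogger(__name__)

#: defaults of the downstream significance filter
FILTER_P = 0.05
FILTER_Z = 3.0


@dataclass(frozen=True)
class QuartetAssignment:
    """Roles in the rooted quartet (((P1, H), P2), O); H is the putative
    hybrid, P2 the putative donor, O the outgroup."""

    p1: str
    h: str
    p2: str
    o: str

    def __post_init__(self) -> None:
        if len({self.p1, self.h, self.p2, self.o}) != 4:
            raise ValueError("quartet roles must name four distinct taxa")


@dataclass(frozen=True)
class SitePatternCounts:
    """Polarized biallelic site-pattern tallies for one quartet.

    n_used counts every site where all four taxa have a plain nucleotide;
    of those, sites where exactly two ingroup taxa share one derived state
    are classified BBAA/ABBA/BABA and the rest fall in n_other.
    """

    n_bbaa: int
    n_abba: int
    n_baba: int
    n_other: int
    n_used: int

    def __post_init__(self) -> None:
        if min(self.n_bbaa, self.n_abba, self.n_baba, self.n_other) < 0:
            raise ValueError("negative site-pattern count")
        total = self.n_bbaa + self.n_abba + self.n_baba + self.n_other
        # tolerance admits expected (real-valued) counts, not just tallies
        if abs(total - self.n_used) > 1e-6 * max(self.n_used, 1):
            raise ValueError("site-pattern counts do not sum to n_used")


@dataclass(frozen=True)
class InvariantsResult:
    """One quartet's test: estimate, bootstrap SE, Z, one-sided p."""

    quartet: QuartetAssignment
    gamma: float
    se: float
    z: float
    p: float
    counts: SitePatternCounts
    swapped: bool = False  # True if P1/P2 were exchanged to canonicalize


def count_site_patterns(aln: Alignment, quartet: QuartetAssignment) -> SitePatternCounts:
    """Tally polarized quartet site patterns from an alignment.

    A site is skipped when any of the four taxa shows a gap or N.  The
    outgroup allele is taken as ancestral; the site is classified when the
    ingroup trio is biallelic with exactly two taxa carrying the shared
    derived state (BBAA: P1+H, ABBA: H+P2, BABA: P1+P2).
    """
    rows = np.stack([aln.row(t) for t in (quartet.p1, quartet.h, quartet.p2, quartet.o)])
    valid = np.isin(rows, np.array([b"A", b"C", b"G", b"T"])).all(axis=0)
    p1, h, p2, o = rows[:, valid]
    d1, dh, d2 = p1 != o, h != o, p2 != o
    n_derived = d1.astype(np.int8) + dh + d2
    two = n_derived == 2
    bbaa = two & d1 & dh & (p1 == h)
    abba = two & dh & d2 & (h == p2)
    baba = two & d1 & d2 & (p1 == p2)
    n_bbaa, n_abba, n_baba = int(bbaa.sum()), int(abba.sum()), int(baba.sum())
    n_used = int(valid.sum())
    return SitePatternCounts(
        n_bbaa=n_bbaa,
        n_abba=n_abba,
        n_baba=n_baba,
        n_other=n_used - n_bbaa - n_abba - n_baba,
        n_used=n_used,
    )


def _gamma_from_freqs(n_bbaa, n_abba, n_baba, n_used):
    n_bbaa, n_abba, n_baba = (np.asarray(v, dtype=float) for v in (n_bbaa, n_abba, n_baba))
    denom = n_bbaa + n_abba - 2.0 * n_baba
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom != 0, (n_abba - n_baba) / denom, np.nan)


def estimate_gamma(counts: SitePatternCounts) -> float:
    """Moment estimator of the inheritance probability.

    gamma_hat = (f_ABBA - f_BABA) / (f_BBAA + f_ABBA - 2 f_BABA).  Under a
    two-topology mixture with equal internal branches — f_BBAA =
    (1-gamma) C + gamma d, f_ABBA = (1-gamma) d + gamma C, f_BABA = d —
    this equals gamma exactly.  A zero denominator yields NaN, which the
    significance filter excludes downstream.
    """
    val = _gamma_from_freqs(counts.n_bbaa, counts.n_abba, counts.n_baba, counts.n_used)
    return float(val)


def pool_counts(counts: Sequence[SitePatternCounts]) -> SitePatternCounts:
    """Sum per-locus tallies into one super-alignment tally."""
    return SitePatternCounts(
        n_bbaa=sum(c.n_bbaa for c in counts),
        n_abba=sum(c.n_abba for c in counts),
        n_baba=sum(c.n_baba for c in counts),
        n_other=sum(c.n_other for c in counts),
        n_used=sum(c.n_used for c in counts),
    )


def z_test(
    counts: SitePatternCounts | Sequence[SitePatternCounts],
    b: int = 200,
    seed: int = 0,
) -> InvariantsResult:
    """Bootstrap Z-test of gamma_hat against 0.

    With pooled counts, SE is the standard deviation of gamma_hat over
    ``b`` multinomial resamples of the classified-site counts (sites
    treated as independent).  With a sequence of per-locus counts, loci
    are resampled with replacement instead (a block bootstrap): sites on
    the same locus share one gene tree, so the site-level resample
    understates the variance and the locus-level one is preferred whenever
    locus boundaries are known.  Z = gamma_hat / SE; p is the one-sided
    upper-tail standard-normal probability.  Deterministic given the seed.
    """
    if b < 50:
        raise ValueError(f"need at least 50 bootstrap replicates, got {b}")
    rng = np.random.default_rng(seed)
    if isinstance(counts, SitePatternCounts):
        pooled = counts
        if pooled.n_used <= 0:
            raise ValueError("no usable sites")
        cells = np.array([pooled.n_bbaa, pooled.n_abba, pooled.n_baba, pooled.n_other])
        draws = rng.multinomial(pooled.n_used, cells / pooled.n_used, size=b)
    else:
        per_locus = np.array(
            [[c.n_bbaa, c.n_abba, c.n_baba, c.n_other] for c in counts]
        )
        pooled = pool_counts(counts)
        if pooled.n_used <= 0:
            raise ValueError("no usable sites")
        idx = rng.integers(0, len(per_locus), size=(b, len(per_locus)))
        draws = per_locus[idx].sum(axis=1)
    gamma = estimate_gamma(pooled)
    reps = _gamma_from_freqs(draws[:, 0], draws[:, 1], draws[:, 2], pooled.n_used)
    se = float(np.nanstd(reps))
    if not math.isfinite(gamma):
        z, p = float("nan"), 1.0
    elif se == 0.0:
        logger.warning("bootstrap SE is zero; Z undefined, reporting p = 1")
        z, p = float("nan"), 1.0
    else:
        z = gamma / se
        p = float(stats.norm.sf(z))
    return InvariantsResult(
        quartet=QuartetAssignment("P1", "H", "P2", "O"), gamma=gamma, se=se, z=z, p=p, counts=pooled
    )


def passes_filter(
    r: InvariantsResult, p_cut: float = FILTER_P, z_cut: float = FILTER_Z
) -> bool:
    """Downstream significance rule: 0 < gamma_hat < 1, p < 0.05, Z > 3.

    Also requires a positive estimator denominator (f_BBAA + f_ABBA -
    2 f_BABA): under the quartet model that quantity equals the difference
    of concordant and discordant pattern rates, C - d > 0, so a
    non-positive value means the P1/H/P2 roles are inconsistent with the
    data (e.g. the putative sister pair is not the dominant one) and the
    estimate is meaningless regardless of its Z-score.
    """
    c = r.counts
    return (
        math.isfinite(r.gamma)
        and 0.0 < r.gamma < 1.0
        and c.n_bbaa + c.n_abba - 2 * c.n_baba > 0
        and r.p < p_cut
        and math.isfinite(r.z)
        and r.z > z_cut
    )


def evaluate_quartet(
    data: Alignment | Sequence[Alignment],
    quartet: QuartetAssignment,
    b: int = 200,
    seed: int = 0,
) -> InvariantsResult:
    """Count patterns for one explicit quartet assignment and Z-test it.

    ``data`` may be one super-alignment (site-level bootstrap) or a list
    of per-locus alignments (locus-level bootstrap, preferred).
    """
    if isinstance(data, Alignment):
        counts: SitePatternCounts | list[SitePatternCounts] = count_site_patterns(data, quartet)
    else:
        counts = [count_site_patterns(a, quartet) for a in data]
    res = z_test(counts, b=b, seed=seed)
    return InvariantsResult(
        quartet=quartet, gamma=res.gamma, se=res.se, z=res.z, p=res.p, counts=res.counts
    )


def triple_scan(
    data: Alignment | Sequence[Alignment],
    taxa: Sequence[str] | None = None,
    outgroup: str = "O",
    b: int = 200,
    seed: int = 0,
) -> list[InvariantsResult]:
    """Test every hybrid assignment among the ingroup taxa.

    Each unordered ingroup triple yields three tests (each member once in
    the hybrid role).  The P1/P2 order is canonicalized so gamma_hat >= 0
    — swapping the parents maps gamma_hat to 1 - gamma_hat, since the two
    orientations share the estimator's denominator — and the swap is
    recorded.  ``data`` as a list of per-locus alignments selects the
    locus-level bootstrap (see :func:`z_test`).  Deterministic given the
    seed.
    """
    first = data if isinstance(data, Alignment) else data[0]
    ingroup = [t for t in (taxa if taxa is not None else first.taxa) if t != outgroup]
    if outgroup not in first.taxa:
        raise ValueError(f"outgroup {outgroup!r} not in alignment")
    if len(ingroup) < 3:
        raise ValueError("need at least 3 ingroup taxa")
    triples = list(itertools.combinations(ingroup, 3))
    sub_seeds = np.random.SeedSequence(seed).generate_state(3 * max(len(triples), 1))
    results: list[InvariantsResult] = []
    for i, triple in enumerate(triples):
        for j, h in enumerate(triple):
            pa, pb = sorted(set(triple) - {h})
            sub_seed = int(sub_seeds[3 * i + j]) % 2**31
            res = evaluate_quartet(data, QuartetAssignment(pa, h, pb, outgroup), b=b, seed=sub_seed)
            if math.isfinite(res.gamma) and res.gamma < 0:
                res = evaluate_quartet(data, QuartetAssignment(pb, h, pa, outgroup), b=b, seed=sub_seed)
                res = InvariantsResult(
                    quartet=res.quartet, gamma=res.gamma, se=res.se, z=res.z,
                    p=res.p, counts=res.counts, swapped=True,
                )
            results.append(res)
    return results


def heatmap_matrix(
    results: Sequence[InvariantsResult],
    hybrid: str,
    leaf_order: Sequence[str],
    p_cut: float = FILTER_P,
    z_cut: float = FILTER_Z,
) -> pd.DataFrame:
    """Gamma matrix for one hybrid: cell (i, j) holds gamma_hat of the
    filtered result with P1 = i, P2 = j; everything else is NaN."""
    mat = pd.DataFrame(np.nan, index=list(leaf_order), columns=list(leaf_order))
    hits = [r for r in results if r.quartet.h == hybrid]
    if not hits:
        logger.warning("no results for hybrid %r; returning empty matrix", hybrid)
        return mat
    for r in hits:
        if passes_filter(r, p_cut=p_cut, z_cut=z_cut):
            mat.loc[r.quartet.p1, r.quartet.p2] = r.gamma
    return mat


def results_table(results: Sequence[InvariantsResult]) -> pd.DataFrame:
    """Flat TSV-ready table of a scan."""
    return pd.DataFrame(
        {
            "P1": [r.quartet.p1 for r in results],
            "H": [r.quartet.h for r in results],
            "P2": [r.quartet.p2 for r in results],
            "gamma": [r.gamma for r in results],
            "SE": [r.se for r in results],
            "Z": [r.z for r in results],
            "p": [r.p for r in results],
            "nBBAA": [r.counts.n_bbaa for r in results],
            "nABBA": [r.counts.n_abba for r in results],
            "nBABA": [r.counts.n_baba for r in results],
            "n_used": [r.counts.n_used for r in results],
            "swapped": [r.swapped for r in results],
            "passed_filter": [passes_filter(r) for r in results],
        }
    )
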