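# Methods

This note documents the models implemented in phylodiscord, the choices
made where the design was genuinely open, and what the synthetic studies
do and do not demonstrate.

## Multispecies coalescent simulation

Species trees carry branch lengths in coalescent units (one unit = 2N
generations, so a pair of lineages coalesces at rate 1).  Time runs from
the tips (0) toward the root.  Node ages are fixed top-down: the root age
is the longest root-to-leaf path and each child's age is its parent's age
minus the connecting branch length; tips therefore need not be
contemporaneous, but ages always increase toward the root.

Within each species-tree interval holding *k* gene lineages the waiting
time to the next coalescence is Exponential with rate *k*(*k*−1)/2; the
coalescing pair is uniform; survivors pass to the parent interval, and
above the root coalescence continues until a single lineage remains.

Hybridization is modeled as an instantaneous pulse, not continuous
migration: an event (recipient edge, donor edge, time *t*, γ) moves each
lineage present on the recipient edge at time *t* to the donor edge
independently with probability γ.  Events are processed in global time
order, before any speciation merge scheduled at the same instant, so a
pulse placed exactly at the top of the recipient edge still sees its
lineages.

Sequences evolve by Jukes–Cantor: a uniform root sequence, and along an
edge of length *t* each site substitutes with probability
(3/4)(1 − e^(−4μt/3)), landing uniformly on the other three states.  μ
(`mut_rate`) is in substitutions/site per coalescent unit.

### The hybrid-quartet scenario

`xanthoceras_scenario(gamma, ...)` builds the rooted quartet
(((P1,H),P2),O) with P1/P2 divergence at 2.0, the outgroup at 3.0, and H
attaching at time 1.0 — to the P1 side with probability 1−γ and to the
P2 edge with probability γ.  The depths are deliberately symmetric: both
parental placements of H leave an internal interval of length exactly 1.0
(H–P1 in [1,2] on the major tree, H–P2 in [1,2] on the donor edge), so
the two mixture components of the site-pattern model share their
concordant-pattern rate and the moment estimator of γ below is unbiased.
They are model depths in coalescent units, not estimates of any empirical
divergence times.  Defaults — 2000 loci × 500 bp at μ = 0.02 — give
roughly 10⁴ BBAA-class sites per megabase, enough to recover γ to a
couple of percentage points while a full simulation-plus-estimation run
stays under a few seconds.

## Quantifying discordance

Robinson–Foulds distances are computed on **unrooted** non-trivial
bipartitions (root placement never changes them); multifurcations simply
contribute fewer bipartitions and are never randomly resolved.  The
empirical-vs-simulated comparison uses the Mann–Whitney U test (U counts
pairs x>y plus half-ties; exact enumeration when both samples have ≤ 8
tie-free observations, otherwise the normal approximation with midrank
tie correction and continuity correction).  The decision rule is read in
the conservative direction: p ≥ 0.05 fails to reject the ILS-only null.

Concordance with a reference topology is reported in two modes, because
"agrees with the plastid tree" is ambiguous: *full topology* (the gene
tree restricted to the reference taxa matches exactly) and *focal split*
(the gene tree contains one named bipartition, e.g. the placement of a
single lineage).  Per-node concordance follows PhyParts semantics: a gene
tree restricted to shared taxa is concordant at a species-tree split if
it contains the restricted split, conflicting if it contains an
incompatible split (all four intersection cells non-empty), and
uninformative otherwise; the three counts always sum to the number of
gene trees.

## Invariants-based hybridization detection

For a quartet (((P1,H),P2),O) each alignment site with plain nucleotides
in all four taxa is polarized by the outgroup; sites where exactly two
ingroup taxa share one derived state are classified BBAA (P1+H), ABBA
(H+P2) or BABA (P1+P2).  Writing f for per-site frequencies, the
two-topology mixture with equal internal branches gives
f_BBAA = (1−γ)C + γd, f_ABBA = (1−γ)d + γC, f_BABA = d, whence

    gamma_hat = (f_ABBA − f_BABA) / (f_BBAA + f_ABBA − 2 f_BABA) = γ,

exactly, for any concordant rate C > discordant rate d.  The estimator is
a method-of-moments analogue of Patterson's D; it is *not* claimed to
reproduce any particular tool's invariant algebra.

Significance uses a bootstrap: Z = γ̂/SE with a one-sided upper-tail
normal p.  Two resampling schemes are provided.  Given one pooled count
vector, classified sites are resampled multinomially (B = 200 default) —
this treats sites as independent.  Given per-locus counts, whole loci are
resampled instead.  The distinction matters: sites on one locus share a
gene tree, so the site-level scheme understates the variance of γ̂ —
under the γ = 0 scenario it inflates the Z > 3 rate to ~13%, while the
locus-level scheme is calibrated (0/100 replicates exceeding Z = 3, with
the 95th percentile of Z near 1.4).  The locus bootstrap is therefore
used whenever locus boundaries are known.

The all-triples scan tests every hybrid assignment (3 per unordered
triple; P1/P2 canonicalized so γ̂ ≥ 0, exploiting γ̂(swapped) = 1 − γ̂).
The downstream filter keeps 0 < γ̂ < 1, p < 0.05, Z > 3, **and** a
positive estimator denominator: under the model the denominator equals
C − d > 0, so a non-positive value means the assumed sister pair is not
the dominant one — the roles are misassigned and the estimate is
meaningless however large its Z.  Without this identifiability guard, a
misrooted assignment in a γ = 0 simulation can show γ̂ ≈ 0.5 with an
enormous Z purely because BABA dominates.

## Triplet branch-length mixtures

For a triplet {A,B,C} each gene tree is restricted to the triplet plus an
outgroup (used only to orient the quartet); the sister pair defines the
topology class and the quartet's internal edge length is the datum
(computed from patristic distances, 2e = d(Y,X)+d(Z,O)−d(Y,Z)−d(X,O)).
Zero-length and unresolved restrictions are tallied but excluded.  Branch
lengths keep whatever units the input gene trees carry.

Per class we compare
- **ILS only:** x ~ Exp(θ); θ̂ = mean (ML), k = 1 parameter;
- **mixture:** f(x) = π₁·(1/θ)e^(−x/θ) + π₂·(1/θ)e^(−(x−δ)/θ)·1[x ≥ δ],
  k = 3 (θ, δ, π₂), π₁ + π₂ = 1 by construction.

Both components share one scale θ: the second distribution is the ILS
branch plus a fixed waiting shift δ, which is the minimal model in which
the shift — not a second free scale — carries the introgression or
speciation signal.

EM details.  Initialization is fixed (π₂ = 0.5, δ = median, θ = mean/2),
so fits are deterministic.  π₂ and θ have closed-form M-steps.  For δ the
expected complete-data log-likelihood is *linear* in δ (gradient
Σr₂/θ > 0 wherever defined), so a pure gradient step can only increase δ
and could never leave an initialization above the optimum; instead the
M-step takes a damped step (factor `gradascentscalar`, default 0.5)
toward the observed-likelihood argmax over a data-quantile candidate
grid, accepted only if the observed log-likelihood does not decrease.
The likelihood is therefore monotone across iterations; iteration stops
after `numsteps` (50) or when the improvement drops below
`likelihoodthresh` (0.01).  If the search ends below the one-component
likelihood (which nests in the mixture at δ = 0 or π₂ = 0), the
null-equivalent point is returned, flagged, so the nesting inequality
loglik₂ ≥ loglik₁ holds exactly.  Against a 50³ grid-search ML oracle on
the 60% Exp(1) + 40% (δ = 1)-shifted fixture (n = 5000) the EM solution
matches π₂ within 0.05 and attains at least the lattice optimum.

Calling: ΔBIC = BIC₂ − BIC₁ < −30 on a **discordant** class is called as
gene flow, with π₂ as its contribution; a shift on the concordant class
is read as speciation, not introgression.  Classes with fewer than 5
usable branch lengths are skipped.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| scenario depths | 1.0 / 2.0 / 3.0 | hybrid attach, P1–P2 split, outgroup (coalescent units) |
| `mut_rate` | 0.02 | substitutions/site per coalescent unit (JC69) |
| loci × sites | 2000 × 500 | scenario sequence effort |
| strip threshold | 0.2 | drop columns with > 20% gaps/N ('−' and 'N' count; exactly 20% is kept) |
| bootstrap B | 200 | Z-test resamples |
| significance | 0 < γ̂ < 1, p < 0.05, Z > 3, denominator > 0 | scan filter |
| EM | numsteps 50, likelihoodthresh 0.01, gradascentscalar 0.5 | mixture fit schedule |
| ΔBIC threshold | −30 | gene-flow call |
| min class size | 5 | triplet class usability |

## What the synthetic studies show — and what they do not

The generator reproduces the *statistical structure* the analyses assume:
MSC gene-tree frequencies (concordance matches 1 − (2/3)e^(−τ) to within
binomial error), pulse introgression with a known γ, and iid JC69 sites
within loci.  Passing tests therefore demonstrate that the estimators
recover their own model's parameters — γ to ±0.03 at the default effort,
calibrated type-I error, π₂ to ±0.05 — not that real transcriptome data
satisfy the model.  Real data add alignment error, substitution-model
misspecification, rate variation, missing data, gene-tree estimation
error, and non-pulse gene flow, none of which are simulated.  Empirical
headline figures from any particular dataset (plastid-topology
concordance percentages, rank-test p-values on real distributions,
empirical π₂ summaries) depend on those data and are outside what the
desk-scale synthetic suite can certify.

Other known limitations: no recombination within loci, no continuous
migration, no demographic size change, JC69 only; the γ estimator's
exactness needs the symmetric-internal-branch design (an asymmetric
network biases it); the locus bootstrap requires locus boundaries, and
single super-alignments fall back to the anti-conservative site scheme;
branch-length units in the triplet mixtures are never converted, so
empirical substitutions/site inputs and coalescent-unit theory are
compared only qualitatively.
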