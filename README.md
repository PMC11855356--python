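# phylodiscord

Tools for asking a recurring question in plant phylogenomics: when the
plastid tree and the nuclear species tree disagree about where a lineage
belongs, is the conflict explained by **incomplete lineage sorting (ILS)**
alone, or did **ancient introgression** move genes across lineages?  The
motivating case is the placement of *Xanthoceras* (Sapindaceae), where
nuclear data put the genus sister to subfam. Hippocastanoideae while
plastid data place it at the family's base, and a minority fraction
γ ≈ 16% of its nuclear genome traces to subfam. Sapindoideae.

The package provides, as composable library modules plus a CLI:

- **`treekit`** — rooted trees (newick, via dendropy), unrooted
  bipartitions, Robinson–Foulds distances, canonical topology keys,
  alignments (FASTA / relaxed PHYLIP) and gap-threshold column stripping.
- **`coalsim`** — gene-tree simulation under the multispecies coalescent
  (MSC) on species trees *and networks*: within an interval holding *k*
  lineages the next coalescence waits Exp(*k*(*k*−1)/2); a hybridization
  pulse routes each lineage on the recipient edge to the donor edge with
  inheritance probability γ.  Jukes–Cantor sequence evolution along the
  simulated gene trees, and the ready-made hybrid-quartet scenario
  `(((P1,H),P2),O)`.
- **`discord`** — topology spectra, concordance fractions (full topology
  or single focal split), RF distance distributions with a Mann–Whitney U
  test of "empirical vs ILS-only simulated", and PhyParts-style per-node
  concordance/conflict counts.
- **`invariants`** — HyDe-style hybridization detection from polarized
  quartet site patterns.  With the outgroup fixing the ancestral state,
  the moment estimator

  γ̂ = (f<sub>ABBA</sub> − f<sub>BABA</sub>) / (f<sub>BBAA</sub> + f<sub>ABBA</sub> − 2 f<sub>BABA</sub>)

  is exactly γ under a symmetric two-topology mixture; a bootstrap Z-test
  (Z = γ̂/SE, one-sided) and the filter 0 < γ̂ < 1, p < 0.05, Z > 3 gate
  the all-triples scan, and results pivot into heatmap matrices.
- **`quibl`** — QuIBL-style triplet analysis: per-topology internal branch
  lengths are fit with a one-component exponential (pure ILS) versus a
  two-component shared-scale mixture π₁·Exp(θ) + π₂·Exp(θ, shift δ) by
  EM; ΔBIC < −30 on a discordant topology class is called as gene flow
  and π₂ measures its contribution.
- **`phylodiscord` CLI** — `simulate | discord | hyde | quibl | demo`
  subcommands with YAML config, explicit seeds, TSV/JSON outputs.

## Worked example

Simulate the hybrid quartet with γ = 0.16 (P1/P2 split at 2.0 coalescent
units, outgroup at 3.0, H drawing 16% of its ancestry from the P2 edge at
time 1.0), evolve 2000 loci × 500 bp under JC69, and estimate γ back from
site patterns:

```python
from phylodiscord import coalsim, invariants

network, sample, loci = coalsim.xanthoceras_scenario(
    gamma=0.16, n_loci=2000, sites_per_locus=500, seed=1)
quartet = invariants.QuartetAssignment("P1", "H", "P2", "O")
counts = [invariants.count_site_patterns(a, quartet) for a in loci]
result = invariants.z_test(counts, b=200, seed=1)
c = result.counts
print(f"pooled counts: BBAA={c.n_bbaa} ABBA={c.n_abba} "
      f"BABA={c.n_baba} (of {c.n_used} sites)")
print(f"gamma_hat = {result.gamma:.3f} +/- {result.se:.3f}  "
      f"Z = {result.z:.1f}  p = {result.p:.2e}")
```

which prints

```
pooled counts: BBAA=16774 ABBA=5750 BABA=3453 (of 1000000 sites)
gamma_hat = 0.147 +/- 0.022  Z = 6.7  p = 7.74e-12
```

BBAA sites (P1 and H share the derived allele) dominate because H is
sister to P1 for 84% of its genome; the excess of ABBA (H with P2) over
BABA (P1 with P2) is the introgression signal, and the point estimate
0.147 recovers the simulated γ = 0.16 to within its bootstrap SE.  The
same study end-to-end, including the discordance tests and the triplet
mixture fits, runs as

```
phylodiscord demo --gamma 0.16 --seed 1 --out-dir out/
```

## Documentation

`docs/methods.md` describes the models, the estimators, every tunable
parameter with its default, and the limits of what the synthetic
scenarios can show.
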