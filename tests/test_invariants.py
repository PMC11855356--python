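"""Site-pattern counting, gamma estimation, bootstrap Z-test, triple scan."""

import math

import numpy as np
import pytest

from phylodiscord import coalsim
from phylodiscord.invariants import (
    QuartetAssignment,
    SitePatternCounts,
    count_site_patterns,
    estimate_gamma,
    evaluate_quartet,
    heatmap_matrix,
    passes_filter,
    pool_counts,
    results_table,
    triple_scan,
    z_test,
)
from phylodiscord.treekit import Alignment

Q = QuartetAssignment("P1", "H", "P2", "O")


def _aln(p1, h, p2, o):
    return Alignment.from_rows([("P1", p1), ("H", h), ("P2", p2), ("O", o)])


def _brute_classify(site):
    """Independent single-site oracle: polarize by the outgroup, demand a
    biallelic ingroup trio with exactly two taxa sharing the derived state."""
    p1, h, p2, o = site
    if any(c not in "ACGT" for c in site):
        return "skip"
    derived = [c != o for c in (p1, h, p2)]
    if sum(derived) != 2:
        return "other"
    states = {c for c, d in zip((p1, h, p2), derived) if d}
    if len(states) != 1:
        return "other"
    if not derived[2]:
        return "BBAA"
    if not derived[0]:
        return "ABBA"
    return "BABA"


class TestSitePatternCounting:
    def test_direct_classification_examples(self):
        c = count_site_patterns(_aln("G", "G", "T", "T"), Q)
        assert (c.n_bbaa, c.n_abba, c.n_baba) == (1, 0, 0)
        c = count_site_patterns(_aln("T", "G", "G", "T"), Q)
        assert (c.n_bbaa, c.n_abba, c.n_baba) == (0, 1, 0)
        c = count_site_patterns(_aln("G", "T", "G", "T"), Q)
        assert (c.n_bbaa, c.n_abba, c.n_baba) == (0, 0, 1)

    def test_gaps_and_ambiguity_skip_site(self):
        c = count_site_patterns(_aln("G-", "NN", "TT", "TT"), Q)
        assert c.n_used == 0

    def test_matches_sitewise_brute_force(self, rng):
        chars = np.array(list("ACGT-N"))
        mat = rng.choice(chars, size=(4, 1000), p=[0.3, 0.25, 0.2, 0.15, 0.05, 0.05])
        aln = Alignment.from_rows(
            [(t, "".join(row)) for t, row in zip(("P1", "H", "P2", "O"), mat)]
        )
        c = count_site_patterns(aln, Q)
        tally = {"BBAA": 0, "ABBA": 0, "BABA": 0, "other": 0, "skip": 0}
        for j in range(1000):
            tally[_brute_classify("".join(mat[:, j]))] += 1
        assert c.n_bbaa == tally["BBAA"]
        assert c.n_abba == tally["ABBA"]
        assert c.n_baba == tally["BABA"]
        assert c.n_other == tally["other"]
        assert c.n_used == 1000 - tally["skip"]

    def test_missing_taxon_named_in_error(self, small_alignment):
        with pytest.raises(KeyError, match="P1"):
            count_site_patterns(small_alignment, Q)


class TestGammaEstimator:
    def test_null_symmetry_gives_zero(self):
        c = SitePatternCounts(500, 120, 120, 260, 1000)
        assert estimate_gamma(c) == 0.0

    def test_worked_mixture_example(self):
        # C=0.8, d=0.1, gamma=0.16 => f = (0.688, 0.212, 0.100)
        c = SitePatternCounts(6880, 2120, 1000, 0, 10000)
        assert estimate_gamma(c) == pytest.approx(0.16)

    def test_parent_swap_gives_one(self):
        c = SitePatternCounts(1000, 3000, 1000, 5000, 10000)
        assert estimate_gamma(c) == pytest.approx(1.0)

    def test_zero_denominator_yields_nan(self):
        c = SitePatternCounts(100, 200, 150, 550, 1000)
        assert math.isnan(estimate_gamma(c))

    def test_exact_on_mixture_identity(self, rng):
        # f_BBAA=(1-g)C+gd, f_ABBA=(1-g)d+gC, f_BABA=d  =>  gamma_hat == g
        for _ in range(100):
            c_ = rng.uniform(0.1, 0.4)
            d_ = rng.uniform(0.005, min(c_ * 0.9, (1 - c_) / 2 * 0.9))
            g = rng.uniform(0, 1)
            n = 10**7
            counts = SitePatternCounts(
                ((1 - g) * c_ + g * d_) * n, ((1 - g) * d_ + g * c_) * n, d_ * n,
                n - (c_ + 2 * d_) * n, n,
            )
            assert estimate_gamma(counts) == pytest.approx(g, abs=1e-12)


class TestZTest:
    def test_symmetric_null_gives_z_zero(self):
        c = SitePatternCounts(4000, 1000, 1000, 4000, 10000)
        r = z_test(c, b=200, seed=1)
        assert r.z == 0.0
        assert r.p == pytest.approx(0.5)

    def test_strong_signal_passes_filter(self):
        # the gamma=0.16 worked example scaled to 10k sites
        c = SitePatternCounts(6880, 2120, 1000, 0, 10000)
        r = z_test(c, b=1000, seed=3)
        assert r.gamma == pytest.approx(0.16)
        assert r.z > 3 and r.p < 0.05
        assert passes_filter(r)

    def test_bootstrap_deterministic(self):
        c = SitePatternCounts(6880, 2120, 1000, 0, 10000)
        assert z_test(c, b=200, seed=9).se == z_test(c, b=200, seed=9).se
        assert z_test(c, b=200, seed=9).se != z_test(c, b=200, seed=10).se

    def test_locus_bootstrap_path(self):
        per_locus = [SitePatternCounts(70, 20, 10, 900, 1000) for _ in range(30)]
        r = z_test(per_locus, b=200, seed=5)
        assert r.counts == pool_counts(per_locus)
        assert r.gamma == pytest.approx(estimate_gamma(r.counts))
        assert r.se >= 0

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            z_test(SitePatternCounts(1, 1, 1, 1, 4), b=10, seed=0)


@pytest.fixture(scope="module")
def scenario_loci():
    _, _, alns = coalsim.xanthoceras_scenario(
        0.16, n_loci=500, sites_per_locus=500, seed=101
    )
    return alns


class TestTripleScan:

    def test_three_ingroup_taxa_three_results(self, scenario_loci):
        res = triple_scan(scenario_loci, outgroup="O", seed=2)
        assert len(res) == 3
        assert sorted(r.quartet.h for r in res) == ["H", "P1", "P2"]

    def test_combinatorial_count_five_taxa(self, rng):
        taxa = list("ABCDEO")
        mat = rng.choice(np.array(list("ACGT")), size=(6, 400))
        aln = Alignment.from_rows([(t, "".join(row)) for t, row in zip(taxa, mat)])
        res = triple_scan(aln, outgroup="O", b=50, seed=4)
        assert len(res) == 3 * math.comb(5, 3)

    def test_canonicalized_gamma_nonnegative_or_swapped(self, scenario_loci):
        for r in triple_scan(scenario_loci, outgroup="O", seed=2):
            if math.isfinite(r.gamma) and not r.swapped:
                assert r.gamma >= 0

    def test_hybrid_flagged_with_donor(self, scenario_loci):
        res = triple_scan(scenario_loci, outgroup="O", seed=2)
        flagged = {r.quartet.h for r in res if passes_filter(r)}
        assert "H" in flagged
        (hit,) = [r for r in res if r.quartet.h == "H"]
        assert hit.quartet.p2 in {"P1", "P2"}
        assert hit.gamma == pytest.approx(0.16, abs=0.06)

    def test_results_table_schema(self, scenario_loci):
        tab = results_table(triple_scan(scenario_loci, outgroup="O", seed=2))
        assert list(tab.columns) == [
            "P1", "H", "P2", "gamma", "SE", "Z", "p",
            "nBBAA", "nABBA", "nBABA", "n_used", "swapped", "passed_filter",
        ]
        assert len(tab) == 3


class TestEndToEndRecovery:
    @pytest.mark.parametrize("gamma", [0.0, 0.16, 0.5, 1.0])
    def test_scenario_gamma_recovery(self, gamma):
        ests = []
        for seed in (1, 2, 3):
            _, _, alns = coalsim.xanthoceras_scenario(
                gamma, n_loci=2000, sites_per_locus=500, seed=seed
            )
            counts = pool_counts([count_site_patterns(a, Q) for a in alns])
            ests.append(estimate_gamma(counts))
        assert np.mean(ests) == pytest.approx(gamma, abs=0.03)


class TestHeatmap:
    def _result(self, p1, h, p2, gamma, z=10.0, p=1e-6):
        c = SitePatternCounts(100, 50, 10, 840, 1000)
        from phylodiscord.invariants import InvariantsResult

        return InvariantsResult(QuartetAssignment(p1, h, p2, "O"), gamma, 0.01, z, p, c)

    def test_no_significant_results_all_missing(self):
        res = [self._result("A", "B", "C", 0.2, z=1.0, p=0.4)]
        mat = heatmap_matrix(res, hybrid="B", leaf_order=["A", "B", "C"])
        assert mat.isna().all().all()

    def test_single_passing_triple_single_cell(self):
        res = [self._result("A", "B", "C", 0.2)]
        mat = heatmap_matrix(res, hybrid="B", leaf_order=["A", "B", "C"])
        assert mat.loc["A", "C"] == pytest.approx(0.2)
        assert mat.notna().sum().sum() == 1

    def test_absent_hybrid_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            mat = heatmap_matrix([], hybrid="X", leaf_order=["A", "B"])
        assert mat.isna().all().all()
        assert "no results" in caplog.text
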