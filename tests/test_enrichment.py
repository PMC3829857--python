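"""Rank-based enrichment: ranking, area statistic, Fisher, DEM calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, kstest, mannwhitneyu

from psormod.datatypes import GeneModule
from psormod.enrichment import (
    RankedGeneList,
    annotation_enrichment,
    call_dems,
    drc_area,
    fisher_overlap,
    rank_by_signed_logp,
    trait_overlap,
)
from tests.conftest import enumerate_ranksum_p


def _ranking(n, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in rng.permutation(n)]
    scores = np.sort(rng.normal(size=n))[::-1]
    return RankedGeneList(genes=genes,
                          score=dict(zip(genes, scores.tolist())))


class TestRanking:
    def test_signed_logp_scores(self):
        stats = pd.DataFrame(
            {"p": [0.01, 0.5, 0.01], "direction": [1, 1, -1]},
            index=["a", "b", "c"],
        )
        ranking = rank_by_signed_logp(stats)
        assert ranking.genes == ["a", "b", "c"]
        assert ranking.score["a"] == pytest.approx(2.0)
        assert ranking.score["b"] == pytest.approx(np.log10(2), abs=1e-3)
        assert ranking.score["c"] == pytest.approx(-2.0)

    def test_all_p_one_orders_by_gene_id(self):
        stats = pd.DataFrame({"p": [1.0, 1.0, 1.0], "direction": [1, -1, 1]},
                             index=["c", "a", "b"])
        ranking = rank_by_signed_logp(stats)
        assert ranking.genes == ["a", "b", "c"]
        assert all(s == 0 for s in ranking.score.values())

    def test_zero_p_clamped_with_warning(self):
        stats = pd.DataFrame({"p": [0.0, 0.5], "direction": [1, 1]},
                             index=["a", "b"])
        with pytest.warns(UserWarning, match="clamped"):
            ranking = rank_by_signed_logp(stats)
        assert ranking.genes[0] == "a"
        assert np.isfinite(ranking.score["a"])


class TestDrcArea:
    def test_exact_small_case(self):
        ranking = _ranking(10)
        fore = set(ranking.genes[:3])
        res = drc_area(ranking, fore)
        assert res.area > 0
        assert res.p == pytest.approx(2.0 / 120.0)
        assert res.p == pytest.approx(enumerate_ranksum_p([1, 2, 3], 10))

    def test_centered_foreground_balanced(self):
        ranking = _ranking(10)
        fore = set(ranking.genes[3:7])  # ranks 4..7
        res = drc_area(ranking, fore)
        assert abs(res.area) < 0.05
        assert res.p == 1.0

    def test_p_matches_independent_ranksum(self, rng):
        for _ in range(25):
            n = int(rng.integers(20, 120))
            k = int(rng.integers(2, min(n - 2, 30)))
            ranking = _ranking(n, seed=int(rng.integers(1e6)))
            fore = set(rng.choice(ranking.genes, size=k, replace=False))
            res = drc_area(ranking, fore)
            fore_ranks = ranking.ranks_of(fore)
            back_ranks = np.setdiff1d(np.arange(1, n + 1), fore_ranks)
            method = "exact" if min(k, n - k) <= 12 else "asymptotic"
            ref = mannwhitneyu(fore_ranks, back_ranks,
                               alternative="two-sided", method=method,
                               use_continuity=True).pvalue
            assert res.p == pytest.approx(ref, rel=1e-9)

    def test_antisymmetry_under_ranking_reversal(self, rng):
        ranking = _ranking(50, seed=3)
        fore = set(rng.choice(ranking.genes, size=8, replace=False))
        res = drc_area(ranking, fore)
        reversed_ranking = RankedGeneList(
            genes=list(reversed(ranking.genes)),
            score={g: -s for g, s in ranking.score.items()},
        )
        rev = drc_area(reversed_ranking, fore)
        assert rev.area == pytest.approx(-res.area)
        assert rev.p == pytest.approx(res.p)

    def test_invariant_to_monotone_score_transform(self):
        # p and area depend on ranks only; the score values are irrelevant
        ranking = _ranking(40, seed=5)
        fore = set(ranking.genes[:6])
        transformed = RankedGeneList(
            genes=ranking.genes,
            score={g: np.exp(s) for g, s in ranking.score.items()},
        )
        a, b = drc_area(ranking, fore), drc_area(transformed, fore)
        assert a.p == b.p and a.area == b.area

    def test_null_p_uniform(self, rng):
        pvals = []
        for _ in range(400):
            ranking = _ranking(60, seed=int(rng.integers(1e9)))
            fore = set(rng.choice(ranking.genes, size=15, replace=False))
            pvals.append(drc_area(ranking, fore).p)
        assert kstest(pvals, "uniform").pvalue > 1e-3

    def test_degenerate_foregrounds_rejected(self):
        ranking = _ranking(10)
        with pytest.raises(ValueError):
            drc_area(ranking, set())
        with pytest.raises(ValueError):
            drc_area(ranking, set(ranking.genes))


class TestFisherOverlap:
    def test_exact_value_against_hypergeometric_enumeration(self):
        universe = {f"u{i}" for i in range(100)}
        fore = set(list(universe)[:10])
        rest = sorted(universe - fore)
        anno = set(list(fore)[:5]) | set(rest[:5])
        oddsr, p = fisher_overlap(fore, anno, universe)
        # two-sided: sum of table probabilities <= that of the observed table
        probs = [hypergeom.pmf(k, 100, 10, 10) for k in range(11)]
        expected = sum(q for q in probs if q <= probs[5] + 1e-12)
        assert p == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(6.716e-4, rel=1e-3)
        assert oddsr > 1

    def test_expected_overlap_gives_or_near_one(self):
        universe = {f"u{i}" for i in range(1000)}
        ordered = sorted(universe)
        fore = set(ordered[:100])
        anno = set(ordered[90:190])  # overlap 10 = 100*100/1000
        oddsr, p = fisher_overlap(fore, anno, universe)
        assert 0.5 < oddsr < 2.0
        assert p > 0.5

    def test_degenerate_full_annotation(self):
        universe = {"a", "b", "c", "d"}
        _, p = fisher_overlap({"a", "b"}, universe, universe)
        assert p == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap({"a"}, {"a"}, set())


class TestCallDems:
    def _module(self, mid, members, fc):
        m = GeneModule(module_id=mid, members=members)
        m.fc_score = fc
        return m

    def _gsea(self, p, area=0.1):
        from psormod.enrichment import GseaResult

        return GseaResult(area=area, p=p,
                          direction="increased" if area >= 0 else "decreased",
                          n_fore=10, n_back=90)

    def test_gsea_fc_route(self):
        universe = {f"u{i}" for i in range(100)}
        members = sorted(universe)[:30]
        mods = [self._module("M1", members, 1.30)]
        calls = call_dems(mods, {"M1": self._gsea(0.01)}, set(), set(), universe)
        assert calls[0].is_dem and calls[0].route == "gsea_fc"
        assert calls[0].direction == "increased"

    def test_both_gates_fail(self):
        universe = {f"u{i}" for i in range(100)}
        members = sorted(universe)[:30]
        mods = [self._module("M1", members, 1.10)]
        calls = call_dems(mods, {"M1": self._gsea(0.01)}, set(), set(), universe)
        assert not calls[0].is_dem and calls[0].route is None

    def test_boundary_fcs_are_strict(self):
        universe = {f"u{i}" for i in range(100)}
        members = sorted(universe)[:30]
        for fc in (1.25, 0.80):
            mods = [self._module("M1", members, fc)]
            calls = call_dems(mods, {"M1": self._gsea(0.0001)}, set(), set(),
                              universe)
            assert not calls[0].is_dem

    def test_fisher_proportion_route(self):
        universe = {f"u{i:03d}" for i in range(200)}
        ordered = sorted(universe)
        members = ordered[:40]
        deg_up = set(ordered[:30])  # 30/40 members are DEGs
        mods = [self._module("M1", members, 1.05)]
        calls = call_dems(mods, {"M1": self._gsea(0.5, area=0.01)}, deg_up,
                          set(), universe)
        assert calls[0].is_dem
        assert calls[0].route == "fisher_proportion"
        assert calls[0].direction == "increased"

    def test_planted_biased_modules_recovered(self, rng):
        # 20 modules; 3 with biased fold-change scores and rankings
        n_genes = 600
        genes = [f"g{i:04d}" for i in range(n_genes)]
        modules = []
        for k in range(20):
            members = genes[k * 30 : (k + 1) * 30]
            modules.append(GeneModule(module_id=f"M{k+1}", members=members))
        biased = {"M1", "M2", "M3"}
        p = rng.uniform(0.001, 1.0, n_genes)
        direction = rng.choice([-1, 1], n_genes)
        for k in range(3):  # biased modules: strongly increased
            sl = slice(k * 30, (k + 1) * 30)
            p[sl] = rng.uniform(1e-8, 1e-4, 30)
            direction[sl] = 1
        stats = pd.DataFrame({"p": p, "direction": direction}, index=genes)
        ranking = rank_by_signed_logp(stats)
        gsea = {m.module_id: drc_area(ranking, set(m.members)) for m in modules}
        for m in modules:
            m.fc_score = 1.6 if m.module_id in biased else 1.0
        calls = call_dems(modules, gsea, set(), set(), set(genes))
        called = {c.module_id for c in calls if c.is_dem}
        assert called == biased


class TestAnnotationAndTraits:
    def test_identical_term_is_most_significant(self):
        universe = {f"u{i}" for i in range(100)}
        members = set(sorted(universe)[:20])
        terms = {"self": set(members), "other": set(sorted(universe)[50:70])}
        out = annotation_enrichment(members, terms, universe)
        assert out["p"].idxmin() == "self"

    def test_disjoint_term_p_one(self):
        universe = {f"u{i}" for i in range(50)}
        members = set(sorted(universe)[:10])
        terms = {"disjoint": set(sorted(universe)[30:40])}
        out = annotation_enrichment(members, terms, universe)
        assert out.loc["disjoint", "p"] == pytest.approx(1.0)

    def test_null_annotation_fdr_controlled(self, rng):
        universe = {f"u{i}" for i in range(300)}
        ordered = sorted(universe)
        flagged = 0
        total = 0
        for _ in range(20):
            members = set(rng.choice(ordered, 30, replace=False))
            terms = {
                f"t{j}": set(rng.choice(ordered, 25, replace=False))
                for j in range(25)
            }
            out = annotation_enrichment(members, terms, universe)
            flagged += int((out["q"] < 0.05).sum() > 0)
            total += 1
        assert flagged / total <= 0.15

    def test_trait_overlap_planted_signal(self, rng):
        universe = {f"u{i:03d}" for i in range(500)}
        ordered = sorted(universe)
        deg = set(ordered[:50])
        trait_map = {"planted": set(ordered[:30]) | set(ordered[100:120])}
        for j in range(20):
            trait_map[f"null{j}"] = set(rng.choice(ordered, 50, replace=False))
        out = trait_overlap(deg, trait_map, universe)
        assert out.index[0] == "planted"
        assert out.loc["planted", "q"] < 0.05
        assert "u000" in out.loc["planted", "overlap_genes"]

    def test_trait_p_equals_fisher_componentwise(self, rng):
        universe = {f"u{i}" for i in range(200)}
        ordered = sorted(universe)
        deg = set(ordered[:40])
        trait_map = {
            f"t{j}": set(rng.choice(ordered, 30, replace=False))
            for j in range(5)
        }
        out = trait_overlap(deg, trait_map, universe)
        for trait, genes in trait_map.items():
            _, p = fisher_overlap(deg, genes, universe)
            assert out.loc[trait, "p"] == pytest.approx(p)
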