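"""Weighted-KS enrichment: oracle agreement, NES calibration, annotation."""

import numpy as np
import pandas as pd
import pytest

from fgf21cohort.enrichment import (
    annotate_panels,
    enrich_collection,
    enrichment_score,
    marker_enrichment,
    nes_and_p,
    rank_genes,
)
from fgf21cohort.errors import EmptyOverlapError, FullCoverageError
from fgf21cohort.io import GeneSetCollection


def brute_force_es(scores_desc, hit_flags, weight=1.0):
    """Independent running-sum oracle: plain Python walk, no shortcuts."""
    n = len(scores_desc)
    n_h = sum(hit_flags)
    total = sum(abs(s) ** weight for s, h in zip(scores_desc, hit_flags) if h)
    running = []
    acc = 0.0
    for s, h in zip(scores_desc, hit_flags):
        if h:
            acc += (abs(s) ** weight / total) if total > 0 else 1.0 / n_h
        else:
            acc -= 1.0 / (n - n_h)
        running.append(acc)
    best = max(running, key=abs)
    return best


def _ranked(scores, genes=None):
    genes = genes or [chr(ord("a") + i) for i in range(len(scores))]
    return rank_genes(pd.Series(scores, index=genes, dtype=float))


class TestEnrichmentScore:
    def test_single_top_hit_drives_es_to_one(self):
        ranked = _ranked([4, 3, 2, 1])
        es, _ = enrichment_score(ranked, {"a"})
        assert es == pytest.approx(1.0)

    def test_single_bottom_hit_unweighted(self):
        """Running sum -1/3, -2/3, -1, 0: the signed max deviation is -1."""
        ranked = _ranked([4, 3, 2, 1])
        es, running = enrichment_score(ranked, {"d"}, weight=0)
        np.testing.assert_allclose(running, [-1 / 3, -2 / 3, -1.0, 0.0])
        assert es == pytest.approx(-1.0)

    def test_five_gene_walk_matches_oracle(self):
        ranked = _ranked([5, 4, 3, 2, 1])
        es, _ = enrichment_score(ranked, {"a", "c"}, weight=1)
        oracle = brute_force_es([5, 4, 3, 2, 1], [1, 0, 1, 0, 0], weight=1)
        assert es == pytest.approx(oracle)
        assert oracle == pytest.approx(2 / 3)

    def test_weight_zero_walk_ends_at_zero_and_es_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(3, 12)
            scores = rng.normal(size=n)
            k = rng.integers(1, n)
            ranked = _ranked(list(scores), [f"g{i}" for i in range(n)])
            members = list(rng.choice(ranked.index, size=k, replace=False))
            es, running = enrichment_score(ranked, members, weight=0)
            assert -1 - 1e-12 <= es <= 1 + 1e-12
            assert abs(running[-1]) < 1e-12

    def test_empty_overlap_and_full_coverage_are_distinct_errors(self):
        ranked = _ranked([3, 2, 1])
        with pytest.raises(EmptyOverlapError):
            enrichment_score(ranked, {"zzz"})
        with pytest.raises(FullCoverageError):
            enrichment_score(ranked, {"a", "b", "c"})

    def test_tie_break_is_deterministic_by_gene_id(self):
        ranked = _ranked([1.0, 1.0, 1.0, 0.5], ["d", "b", "a", "c"])
        assert list(ranked.index) == ["a", "b", "d", "c"]


class TestNes:
    def test_degenerate_null_gives_nes_one_and_p_one(self):
        """When the observed ES equals every same-sign permutation ES the
        add-one rule yields NES = 1 and p = 1."""
        ranked = _ranked([2, 1])
        es, _ = enrichment_score(ranked, {"a"})
        res = nes_and_p(es, ranked, {"a"}, n_perm=100, seed=0)
        assert res.nes == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)
        assert not res.pass_abs

    def test_planted_top_loaded_set_passes(self):
        """A set planted at the top of the ranking passes |NES|>1, p<.05 in
        >= 95% of seeds."""
        passes = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = rng.normal(0, 1, 300)
            scores[:15] += 3.0
            ranked = _ranked(list(scores), [f"g{i}" for i in range(300)])
            planted = [f"g{i}" for i in range(15)]
            es, _ = enrichment_score(ranked, planted)
            res = nes_and_p(es, ranked, planted, n_perm=200, seed=seed)
            passes += res.pass_abs
        assert passes / 20 >= 0.95

    def test_decoy_set_pass_rate_is_controlled(self):
        """Random sets on a null ranking pass at <= 5% + MC error."""
        passes = 0
        n_trials = 200
        rng = np.random.default_rng(99)
        scores = rng.normal(0, 1, 300)
        ranked = _ranked(list(scores), [f"g{i}" for i in range(300)])
        for t in range(n_trials):
            decoy = list(rng.choice(ranked.index, size=15, replace=False))
            es, _ = enrichment_score(ranked, decoy)
            res = nes_and_p(es, ranked, decoy, n_perm=200, seed=1000 + t)
            passes += res.pass_abs
        rate = passes / n_trials
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_trials)

    def test_permutation_p_is_seed_stable_within_mc_error(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(0, 1, 200)
        ranked = _ranked(list(scores), [f"g{i}" for i in range(200)])
        members = [f"g{i}" for i in range(0, 200, 10)]
        es, _ = enrichment_score(ranked, members)
        ps = [nes_and_p(es, ranked, members, n_perm=500, seed=s).p
              for s in range(6)]
        spread = max(ps) - min(ps)
        assert spread < 4 * np.sqrt(0.25 / 500) * 2  # loose binomial band


class TestMarkerEnrichment:
    def test_requires_immune_marker_category(self):
        coll = GeneSetCollection(sets={"m": ["a"]}, category="pathway")
        with pytest.raises(ValueError):
            marker_enrichment(pd.Series([1.0], index=["a"]), coll)

    def test_disjoint_marker_set_is_reported_as_empty_overlap(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.normal(size=50),
                           index=[f"g{i}" for i in range(50)])
        coll = GeneSetCollection(
            sets={"macrophage": [f"g{i}" for i in range(5)],
                  "alien": ["zz1", "zz2"]},
            category="immune_marker",
        )
        frame = marker_enrichment(scores, coll, n_perm=100, seed=0)
        assert frame.loc["alien", "note"] == "empty overlap"
        assert not frame.loc["alien", "applicable_pass"]

    def test_upregulated_marker_program_passes_signed_rule(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(0, 1, 300)
        scores[:20] += 3.0
        series = pd.Series(scores, index=[f"g{i}" for i in range(300)])
        coll = GeneSetCollection(
            sets={"macrophage_markers": [f"g{i}" for i in range(20)]},
            category="immune_marker",
        )
        frame = marker_enrichment(series, coll, n_perm=300, seed=3)
        assert bool(frame.loc["macrophage_markers", "pass_signed"])
        assert bool(frame.loc["macrophage_markers", "applicable_pass"])


class TestAnnotatePanels:
    def _panels(self):
        return GeneSetCollection(
            sets={"collagens": ["COL1A1", "COL3A1"],
                  "proteoglycans": ["DCN"],
                  "ecm_regulators": ["MMP9", "COL1A1"]},
            category="matrisome",
        )

    def test_membership_and_unannotated_labels(self):
        annotation, counts = annotate_panels(
            ["COL1A1", "DCN", "ACTB"], self._panels()
        )
        assert annotation.loc["COL1A1", "panels"] == "collagens;ecm_regulators"
        assert annotation.loc["DCN", "panels"] == "proteoglycans"
        assert annotation.loc["ACTB", "panels"] == "unannotated"

    def test_counts_sum_to_gene_panel_memberships(self):
        genes = ["COL1A1", "COL3A1", "DCN", "MMP9", "ACTB"]
        annotation, counts = annotate_panels(genes, self._panels())
        memberships = sum(
            len(p.split(";")) for p in annotation["panels"] if p != "unannotated"
        )
        assert counts.sum() == memberships == 5


def test_enrich_collection_selects_rule_by_category(strong_cohort):
    """On planted cohort data: pathway sets use |NES|>1, marker sets NES>1."""
    from fgf21cohort.dge import call_degs
    from fgf21cohort.simulate import generate_gene_sets
    from fgf21cohort.stratify import control_reference

    config, expr, meta, truth = strong_cohort
    ref = control_reference(expr, meta)
    up = truth.patient_strata.index[truth.patient_strata == "up"]
    genes = list(truth.gene_programs["gene_id"]) + \
        [g for g in expr.index if g.startswith("G")][-300:]
    table = call_degs(expr.loc[sorted(set(genes))], meta, up, ref)
    sets = generate_gene_sets(config)
    frame = enrich_collection(table["signed_fc"], sets, n_perm=200, seed=0)
    assert bool(frame.loc["autophagy", "applicable_pass"])
    assert not bool(frame.loc["decoy_autophagy", "applicable_pass"])
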