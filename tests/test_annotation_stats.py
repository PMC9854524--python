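"""GO classification, hypergeometric enrichment, BH-FDR, taxonomy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slimscan.annotation_stats import (
    TAXON_CATEGORIES,
    bh_fdr,
    classify_terms,
    enrich,
    taxon_profile,
)
from slimscan.seq_io import AnnotationTable
from slimscan.synthetic import GOTermSpec, SyntheticConfig, generate_database
from oracles import hypergeom_upper_tail


def make_table(rows):
    """rows: accession -> (gene, taxon, [(term, ns), ...])"""
    table = AnnotationTable()
    for acc, (gene, taxon, terms) in rows.items():
        table.add(acc, gene, taxon, terms)
    return table


class TestClassify:
    def test_distinct_gene_counts(self):
        table = make_table({
            "g1": ("g1", "bacteria", [("T1", "MF"), ("T2", "BP")]),
            "g2": ("g2", "bacteria", [("T1", "MF")]),
        })
        ranked = classify_terms(["g1", "g2"], table)
        assert ranked == [(("T1", "MF"), 2), (("T2", "BP"), 1)]

    def test_gene_counted_once_per_term(self):
        # duplicate annotation collapses because terms are a set
        table = make_table({"g1": ("g1", "bacteria", [("T1", "MF"),
                                                      ("T1", "MF")])})
        assert classify_terms(["g1"], table) == [(("T1", "MF"), 1)]

    def test_ranking_descending_ties_alphabetical(self):
        table = make_table({
            "g1": ("g1", "bacteria", [("TB", "MF"), ("TA", "MF")]),
            "g2": ("g2", "bacteria", [("TC", "BP")]),
        })
        ranked = classify_terms(["g1", "g2"], table)
        assert ranked == [(("TA", "MF"), 1), (("TB", "MF"), 1),
                          (("TC", "BP"), 1)]

    def test_empty_study_rejected(self):
        with pytest.raises(ValueError):
            classify_terms([], make_table({}))


def _enrichment_table(n_bg, k_term, n_study):
    """Background of n_bg genes; first k_term carry T1; study is the
    first n_study genes."""
    rows = {}
    for i in range(n_bg):
        terms = [("T1", "MF")] if i < k_term else []
        rows[f"g{i}"] = (f"g{i}", "bacteria", terms)
    return make_table(rows), [f"g{i}" for i in range(n_study)], \
        [f"g{i}" for i in range(n_bg)]


class TestEnrich:
    def test_hand_worked_hypergeometric(self):
        # N=20, K=5, n=6, k=4: p = (C(5,4)C(15,2)+C(5,5)C(15,1))/C(20,6)
        rows = {}
        for i in range(20):
            terms = [("T1", "MF")] if i < 5 else []
            rows[f"g{i}"] = (f"g{i}", "bacteria", terms)
        table = make_table(rows)
        study = [f"g{i}" for i in [0, 1, 2, 3, 5, 6]]  # k=4 of K=5
        background = [f"g{i}" for i in range(20)]
        (result,) = enrich(study, background, table)
        assert result.k == 4 and result.K == 5
        assert result.p_value == pytest.approx(540 / 38760, rel=1e-12)
        assert result.fold_enrichment == pytest.approx((4 / 6) / (5 / 20))

    def test_saturated_term_is_null(self):
        table, study, background = _enrichment_table(12, 12, 12)
        (result,) = enrich(study, background, table)
        assert result.p_value == pytest.approx(1.0)
        assert result.fold_enrichment == pytest.approx(1.0)

    def test_study_outside_background_rejected(self):
        table, study, background = _enrichment_table(10, 3, 4)
        with pytest.raises(ValueError):
            enrich(study + ["zz"], background, table)

    def test_empty_sets_rejected(self):
        table, study, background = _enrichment_table(10, 3, 4)
        with pytest.raises(ValueError):
            enrich([], background, table)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.data())
    def test_pvalue_matches_enumeration(self, data):
        """Upper-tail probabilities agree with explicit draw counting."""
        N = data.draw(st.integers(6, 25))
        K = data.draw(st.integers(1, N - 1))
        n = data.draw(st.integers(1, min(5, N - 1)))
        table, study, background = _enrichment_table(N, K, n)
        results = enrich(study, background, table)
        if not results:
            return
        (result,) = results
        oracle = hypergeom_upper_tail(N, K, n, result.k)
        assert result.p_value == pytest.approx(oracle, rel=1e-9)

    def test_planted_term_has_smallest_fdr(self):
        """A term planted at fold 4 in a 50-gene study over a 1000-gene
        background dominates the enrichment ranking."""
        rng = np.random.default_rng(5)
        rows = {}
        study = []
        for i in range(1000):
            gene = f"g{i:04d}"
            in_study = i < 50
            terms = []
            for term, ns, p_bg, fold in [
                ("T_planted", "MF", 0.08, 4.0),
                ("T_null1", "MF", 0.15, 1.0),
                ("T_null2", "BP", 0.25, 1.0),
                ("T_null3", "BP", 0.08, 1.0),
            ]:
                p = min(1.0, p_bg * (fold if in_study else 1.0))
                if rng.random() < p:
                    terms.append((term, ns))
            rows[gene] = (gene, "bacteria", terms)
            if in_study:
                study.append(gene)
        table = make_table(rows)
        results = enrich(study, list(rows), table)
        best = min(results, key=lambda r: r.fdr)
        assert best.term == "T_planted"
        assert best.significant


class TestBH:
    def test_closed_form_hand_case(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_bounds_and_permutation_invariance(self, pvals):
        adj = bh_fdr(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        perm = np.random.default_rng(0).permutation(len(pvals))
        adj_perm = bh_fdr(np.asarray(pvals)[perm])
        assert np.allclose(adj_perm, adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestTaxonProfile:
    def test_percentages_from_counts(self):
        rows = {}
        for i in range(100):
            cat = "bacteria" if i < 64 else "human"
            rows[f"g{i}"] = (f"gene{i}", cat, [])
        table = make_table(rows)
        profile = taxon_profile(list(rows), table)
        assert profile.counts["bacteria"] == 64
        assert profile.percentages["bacteria"] == pytest.approx(64.0)

    def test_single_gene_is_100_percent(self):
        table = make_table({"g1": ("gene1", "archaea", [])})
        profile = taxon_profile(["g1"], table)
        assert profile.percentages["archaea"] == 100.0

    def test_all_categories_present_with_zeros(self):
        table = make_table({"g1": ("gene1", "archaea", [])})
        profile = taxon_profile(["g1"], table)
        assert set(profile.counts) == set(TAXON_CATEGORIES)
        assert profile.counts["algae"] == 0

    def test_ortholog_counts_once_per_category(self):
        table = make_table({
            "a1": ("ccmE", "bacteria", []),
            "a2": ("ccmE", "bacteria", []),
            "a3": ("ccmE", "archaea", []),
        })
        profile = taxon_profile(["a1", "a2", "a3"], table)
        assert profile.counts["bacteria"] == 1
        assert profile.counts["archaea"] == 1

    def test_unknown_category_rejected(self):
        table = AnnotationTable()
        table.add("g1", "gene1", "martians", [])
        with pytest.raises(ValueError, match="unknown taxon"):
            taxon_profile(["g1"], table)


class TestSyntheticEnrichmentCalibration:
    def test_generator_fold_converges(self):
        """Empirical fold of a planted term over replicates approaches
        the configured fold within a 3-SE band."""
        catalog = (GOTermSpec("T1", "MF", 0.10, 3.0),)
        folds = []
        for seed in (1, 2, 3):
            config = SyntheticConfig(
                n_proteins=400, length_mean=80.0, length_sd=10.0,
                planting_rate=0.5, go_catalog=catalog, seed=seed,
            )
            _, table, truth = generate_database(config)
            planted = truth.proteins.planted.values
            has_term = np.array([
                ("T1", "MF") in table.go_terms(acc)
                for acc in truth.proteins.accession
            ])
            p_planted = has_term[planted].mean()
            p_bg = has_term[~planted].mean()
            folds.append(p_planted / p_bg)
        mean_fold = np.mean(folds)
        se = np.std(folds, ddof=1) / np.sqrt(len(folds))
        assert abs(mean_fold - 3.0) <= max(3 * se, 0.75)
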