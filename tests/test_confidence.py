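"""Keyword scoring, confidence combination, ROC and weight sweep."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from granulekit.confidence import (
    AnnotationCatalog,
    ConfidenceWeights,
    LabelledSet,
    build_score_table,
    confidence,
    rank_and_flag,
    raw_scores,
    roc_auc,
    score_all,
    sweep_weights,
)


class TestScoreTable:
    def test_fractions_match_exhaustive_hand_count(self, tiny_catalog):
        catalog, labels = tiny_catalog
        table = build_score_table(catalog, labels, "location")
        # 'ves': 2/3 positives, 1/3 negatives; 'nuc': 0/3 vs 2/3
        assert table.loc["ves", "frac_pos"] == pytest.approx(2 / 3)
        assert table.loc["ves", "frac_neg"] == pytest.approx(1 / 3)
        assert table.loc["ves", "score"] == pytest.approx(1 / 3)
        assert table.loc["nuc", "score"] == pytest.approx(-2 / 3)

    def test_keyword_exclusive_to_positives_scores_one(self):
        loc = {"a": frozenset({"kw"}), "b": frozenset({"kw"}), "c": frozenset()}
        catalog = AnnotationCatalog(
            loc=loc,
            intloc={k: () for k in loc},
            proteomes={k: frozenset({"P1"}) for k in loc},
        )
        labels = LabelledSet(frozenset({"a", "b"}), frozenset({"c"}))
        table = build_score_table(catalog, labels, "location")
        assert table.loc["kw", "score"] == 1.0

    def test_scores_bounded_and_negative_for_negative_only_keywords(self, tiny_catalog):
        catalog, labels = tiny_catalog
        for flavour in ("location", "interactor"):
            table = build_score_table(catalog, labels, flavour)
            assert ((table["score"] >= -1) & (table["score"] <= 1)).all()
        table = build_score_table(catalog, labels, "location")
        assert table.loc["nuc", "score"] < 0

    def test_empty_label_side_is_an_error(self, tiny_catalog):
        catalog, _ = tiny_catalog
        with pytest.raises(ValueError):
            build_score_table(
                catalog, LabelledSet(frozenset(), frozenset({"n1"})), "location"
            )


class TestConfidence:
    def test_no_keywords_gives_zero_raw_score(self, tiny_catalog):
        catalog, labels = tiny_catalog
        loc_t = build_score_table(catalog, labels, "location")
        int_t = build_score_table(catalog, labels, "interactor")
        df = raw_scores(catalog, loc_t, int_t)
        assert df.loc["p3", "raw"] == 0.0

    def test_raw_score_linear_in_proteome_count(self):
        # identical keyword evidence, memberships 1 vs 3
        loc = {"a": frozenset({"kw"}), "b": frozenset({"kw"}), "neg": frozenset()}
        catalog = AnnotationCatalog(
            loc=loc,
            intloc={k: () for k in loc},
            proteomes={
                "a": frozenset({"P1"}),
                "b": frozenset({"P1", "P2", "P3"}),
                "neg": frozenset({"P1"}),
            },
        )
        labels = LabelledSet(frozenset({"a", "b"}), frozenset({"neg"}))
        loc_t = build_score_table(catalog, labels, "location")
        int_t = build_score_table(catalog, labels, "interactor")
        df = raw_scores(catalog, loc_t, int_t)
        assert df.loc["b", "raw"] == pytest.approx(3 * df.loc["a", "raw"])

    def test_spreadsheet_style_recomputation_on_fixture(self, tiny_catalog):
        catalog, labels = tiny_catalog
        loc_t = build_score_table(catalog, labels, "location")
        int_t = build_score_table(catalog, labels, "interactor")
        weights = ConfidenceWeights(12.0, 1.0)
        df = score_all(catalog, loc_t, int_t, weights)
        # independent brute-force recomputation
        expected_raw = {}
        for pid in catalog.roster:
            loc_sum = sum(loc_t.loc[k, "score"] for k in catalog.loc[pid])
            int_sum = sum(int_t.loc[k, "score"] for k in catalog.intloc[pid])
            expected_raw[pid] = len(catalog.proteomes[pid]) * (
                12.0 * loc_sum + 1.0 * int_sum
            )
        lo = min(expected_raw.values())
        hi = max(expected_raw.values())
        for pid, raw in expected_raw.items():
            assert df.loc[pid, "raw"] == pytest.approx(raw)
            assert df.loc[pid, "value"] == pytest.approx((raw - lo) / (hi - lo))
        assert df["value"].between(0, 1).all()

    def test_unknown_protein_raises(self, tiny_catalog):
        catalog, labels = tiny_catalog
        loc_t = build_score_table(catalog, labels, "location")
        int_t = build_score_table(catalog, labels, "interactor")
        with pytest.raises(KeyError):
            confidence("absent", catalog, loc_t, int_t)

    def test_invariant_under_protein_relabelling(self, tiny_catalog):
        catalog, labels = tiny_catalog
        loc_t = build_score_table(catalog, labels, "location")
        int_t = build_score_table(catalog, labels, "interactor")
        base = score_all(catalog, loc_t, int_t)

        mapping = {pid: f"x_{pid}" for pid in catalog.roster}
        relabelled = AnnotationCatalog(
            loc={mapping[k]: v for k, v in catalog.loc.items()},
            intloc={mapping[k]: v for k, v in catalog.intloc.items()},
            proteomes={mapping[k]: v for k, v in catalog.proteomes.items()},
        )
        relabels = LabelledSet(
            frozenset(mapping[p] for p in labels.positives),
            frozenset(mapping[p] for p in labels.negatives),
        )
        loc_t2 = build_score_table(relabelled, relabels, "location")
        int_t2 = build_score_table(relabelled, relabels, "interactor")
        again = score_all(relabelled, loc_t2, int_t2)
        for pid in catalog.roster:
            assert again.loc[mapping[pid], "value"] == pytest.approx(
                base.loc[pid, "value"]
            )


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False]) == 1.0

    def test_matches_pair_counting_oracle_on_fixture(self):
        values = [0.1, 0.4, 0.35, 0.8, 0.8, 0.2, 0.55, 0.7]
        labels = [False, True, False, True, False, False, True, True]
        pos = [v for v, l in zip(values, labels) if l]
        neg = [v for v, l in zip(values, labels) if not l]
        u = sum(
            1.0 if p > n else (0.5 if p == n else 0.0)
            for p, n in itertools.product(pos, neg)
        )
        assert roc_auc(values, labels) == pytest.approx(u / (len(pos) * len(neg)))

    def test_random_scores_near_half(self, rng):
        values = rng.random(4000)
        labels = rng.random(4000) < 0.5
        assert roc_auc(values, labels) == pytest.approx(0.5, abs=0.05)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])


class TestSweep:
    def test_single_point_grid(self, tiny_catalog):
        catalog, labels = tiny_catalog
        got = sweep_weights(catalog, labels, [(5.0, 2.0)])
        assert (got.w_loc, got.w_intloc) == (5.0, 2.0)

    def test_no_interactor_keywords_tie_breaks_to_smallest(self):
        loc = {"a": frozenset({"kw"}), "b": frozenset()}
        catalog = AnnotationCatalog(
            loc=loc,
            intloc={k: () for k in loc},
            proteomes={k: frozenset({"P1"}) for k in loc},
        )
        labels = LabelledSet(frozenset({"a"}), frozenset({"b"}))
        grid = [(1.0, w) for w in (0.0, 1.0, 5.0)]
        got = sweep_weights(catalog, labels, grid)
        assert got.w_intloc == 0.0

    def test_recovers_injected_informativeness_ratio(self):
        # location keywords perfectly separate; interactor keywords are noise,
        # so the sweep must favour grid points dominated by w_loc
        from granulekit.synthetic import SyntheticCatalogSpec, generate_catalog

        spec = SyntheticCatalogSpec(
            n_positives=40,
            n_negatives=160,
            keyword_odds={"ves": 40.0, "nuc": 0.05},
            interactor_fidelity=0.5,  # interactor keywords carry no signal
            seed=7,
        )
        catalog, labels = generate_catalog(spec)
        grid = [(w, 1.0) for w in (0.0, 1.0, 4.0, 12.0, 40.0)]
        got = sweep_weights(catalog, labels, grid)
        assert got.w_loc >= 4.0

    def test_perfectly_separating_keyword_reaches_auc_one(self):
        from granulekit.synthetic import SyntheticCatalogSpec, generate_catalog

        spec = SyntheticCatalogSpec(
            n_positives=25,
            n_negatives=100,
            keyword_odds={"marker": np.inf},
            base_rate=0.0,  # the marker never occurs among negatives
            interactor_mean=0.0,
            seed=3,
        )
        catalog, labels = generate_catalog(spec)
        loc_t = build_score_table(catalog, labels, "location")
        int_t = build_score_table(catalog, labels, "interactor")
        df = raw_scores(catalog, loc_t, int_t)
        label_vec = [p in labels.positives for p in catalog.roster]
        assert roc_auc(df["raw"].to_numpy(), label_vec) == 1.0


class TestRankAndFlag:
    @pytest.mark.parametrize(
        "value,n_proteome,flagged",
        [
            (0.334, 1, True),  # strictly above threshold
            (0.333, 1, False),  # boundary is exclusive
            (0.1, 2, True),  # proteome-count route
            (0.1, 1, False),
        ],
    )
    def test_flag_rules(self, value, n_proteome, flagged):
        import pandas as pd

        scores = pd.DataFrame(
            {"value": [value], "n_proteome": [n_proteome],
             "loc_sum": [0.0], "intloc_sum": [0.0]},
            index=pd.Index(["p"], name="id"),
        )
        out = rank_and_flag(scores)
        assert bool(out.loc["p", "flagged"]) is flagged

    def test_sorted_descending_with_lexicographic_ties(self):
        import pandas as pd

        scores = pd.DataFrame(
            {
                "value": [0.5, 0.9, 0.5],
                "n_proteome": [1, 1, 1],
                "loc_sum": 0.0,
                "intloc_sum": 0.0,
            },
            index=pd.Index(["b", "c", "a"], name="id"),
        )
        out = rank_and_flag(scores)
        assert list(out.index) == ["c", "a", "b"]


@given(
    st.lists(
        st.tuples(st.floats(0, 1), st.booleans()), min_size=4, max_size=40
    ).filter(lambda xs: any(l for _, l in xs) and any(not l for _, l in xs))
)
def test_auc_always_in_unit_interval(pairs):
    values = [v for v, _ in pairs]
    labels = [l for _, l in pairs]
    assert 0.0 <= roc_auc(values, labels) <= 1.0
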