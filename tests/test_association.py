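"""Contingency counting, odds ratios, confidence intervals, chi-square."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.contingency_tables import Table2x2

from opiomine.association import (
    DEFAULT_RHOS,
    INF,
    AnalysisConfig,
    ContingencyTable,
    associate,
    association_matrix,
    build_contingency,
    chi_square_test,
    group_mentions_by_post,
    odds_ratio,
    or_confidence_interval,
    pair_events,
    sentence_count_profile,
)
from opiomine.corpus import load_corpus, match_terms, preprocess
from opiomine.synth import default_association_spec, generate_corpus, write_ndjson

from .conftest import make_mention
from .oracles import contingency_bruteforce


def mention(post_id, cls, domain, sent):
    term = {"heroin": "heroin", "Intravenous": "vein", "Smoking": "smoke",
            "Grind": "crush"}.get(cls, cls)
    return make_mention(
        post_id=post_id, term=term, domain=domain, class_label=cls,
        sentence_index=sent,
    )


class TestPairEvents:
    def test_adjacent_sentences_within_rho_one(self):
        pms = [mention("p", "heroin", "substance", 0),
               mention("p", "Intravenous", "roa", 1)]
        assert pair_events(pms, "heroin", "substance", "Intravenous", "roa", 1) == (1, 0, 0)

    def test_distance_above_threshold_gives_separate_events(self):
        pms = [mention("p", "heroin", "substance", 0),
               mention("p", "Intravenous", "roa", 3)]
        assert pair_events(pms, "heroin", "substance", "Intravenous", "roa", 2) == (0, 1, 1)

    def test_whole_post_window(self):
        pms = [mention("p", "heroin", "substance", 0),
               mention("p", "Intravenous", "roa", 3)]
        assert pair_events(pms, "heroin", "substance", "Intravenous", "roa", INF) == (1, 0, 0)

    def test_same_sentence_at_rho_zero(self):
        pms = [mention("p", "heroin", "substance", 2),
               mention("p", "Intravenous", "roa", 2)]
        assert pair_events(pms, "heroin", "substance", "Intravenous", "roa", 0) == (1, 0, 0)

    def test_one_sided_post(self):
        pms = [mention("p", "heroin", "substance", 0)]
        assert pair_events(pms, "heroin", "substance", "Intravenous", "roa", 0) == (0, 1, 0)


class TestBuildContingency:
    def _four_posts(self):
        mentions = [
            mention("joint", "heroin", "substance", 0),
            mention("joint", "Intravenous", "roa", 0),
            mention("aonly", "heroin", "substance", 0),
            mention("bonly", "Intravenous", "roa", 0),
            mention("other", "Grind", "tampering", 0),
            mention("other", "Smoking", "roa", 0),
        ]
        return group_mentions_by_post(mentions)

    def test_one_post_per_cell(self):
        table = build_contingency(
            self._four_posts(), "heroin", "substance", "Intravenous", "roa", 0
        )
        assert table.cells() == (1, 1, 1, 1)

    def test_universe_excludes_out_of_domain_posts(self):
        by_post = group_mentions_by_post(
            [mention("t", "Grind", "tampering", 0)]
            + [m for pms in self._four_posts().values() for m in pms]
        )
        table = build_contingency(
            by_post, "heroin", "substance", "Intravenous", "roa", 0,
        )
        # the tampering-only post is outside the substance/roa universe
        assert table.total == 4

    def test_missing_class_everywhere_is_degenerate(self):
        by_post = group_mentions_by_post([mention("p", "heroin", "substance", 0)])
        table = build_contingency(
            by_post, "heroin", "substance", "Intravenous", "roa", 0
        )
        assert table.degenerate

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError, match="empty universe"):
            build_contingency({}, "heroin", "substance", "Intravenous", "roa", 0)

    def test_both_universe_policy(self):
        table = build_contingency(
            self._four_posts(), "heroin", "substance", "Intravenous", "roa", 0,
            universe="both",
        )
        assert table.total == 1  # only the joint post holds both domains


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_pipeline_tables_match_bruteforce(self, seed, tmp_path, taxonomy):
        spec = default_association_spec(seed=seed, n_posts=150, true_or=3.0)
        lines, _ = generate_corpus(spec)
        path = tmp_path / "c.ndjson"
        write_ndjson(lines, path)
        corpus = preprocess(load_corpus(path), min_lemma_freq=1)
        mentions = match_terms(corpus, taxonomy)
        by_post = group_mentions_by_post(mentions)
        classes = {
            ("heroin", "substance", "Intravenous", "roa"),
            ("heroin", "substance", "Smoking", "roa"),
            ("oxycodone", "substance", "Chew", "roa"),
            ("morphine", "substance", "Intravenous", "roa"),
            ("heroin", "substance", "Grind", "tampering"),
        }
        for ca, da, cb, db in classes:
            for rho in DEFAULT_RHOS:
                table = build_contingency(by_post, ca, da, cb, db, rho)
                assert table.cells() == contingency_bruteforce(
                    by_post, ca, da, cb, db, rho
                ), (ca, cb, rho)


class TestRhoMonotonicity:
    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_event_conservation_across_rho(self, data):
        n_posts = data.draw(st.integers(1, 8))
        mentions = []
        for i in range(n_posts):
            for cls, dom in (("heroin", "substance"), ("Intravenous", "roa")):
                for si in data.draw(
                    st.lists(st.integers(0, 12), max_size=3)
                ):
                    mentions.append(mention(f"p{i}", cls, dom, si))
        if not mentions:
            return
        by_post = group_mentions_by_post(mentions)
        tables = [
            build_contingency(
                by_post, "heroin", "substance", "Intravenous", "roa", rho
            )
            for rho in DEFAULT_RHOS
        ]
        n11s = [t.n11 for t in tables]
        assert n11s == sorted(n11s)  # non-decreasing in rho
        assert len({t.n11 + t.n10 for t in tables}) == 1
        assert len({t.n11 + t.n01 for t in tables}) == 1
        n10s = [t.n10 for t in tables]
        n01s = [t.n01 for t in tables]
        assert n10s == sorted(n10s, reverse=True)
        assert n01s == sorted(n01s, reverse=True)


class TestOddsRatio:
    def test_flat_table_is_one(self):
        assert odds_ratio(ContingencyTable(10, 10, 10, 10))[0] == 1.0

    def test_direct_formula(self):
        or_val, corrected = odds_ratio(ContingencyTable(20, 10, 5, 40))
        assert or_val == 16.0
        assert not corrected

    def test_haldane_correction_on_zero_cell(self):
        or_val, corrected = odds_ratio(ContingencyTable(20, 0, 5, 40))
        assert corrected
        assert or_val == (20.5 * 40.5) / (0.5 * 5.5)

    def test_undefined_policy_raises(self):
        with pytest.raises(ZeroDivisionError):
            odds_ratio(ContingencyTable(20, 0, 5, 40), zero_cell="undefined")

    def test_transpose_invariance(self):
        # swapping the two classes swaps n10/n01: OR unchanged
        a = odds_ratio(ContingencyTable(20, 10, 5, 40))[0]
        b = odds_ratio(ContingencyTable(20, 5, 10, 40))[0]
        assert a == b


class TestConfidenceInterval:
    def test_symmetric_on_log_scale_and_contains_one(self):
        lo, hi = or_confidence_interval(ContingencyTable(10, 10, 10, 10))
        assert lo < 1 < hi
        assert math.isclose(math.log(lo), -math.log(hi), abs_tol=1e-12)

    def test_widens_with_level(self):
        t = ContingencyTable(20, 10, 5, 40)
        widths = []
        for level in (0.80, 0.90, 0.95, 0.99):
            lo, hi = or_confidence_interval(t, level=level)
            widths.append(math.log(hi) - math.log(lo))
        assert widths == sorted(widths)

    def test_matches_statsmodels_woolf(self):
        t = ContingencyTable(20, 10, 5, 40)
        lo, hi = or_confidence_interval(t, level=0.95)
        sm_lo, sm_hi = Table2x2(
            np.array([[20, 10], [5, 40]])
        ).oddsratio_confint(alpha=0.05)
        assert lo == pytest.approx(sm_lo, rel=1e-9)
        assert hi == pytest.approx(sm_hi, rel=1e-9)

    def test_ci_brackets_point_estimate(self):
        t = ContingencyTable(33, 17, 12, 80)
        or_val, _ = odds_ratio(t)
        lo, hi = or_confidence_interval(t)
        assert lo <= or_val <= hi


class TestChiSquare:
    def test_perfect_independence(self):
        stat, p, sig = chi_square_test(ContingencyTable(10, 10, 10, 10))
        assert stat == 0.0
        assert p == pytest.approx(1.0)
        assert not sig

    def test_strong_association_hand_computed(self):
        # all expected cells are 27.5; statistic = 4 * (22.5^2 / 27.5)
        stat, p, sig = chi_square_test(ContingencyTable(50, 5, 5, 50))
        assert stat == pytest.approx(4 * 22.5**2 / 27.5)
        assert p < 0.01
        assert sig

    def test_alpha_threshold_contract(self):
        # p around .02: significant at .05, not at .01
        table = ContingencyTable(30, 20, 18, 32)
        _, p, sig_01 = chi_square_test(table, alpha=0.01)
        _, _, sig_05 = chi_square_test(table, alpha=0.05)
        assert 0.01 < p < 0.05
        assert sig_05 and not sig_01

    def test_zero_margin_flagged(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_test(ContingencyTable(5, 5, 0, 0))


class TestAssociate:
    def test_full_result_consistency(self):
        res = associate(ContingencyTable(20, 10, 5, 40))
        assert res.ci_low <= res.odds_ratio <= res.ci_high
        assert res.significant == (res.p_value < res.alpha)
        assert res.defined

    def test_degenerate_table_reported_not_dropped(self):
        res = associate(ContingencyTable(0, 10, 0, 0))
        assert not res.defined
        assert not res.significant


@pytest.fixture(scope="module")
def planted_grid(tmp_path_factory, taxonomy):
    spec = default_association_spec(seed=11, n_posts=2000, true_or=4.0)
    lines, _ = generate_corpus(spec)
    path = tmp_path_factory.mktemp("assoc") / "c.ndjson"
    write_ndjson(lines, path)
    corpus = preprocess(load_corpus(path), min_lemma_freq=1)
    mentions = match_terms(corpus, taxonomy)
    return mentions, taxonomy


class TestAssociationMatrix:
    def test_planted_pair_has_max_or_and_significant(self, planted_grid):
        mentions, taxonomy = planted_grid
        grid = association_matrix(
            mentions, taxonomy, "substance", "roa",
            AnalysisConfig(rho=INF, year=2018),
        )
        defined = {k: r for k, r in grid.items() if r.defined}
        best = max(defined, key=lambda k: defined[k].odds_ratio)
        assert best == ("heroin", "Intravenous")
        assert defined[best].significant

    def test_n11_monotone_between_rho_zero_and_inf(self, planted_grid):
        mentions, taxonomy = planted_grid
        g0 = association_matrix(
            mentions, taxonomy, "substance", "roa", AnalysisConfig(rho=0, year=2018)
        )
        ginf = association_matrix(
            mentions, taxonomy, "substance", "roa", AnalysisConfig(rho=INF, year=2018)
        )
        for key in g0:
            assert g0[key].table.n11 <= ginf[key].table.n11

    def test_empty_mentions_is_error(self, taxonomy):
        with pytest.raises(ValueError):
            association_matrix([], taxonomy, "substance", "roa")

    def test_low_support_classes_excluded(self, planted_grid):
        mentions, taxonomy = planted_grid
        grid = association_matrix(
            mentions, taxonomy, "substance", "roa",
            AnalysisConfig(rho=INF, year=2018),
        )
        assert not any(cb in ("Intrathecal", "Urogenital") for _, cb in grid)


class TestSentenceProfile:
    def test_share_le_two(self):
        prof = sentence_count_profile([1, 2, 3])
        assert prof["share_le_2"] == pytest.approx(2 / 3)

    def test_all_single_sentence(self):
        prof = sentence_count_profile([1] * 10)
        assert prof["share_gt_10"] == 0.0
        assert prof["median"] == 1.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            sentence_count_profile([])
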