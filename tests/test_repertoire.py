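"""Repertoire statistics against brute-force oracles and planted truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from olfscreen.repertoire import (
    class_comparison,
    expressed_fraction,
    half_fraction,
    rank_and_cumulative,
    repertoire_summary,
    rerun_excluding_segregating,
    score_expression_association,
    status_distribution_test,
)
from olfscreen.types import OlfscreenError
from tests.conftest import make_matrix


def brute_force_half_fraction(values):
    """Scan oracle: smallest k with top-k sum >= half the total."""
    ordered = sorted(values, reverse=True)
    total = sum(ordered)
    acc = 0.0
    for k, v in enumerate(ordered, start=1):
        acc += v
        if acc >= 0.5 * total:
            return k / len(ordered)
    return 1.0


def brute_force_ks(x, y):
    """Max ECDF gap oracle."""
    gap = 0.0
    for v in list(x) + list(y):
        fx = sum(1 for a in x if a <= v) / len(x)
        fy = sum(1 for b in y if b <= v) / len(y)
        gap = max(gap, abs(fx - fy))
    return gap


class TestExpressedFraction:
    def test_counting(self):
        m = make_matrix([[0.5, 0.001], [0.02, 0.001],
                         [0.001, 0.05], [0.001, 0.001]], floor=0.003)
        assert expressed_fraction(
            m, ["g1", "g2", "g3", "g4"], 0.01) == pytest.approx(0.75)

    def test_all_at_floor(self):
        m = make_matrix(np.full((5, 3), 0.003), floor=0.003)
        assert expressed_fraction(m, [f"g{i+1}" for i in range(5)],
                                  0.01) == 0.0

    def test_monotone_in_cutoff(self, floored, small_study):
        genes = list(small_study.catalog.or_genes)
        oe = floored.samples_in_group("OE")
        fracs = [expressed_fraction(floored, genes, c, oe)
                 for c in (0.003, 0.01, 0.1, 1.0)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_empty_set_rejected(self, floored):
        with pytest.raises(OlfscreenError):
            expressed_fraction(floored, [], 0.01)

    def test_recovers_planted_fractions(self, floored, small_study):
        """Recovered expressed fractions match the truth-computable
        expectation (silent genes never detected; expressed genes detected
        with a probability given by their planted mean and noise sd)."""
        truth = small_study.truth
        oe = floored.samples_in_group("OE")
        for status in ("intact", "pseudogene"):
            genes = list(small_study.catalog.genes_with_status(status))
            mu = np.log10(truth.group_linear_mean.loc[genes, "OE"].values)
            sd = truth.noise_sd_log10.loc[genes].values
            # mean-one noise shifts log10 values down by sd^2*ln(10)/2
            shift = 0.5 * sd ** 2 * np.log(10.0)
            z = (np.log10(0.01) - (mu - shift)) / sd
            p_expr = 1.0 - stats.norm.cdf(z) ** len(oe)
            expected = p_expr.mean()
            sem = np.sqrt(np.sum(p_expr * (1 - p_expr))) / len(genes)
            observed = expressed_fraction(floored, genes, 0.01, oe)
            assert observed == pytest.approx(expected, abs=4 * sem + 0.01)


class TestHalfFraction:
    def test_uniform(self):
        assert half_fraction(np.ones(10)) == 0.5

    def test_hand_cases(self):
        assert half_fraction(np.array([8.0, 4, 2, 1])) == 0.25
        assert half_fraction(np.array([1.0, 1, 1, 1, 0, 0, 0, 0])) == 0.25

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 1000))
            v = rng.exponential(1.0, size=n) + 1e-9
            assert half_fraction(v) == brute_force_half_fraction(v)

    def test_zero_total_rejected(self):
        with pytest.raises(OlfscreenError):
            half_fraction(np.zeros(5))

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6,
                              allow_nan=False), min_size=1, max_size=200))
    def test_half_fraction_properties(self, values):
        v = np.asarray(values)
        hf = half_fraction(v)
        assert 0 < hf <= 1
        assert hf == brute_force_half_fraction(v)
        # scale invariance
        assert half_fraction(3.0 * v) == hf


class TestRankAndCumulative:
    def test_curve_invariants(self, floored, small_study):
        genes = list(small_study.catalog.or_genes)
        oe = floored.samples_in_group("OE")
        rank, cum, hf = rank_and_cumulative(floored, genes, oe)
        c = cum["cumulative_fraction"].values
        assert (np.diff(c) >= -1e-12).all()
        assert c[-1] == pytest.approx(1.0, abs=1e-12)
        assert 0 < hf <= 1
        assert (np.diff(rank["fpkm"].values) <= 1e-12).all()

    def test_ties_broken_by_gene_id(self):
        m = make_matrix([[2.0], [2.0], [1.0]], genes=["b", "a", "c"],
                        floor=0.003)
        rank, _, _ = rank_and_cumulative(m, ["b", "a", "c"], ["s1"])
        assert list(rank["gene_id"]) == ["a", "b", "c"]


class TestStatusDistribution:
    def test_identical_distributions(self):
        vals = np.linspace(0.1, 5, 20)
        m = make_matrix(np.concatenate([vals, vals])[:, None], floor=0.003)
        genes = [f"g{i+1}" for i in range(40)]
        catalog = _catalog(genes, ["intact"] * 20 + ["pseudogene"] * 20)
        _, ks_stat, ks_p = status_distribution_test(m, catalog, ["s1"])
        assert ks_stat == pytest.approx(0.0)
        assert ks_p > 0.99

    def test_ks_matches_bruteforce(self, rng):
        for _ in range(50):
            x = rng.lognormal(0, 1, size=int(rng.integers(3, 50)))
            y = rng.lognormal(0.5, 1, size=int(rng.integers(3, 50)))
            assert stats.ks_2samp(x, y).statistic == pytest.approx(
                brute_force_ks(x, y), abs=1e-12)

    def test_planted_shift_significant(self, floored, small_study):
        oe = floored.samples_in_group("OE")
        by, _, p = status_distribution_test(
            floored, small_study.catalog, oe)
        assert by["intact"][0] > by["pseudogene"][0]
        assert p < 1e-6


def _catalog(genes, statuses, **cols):
    import pandas as pd
    n = len(genes)
    df = pd.DataFrame({
        "symbol": genes, "or_status": statuses,
        "or_class": cols.get("or_class",
                             pd.Series([np.nan] * n, dtype=object)),
        "segregating_pseudogene": cols.get("segregating", [False] * n),
        "ortholog_id": pd.Series([np.nan] * n, dtype=object),
        "literature_hits": np.nan,
        "functionality_score": cols.get("score", np.nan),
    }, index=pd.Index(genes, name="gene_id"))
    from olfscreen.types import GeneCatalog
    return GeneCatalog(df)


class TestClassComparison:
    def test_chi2_matches_hand_formula(self):
        # 2x2 chi-square without continuity correction on [[30,10],[10,30]]:
        # n(ad-bc)^2 / (row1 row2 col1 col2) = 80*(900-100)^2/40^4 = 20
        chi2 = stats.chi2_contingency([[30, 10], [10, 30]],
                                      correction=False)[0]
        n, a, b, c, d = 80, 30, 10, 10, 30
        hand = n * (a * d - b * c) ** 2 / (40 * 40 * 40 * 40)
        assert chi2 == pytest.approx(hand) == pytest.approx(20.0)

    def test_identical_compositions_null(self):
        half = np.concatenate([np.full(15, 0.004), np.linspace(0.02, 2, 15)])
        vals = np.tile(half, 2)[:, None]
        genes = [f"g{i+1}" for i in range(60)]
        catalog = _catalog(genes, ["intact"] * 60,
                           or_class=["I"] * 30 + ["II"] * 30)
        m = make_matrix(vals, genes=genes, floor=0.003)
        res = class_comparison(m, catalog, ["s1"])
        assert res["chi2_p"] > 0.9
        assert res["ks_p"] > 0.9

    def test_degenerate_table_flagged(self):
        vals = np.tile(np.linspace(0.02, 2, 30), 2)[:, None]
        genes = [f"g{i+1}" for i in range(60)]
        catalog = _catalog(genes, ["intact"] * 60,
                           or_class=["I"] * 30 + ["II"] * 30)
        res = class_comparison(make_matrix(vals, genes=genes, floor=0.003),
                               catalog, ["s1"])
        assert res["chi2_unreliable"] and res["chi2_p"] == 1.0

    def test_planted_class_gap_detected(self):
        """With a planted class I deficit both the expressed-count
        chi-square and the level KS respond."""
        from olfscreen.io import apply_fpkm_floor
        from olfscreen.simulate import SimulationConfig, \
            simulate_expression_study
        cfg = SimulationConfig(seed=23, n_genes=2000, n_or_intact=450,
                               n_or_pseudo=450, class_i_fraction=0.3,
                               class_i_logdrop=1.2,
                               n_planted_overexpressed=0,
                               n_respiratory_contaminants=0)
        st = simulate_expression_study(cfg)
        m = apply_fpkm_floor(st.expression)
        res = class_comparison(m, st.catalog, m.samples_in_group("OE"))
        assert res["ks_p"] < 1e-3
        assert res["chi2_p"] < 0.05


class TestScoreAssociation:
    def test_monotone_score_detected(self, floored, small_study):
        """Intact ORs have both higher scores and higher expression, so the
        median-split KS is strongly significant."""
        p = score_expression_association(
            floored, small_study.catalog, floored.samples_in_group("OE"))
        assert p < 1e-6

    def test_all_equal_scores_rejected(self, floored):
        genes = [f"g{i+1}" for i in range(10)]
        catalog = _catalog(genes, ["intact"] * 10, score=[0.5] * 10)
        m = make_matrix(np.linspace(0.1, 1, 10)[:, None], genes=genes,
                        floor=0.003)
        with pytest.raises(OlfscreenError):
            score_expression_association(m, catalog, ["s1"])

    def test_null_scores_uniformish(self, rng):
        """Independent scores give p-values that are not systematically
        small."""
        ps = []
        for i in range(40):
            genes = [f"g{j+1}" for j in range(60)]
            catalog = _catalog(genes, ["intact"] * 60,
                               score=rng.uniform(0, 1, 60))
            m = make_matrix(rng.lognormal(0, 1, 60)[:, None], genes=genes,
                            floor=0.003)
            ps.append(score_expression_association(m, catalog, ["s1"]))
        assert np.mean(np.array(ps) < 0.05) < 0.2
        assert np.median(ps) > 0.2


class TestSegregatingRerun:
    def test_no_flags_identical(self, floored, small_study):
        cat = small_study.catalog
        unflagged = _catalog(list(cat.gene_ids),
                             list(cat.table["or_status"]),
                             or_class=cat.table["or_class"].values)
        oe = floored.samples_in_group("OE")
        full, reduced = rerun_excluding_segregating(
            repertoire_summary, unflagged, floored, samples=oe)
        assert full.half_fraction == reduced.half_fraction
        assert full.ks_p_intact_vs_pseudo == reduced.ks_p_intact_vs_pseudo

    def test_independent_flags_small_effect(self, floored, small_study):
        """Flags independent of expression barely move the skew statistic."""
        oe = floored.samples_in_group("OE")
        full, reduced = rerun_excluding_segregating(
            repertoire_summary, small_study.catalog, floored, samples=oe)
        assert abs(full.half_fraction - reduced.half_fraction) < 0.05
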