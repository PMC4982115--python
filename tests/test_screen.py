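"""Overexpression screen: normalization, the exact NB test against a
brute-force conditional-binomial oracle, and the retention/filter rules."""

import math

import numpy as np
import pandas as pd
import pytest

from olfscreen.io import apply_fpkm_floor
from olfscreen.screen import (
    DispersionModel,
    ScreenConfig,
    classify_evidence_class,
    estimate_dispersions,
    estimate_size_factors,
    fpkm_fold_change,
    nb_two_group_test,
    run_screen,
    shared_tissue_fold_change,
)
from olfscreen.simulate import (
    SHARED_CONTROL_TISSUES,
    simulate_null_counts,
)
from olfscreen.types import (
    CountMatrix,
    ExpressionMatrix,
    GeneCatalog,
    OlfscreenError,
    OrthologMap,
)
from tests.conftest import make_matrix


def counts_of(values, samples, groups):
    df = pd.DataFrame(np.asarray(values, dtype=int),
                      index=[f"g{i+1}" for i in range(len(values))],
                      columns=samples)
    return CountMatrix(df, groups)


class TestSizeFactors:
    def test_identical_samples(self):
        c = counts_of([[10, 10], [50, 50]], ["a", "b"],
                      {"a": "A", "b": "B"})
        s = estimate_size_factors(c)
        assert np.allclose(s.values, [1.0, 1.0])

    def test_doubled_sample_sqrt2(self):
        """B = 2*A exactly: median-of-ratios gives (1/sqrt2, sqrt2)."""
        c = counts_of([[10, 20], [20, 40], [30, 60]], ["a", "b"],
                      {"a": "A", "b": "B"})
        s = estimate_size_factors(c)
        assert s["a"] == pytest.approx(1 / math.sqrt(2))
        assert s["b"] == pytest.approx(math.sqrt(2))

    def test_single_sample(self):
        c = counts_of([[10], [20]], ["a"], {"a": "A"})
        assert estimate_size_factors(c).tolist() == [1.0]

    def test_geometric_mean_one(self, small_study):
        s = estimate_size_factors(small_study.counts)
        assert np.exp(np.mean(np.log(s.values))) == pytest.approx(1.0)

    def test_no_universally_expressed_gene(self):
        c = counts_of([[0, 5], [5, 0]], ["a", "b"], {"a": "A", "b": "B"})
        with pytest.raises(OlfscreenError):
            estimate_size_factors(c)


class TestDispersions:
    def test_poisson_counts_near_zero(self):
        c = simulate_null_counts(300, 100, 100, mean=100, dispersion=0.0,
                                 seed=1)
        s = estimate_size_factors(c)
        d = estimate_dispersions(c, s, {"A": c.samples_in_group("A"),
                                        "B": c.samples_in_group("B")},
                                 sharing="none")
        assert abs(d.alpha.mean()) < 0.01

    def test_nb_dispersion_recovered(self):
        c = simulate_null_counts(300, 100, 100, mean=100, dispersion=0.1,
                                 seed=2)
        s = estimate_size_factors(c)
        d = estimate_dispersions(c, s, {"A": c.samples_in_group("A"),
                                        "B": c.samples_in_group("B")},
                                 sharing="none")
        assert d.alpha.mean() == pytest.approx(0.1, abs=0.03)

    def test_constant_counts_zero(self):
        c = counts_of([[7, 7, 7, 7]], list("abcd"),
                      {s: "A" for s in "abcd"})
        s = estimate_size_factors(c)
        d = estimate_dispersions(c, s, {"A": list("abcd")})
        assert d.alpha.iloc[0] == 0.0


def conditional_binomial_oracle(k_a: int, k_b: int, frac_a: float) -> float:
    """Brute-force exact Poisson-conditional (binomial) test: enumerate all
    splits of the total and sum probabilities <= the observed one."""
    total = k_a + k_b
    probs = [math.comb(total, a) * frac_a ** a * (1 - frac_a) ** (total - a)
             for a in range(total + 1)]
    obs = probs[k_a]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-8)))


class TestNbTest:
    def _model(self, c, alpha=0.0):
        s = pd.Series(1.0, index=c.sample_ids)
        return s, DispersionModel(pd.Series(alpha, index=c.gene_ids), s)

    def test_identical_group_sums_p_one(self):
        c = counts_of([[10, 10, 10, 10]], list("abcd"),
                      {"a": "A", "b": "A", "c": "B", "d": "B"})
        s, d = self._model(c)
        assert nb_two_group_test(c, s, d, ["a", "b"], ["c", "d"], "g1") == 1.0

    @pytest.mark.parametrize("k_a,k_b,n_a,n_b", [
        (0, 20, 2, 2), (5, 15, 2, 2), (10, 10, 2, 2),
        (3, 17, 1, 3), (20, 0, 3, 1), (7, 6, 2, 3), (1, 1, 1, 1),
    ])
    def test_matches_binomial_oracle_at_zero_dispersion(
            self, k_a, k_b, n_a, n_b):
        samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
        groups = {s: ("A" if s.startswith("a") else "B") for s in samples}
        row = ([k_a // n_a + (1 if i < k_a % n_a else 0) for i in range(n_a)]
               + [k_b // n_b + (1 if i < k_b % n_b else 0) for i in range(n_b)])
        c = counts_of([row], samples, groups)
        s, d = self._model(c, alpha=0.0)
        ga = [s_ for s_ in samples if s_.startswith("a")]
        gb = [s_ for s_ in samples if s_.startswith("b")]
        p = nb_two_group_test(c, s, d, ga, gb, "g1")
        oracle = conditional_binomial_oracle(k_a, k_b, n_a / (n_a + n_b))
        assert p == pytest.approx(oracle, abs=1e-6)

    def test_overlapping_groups_rejected(self):
        c = counts_of([[1, 2]], ["a", "b"], {"a": "A", "b": "B"})
        s, d = self._model(c)
        with pytest.raises(OlfscreenError):
            nb_two_group_test(c, s, d, ["a"], ["a", "b"], "g1")

    def test_large_total_no_overflow(self):
        c = counts_of([[600_000, 400_000]], ["a", "b"],
                      {"a": "A", "b": "B"})
        s, d = self._model(c, alpha=0.05)
        p = nb_two_group_test(c, s, d, ["a"], ["b"], "g1")
        assert 0 < p <= 1


class TestFoldChange:
    def test_arithmetic(self):
        m = make_matrix([[0.6, 0.6, 0.1, 0.1]], floor=0.003)
        assert fpkm_fold_change(m, "g1", ["s1", "s2"],
                                ["s3", "s4"]) == pytest.approx(6.0)

    def test_floor_identity(self):
        m = make_matrix([[0.003, 0.003, 0.003]], floor=0.003)
        assert fpkm_fold_change(m, "g1", ["s1"], ["s2", "s3"]) == 1.0

    def test_empty_group_rejected(self):
        m = make_matrix([[1.0, 2.0]], floor=0.003)
        with pytest.raises(OlfscreenError):
            fpkm_fold_change(m, "g1", [], ["s1"])


def _mini_catalog(genes, hits=None, orthologs=None):
    hits = hits or {}
    orthologs = orthologs or {}
    return GeneCatalog(pd.DataFrame({
        "symbol": genes, "or_status": "non_OR",
        "or_class": pd.Series(np.nan, index=genes, dtype=object),
        "segregating_pseudogene": False,
        "ortholog_id": pd.Series({g: orthologs.get(g) for g in genes},
                                 dtype=object),
        "literature_hits": pd.Series({g: hits.get(g, np.nan) for g in genes}),
        "functionality_score": np.nan,
    }, index=pd.Index(genes, name="gene_id")))


class TestRunScreen:
    @pytest.fixture()
    def mini(self):
        samples = ["OE1", "OE2", "OE3", "OE4", "rsp",
                   "c1", "c2", "c3", "c4"]
        groups = {s: "OE" for s in samples[:4]}
        groups["rsp"] = "respiratory"
        groups.update({s: "control:t" + s[-1] for s in samples[5:]})
        fpkm = pd.DataFrame({
            # gA: clean hit (fold 10, tiny respiratory signal)
            "gA": [1.0, 1.0, 1.0, 1.0, 0.005, 0.1, 0.1, 0.1, 0.1],
            # gB: overexpressed but respiratory-contaminated (ratio 0.15)
            "gB": [1.0, 1.0, 1.0, 1.0, 0.15, 0.1, 0.1, 0.1, 0.1],
            # gC: fold 7 but weak counts -> rescued by mouse
            "gC": [0.7, 0.7, 0.7, 0.7, 0.005, 0.1, 0.1, 0.1, 0.1],
            # gD: fold 2 only
            "gD": [0.2, 0.2, 0.2, 0.2, 0.005, 0.1, 0.1, 0.1, 0.1],
            # housekeeping ballast so size factors are well-defined
            **{f"hk{i}": [v] * 9 for i, v in enumerate((5.0, 8.0, 2.0,
                                                        1.0, 3.0, 6.0))},
        }, index=samples).T
        counts = pd.DataFrame({
            "gA": [400, 400, 400, 400, 2, 40, 40, 40, 40],
            "gB": [400, 400, 400, 400, 60, 40, 40, 40, 40],
            "gC": [30, 31, 30, 29, 2, 25, 26, 25, 24],
            "gD": [80, 80, 80, 80, 2, 40, 40, 40, 40],
            **{f"hk{i}": [v] * 9 for i, v in enumerate((150, 240, 60,
                                                        30, 90, 180))},
        }, index=samples).T
        m = ExpressionMatrix(fpkm, groups, floor=0.003)
        c = CountMatrix(counts, groups)
        catalog = _mini_catalog(list(fpkm.index),
                                hits={"gA": 12, "gC": 0},
                                orthologs={"gC": "mgC"})
        om = OrthologMap({"gC": "mgC"})
        return m, c, catalog, om

    def test_statuses_and_classes(self, mini):
        m, c, catalog, om = mini
        records = {r.gene_id: r for r in run_screen(
            m, c, catalog, om, mouse_screen={"mgC": True})}
        assert records["gA"].status == "retained"
        assert records["gA"].p_value < 1e-5
        assert records["gB"].status == "respiratory_filtered"
        assert records["gB"].respiratory_ratio == pytest.approx(0.15)
        assert records["gC"].status == "rescued_by_mouse"
        assert records["gD"].status == "failed_fold"
        assert records["gA"].evidence_class == "A"
        assert records["gC"].evidence_class == "B"
        assert records["gB"].evidence_class == "NA"  # filtered, not retained

    def test_no_respiratory_sample_disables_filter(self, mini, caplog):
        m, c, catalog, om = mini
        keep = [s for s in m.sample_ids if s != "rsp"]
        m2 = ExpressionMatrix(m.values[keep],
                              {s: m.sample_groups[s] for s in keep},
                              floor=0.003)
        c2 = CountMatrix(c.counts[keep],
                         {s: c.sample_groups[s] for s in keep})
        with caplog.at_level("WARNING"):
            records = {r.gene_id: r for r in run_screen(m2, c2, catalog, om)}
        assert records["gB"].status == "retained"
        assert "respiratory" in caplog.text

    def test_monotone_in_cutoffs(self, mini):
        m, c, catalog, om = mini
        loose = {r.gene_id for r in run_screen(
            m, c, catalog, om, cfg=ScreenConfig()) if r.retained}
        strict = {r.gene_id for r in run_screen(
            m, c, catalog, om,
            cfg=ScreenConfig(fold_cutoff=12.0, p_cutoff=1e-8,
                             rescue_human_fold_min=12.0)) if r.retained}
        assert strict <= loose


def test_classify_threshold_boundary():
    catalog = _mini_catalog(["g1", "g2", "g3"], hits={"g1": 12, "g2": 0})
    from olfscreen.screen import ScreenRecord
    recs = [ScreenRecord(g, 10.0, 1e-5, 0.0, "retained")
            for g in ["g1", "g2", "g3"]]
    classify_evidence_class(recs, catalog, hit_threshold=1)
    assert [r.evidence_class for r in recs] == ["A", "B", "NA"]


class TestSharedTissueFold:
    def test_full_set_consistency(self, small_paired):
        human = small_paired.human
        m = apply_fpkm_floor(human.expression)
        gene = human.truth.planted_overexpressed_gene_ids[0]
        mm = apply_fpkm_floor(small_paired.mouse.expression)
        h_fold, _ = shared_tissue_fold_change(
            m, mm, SHARED_CONTROL_TISSUES, gene, small_paired.orthologs)
        oe = m.samples_in_group("OE")
        ctrl = [s for s in m.sample_ids
                if m.sample_groups[s].split(":")[-1] in SHARED_CONTROL_TISSUES
                and m.sample_groups[s].startswith("control")]
        assert h_fold == pytest.approx(fpkm_fold_change(m, gene, oe, ctrl))

    def test_discordant_planting(self, small_paired):
        """A human-planted gene without a mouse-planted ortholog shows fold
        >= 6 in human and ~1 in mouse."""
        human, mouse = small_paired.human, small_paired.mouse
        m = apply_fpkm_floor(human.expression)
        mm = apply_fpkm_floor(mouse.expression)
        shared_h = set(mouse.truth.extras["shared_planted_human_ids"])
        only_human = [g for g in human.truth.planted_overexpressed_gene_ids
                      if g not in shared_h
                      and small_paired.orthologs.get(g) is not None]
        folds_h, folds_m = [], []
        for gene in only_human:
            fh, fm = shared_tissue_fold_change(
                m, mm, SHARED_CONTROL_TISSUES, gene, small_paired.orthologs)
            folds_h.append(fh)
            folds_m.append(fm)
        # discordance discipline holds only where an ortholog exists at all:
        # human planted genes without shared planting have no planted mouse fold
        assert not only_human or (np.nanmedian(folds_m) < 3)

    def test_no_shared_tissue_error(self, small_paired):
        m = apply_fpkm_floor(small_paired.human.expression)
        mm = apply_fpkm_floor(small_paired.mouse.expression)
        with pytest.raises(OlfscreenError):
            shared_tissue_fold_change(m, mm, ["bone"], "OVX0001",
                                      small_paired.orthologs)
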