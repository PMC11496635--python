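import numpy as np
import pytest
from scipy.stats import hypergeom

from ionrank.evaluation import (
    annotation_delta,
    average_precision,
    bh_adjust,
    filter_enrichment_terms,
    intensity_profile,
    map_over_groups,
    match_reference,
    subclass_enrichment,
)
from ionrank.io import MoleculeRecord

from conftest import grid_dataset

T, D = False, True  # label shorthand: target / decoy (AP takes True=target)


def brute_force_ap(labels):
    """Independent oracle: recompute precision@k with fresh slicing."""
    total = 0.0
    hits = 0
    for k in range(1, len(labels) + 1):
        if labels[k - 1]:
            hits += 1
            total += sum(labels[:k]) / k
    return total / hits


class TestAveragePrecision:
    def test_interleaved_example(self):
        assert average_precision([True, False, True, False]) == pytest.approx(
            (1 + 2 / 3) / 2
        )

    def test_all_targets_first(self):
        assert average_precision([True, True, False, False]) == 1.0

    def test_single_target_second(self):
        assert average_precision([False, True]) == 0.5

    def test_no_targets_rejected(self):
        with pytest.raises(ValueError):
            average_precision([False, False])

    def test_matches_brute_force_on_random_lists(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(1, 21))
            labels = (rng.random(n) < 0.4).tolist()
            if not any(labels):
                labels[int(rng.integers(n))] = True
            assert average_precision(labels) == pytest.approx(
                brute_force_ap(labels), abs=1e-12
            )


class TestMapOverGroups:
    def test_mean_of_group_aps(self):
        groups = {"a": [True, True], "b": [False, True]}
        assert map_over_groups(groups) == pytest.approx(0.75)

    def test_single_group(self):
        assert map_over_groups({"a": [True, False]}) == 1.0

    def test_zero_target_group_skipped(self):
        with pytest.warns(UserWarning):
            got = map_over_groups({"a": [True], "b": [False]})
        assert got == 1.0


class TestAnnotationDelta:
    def test_equal_counts(self):
        assert annotation_delta(10, 10) == (0.0, 0.0)

    def test_direct_arithmetic_with_pseudocount(self):
        log_diff, lfc = annotation_delta(110, 10)
        assert log_diff == pytest.approx(np.log10(101), abs=1e-9)
        assert lfc == pytest.approx(np.log2(111 / 11), abs=1e-9)

    def test_direction(self):
        log_diff, lfc = annotation_delta(0, 100)
        assert log_diff < 0 and lfc < 0

    def test_sign_agreement(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            ml, base = rng.integers(0, 500, 2)
            log_diff, _ = annotation_delta(int(ml), int(base))
            assert np.sign(log_diff) == np.sign(ml - base)


class TestIntensityProfile:
    def test_constant_image_log10(self):
        ds = grid_dataset(
            [([500.0], [10.0]), ([500.0], [10.0]), ([500.0], [10.0]), ([500.0], [10.0])],
            shape=(2, 2),
        )
        out = intensity_profile(ds, {"set_a": [500.0]})
        assert out["medians"]["set_a"] == pytest.approx(1.0)

    def test_equal_sets_zero_difference(self):
        ds = grid_dataset([([500.0], [10.0]), ([500.0], [10.0])], shape=(1, 2))
        out = intensity_profile(ds, {"a": [500.0], "b": [500.0]})
        assert out["medians"]["a"] == out["medians"]["b"]

    def test_planted_low_intensity_set_ranks_lower(self):
        rng = np.random.default_rng(4)
        high = [200.0 + i for i in range(5)]
        low = [400.0 + i for i in range(5)]
        pixels = []
        for _ in range(16):
            mz = np.array(high + low)
            inten = np.concatenate(
                [rng.uniform(900, 1100, 5), rng.uniform(9, 11, 5)]
            )
            order = np.argsort(mz)
            pixels.append((mz[order], inten[order]))
        ds = grid_dataset(pixels, shape=(4, 4))
        out = intensity_profile(ds, {"only_baseline": high, "only_ml": low})
        assert out["medians"]["only_ml"] < out["medians"]["only_baseline"]
        assert out["tests"][("only_baseline", "only_ml")]["p_value"] < 0.01


class TestEnrichment:
    def _background(self, n_in=100, n_total=1000):
        recs = [
            MoleculeRecord(f"C{i}H{i}O2", f"in{i}", subclass="Lipids")
            for i in range(2, n_in + 2)
        ]
        recs += [
            MoleculeRecord(f"C{i}H{i}O3", f"out{i}", subclass="Other")
            for i in range(2, n_total - n_in + 2)
        ]
        return recs

    def test_toy_fold_enrichment(self):
        bg = self._background()
        query = [m.formula for m in bg[:10]] + [m.formula for m in bg[100:110]]
        rows = subclass_enrichment(query, bg)
        lip = next(r for r in rows if r.subclass == "Lipids")
        assert (lip.a, lip.b, lip.c, lip.d) == (10, 10, 90, 890)
        assert lip.log2_fold_enrichment == pytest.approx(np.log2(5), abs=1e-9)
        assert lip.log2_fold_enrichment == pytest.approx(2.3219, abs=1e-4)

    def test_p_equals_hypergeometric_tail(self):
        bg = self._background(20, 60)
        query = [m.formula for m in bg[:8]] + [m.formula for m in bg[25:29]]
        rows = subclass_enrichment(query, bg)
        for r in rows:
            # one-tailed Fisher (greater) == hypergeometric survival at a-1
            n_query = r.a + r.b
            n_in_class = r.a + r.c
            n_total = r.a + r.b + r.c + r.d
            p_oracle = hypergeom.sf(r.a - 1, n_total, n_in_class, n_query)
            assert r.p_value == pytest.approx(p_oracle, rel=1e-9)

    def test_null_query_calibration(self):
        rng = np.random.default_rng(8)
        bg = self._background(30, 120)
        n_sig = 0
        n_tests = 0
        for _ in range(200):
            query = [bg[i].formula for i in rng.choice(len(bg), 20, replace=False)]
            for r in subclass_enrichment(query, bg):
                n_tests += 1
                n_sig += r.p_value < 0.05
        # Fisher test is conservative on discrete tables: at most ~5% + noise
        assert n_sig / n_tests < 0.08

    def test_empty_query(self):
        assert subclass_enrichment([], self._background(5, 10)) == []

    def test_unlabeled_background_rejected(self):
        with pytest.raises(ValueError):
            subclass_enrichment(["H2O"], [MoleculeRecord("H2O", "water")])

    def test_reporting_filter(self):
        from ionrank.evaluation import EnrichmentRow

        row_sig = EnrichmentRow("Lipids", 5, 5, 5, 85, 0.001, 2.0)
        row_ns = EnrichmentRow("Other", 1, 9, 20, 70, 0.7, -1.0)
        per_ds = {f"d{i}": [row_sig, row_ns] for i in range(10)}
        per_ds["d9"] = [row_ns]
        assert filter_enrichment_terms(per_ds) == ["Lipids"]
        assert filter_enrichment_terms({"d0": [row_ns]}) == []


class TestBhAdjust:
    def test_monotone_and_bounded(self):
        p = np.array([0.001, 0.02, 0.04, 0.5])
        adj = bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1)


class TestMatchReference:
    def test_hand_contingency(self):
        annotations = {("A", "+H"), ("B", "+Na")}
        reference = {("A", "+H"), ("C", "+K")}
        universe = {("A", "+H"), ("B", "+Na"), ("C", "+K"), ("D", "+H")}
        out = match_reference(annotations, reference, universe)
        assert (out["tp"], out["fp"], out["fn"], out["tn"]) == (1, 1, 1, 1)
        assert out["tpr"] == 0.5

    def test_perfect_agreement(self):
        ions = {("A", "+H"), ("B", "+K")}
        universe = ions | {("C", "+Na")}
        out = match_reference(ions, ions, universe)
        assert out["tpr"] == 1.0 and out["fpr"] == 0.0

    def test_disjoint_sets(self):
        out = match_reference(
            {("A", "+H")}, {("B", "+Na")}, {("A", "+H"), ("B", "+Na")}
        )
        assert out["tpr"] == 0.0

    def test_adduct_restriction_and_exclusive_mode(self):
        annotations = {("A", "+H"), ("B", "+H")}
        reference = {("A", "+H"), ("X", "-H")}  # -H dropped by restriction
        universe = {("A", "+H"), ("B", "+H")}
        out = match_reference(
            annotations, reference, universe, other_method={("B", "+H")}
        )
        assert out["tp"] == 1 and out["fp"] == 0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            match_reference({("A", "+H")}, {("X", "-H")}, {("A", "+H")})
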