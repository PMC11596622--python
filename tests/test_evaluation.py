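"""Confusion tallies, the six metrics, exact MCC, CV accumulation, reports.

The fixed-point MCC examples are confusion matrices of published
compound-pathway association models; the implementation must reproduce
their reported values to 3 decimal places from the raw counts alone.
"""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathassoc.dataset import stratified_split
from pathassoc.evaluation import (
    ConfusionCounts,
    aggregate_by_group,
    aggregate_overall,
    confusion,
    derived_metrics,
    mcc,
    run_cv,
    size_mcc_correlation,
    write_reports,
)
from pathassoc.model import MLPConfig

counts = st.integers(min_value=0, max_value=10**6)

CV_CONFIG = MLPConfig(hidden_sizes=(32, 16), batch_size=128, max_epochs=3, seed=0)


class TestConfusion:
    def test_hand_tally(self):
        c = confusion([1, 0, 1, 0], [1, 0, 0, 1])
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 1, 1)

    def test_all_correct(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == 0 and c.fn == 0

    def test_against_elementwise_recount(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=1000)
        p = rng.integers(0, 2, size=1000)
        c = confusion(y, p)
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for yi, pi in zip(y, p):
            key = ("t" if yi == pi else "f") + ("p" if pi else "n")
            tally[key] += 1
        assert (c.tp, c.tn, c.fp, c.fn) == (
            tally["tp"], tally["tn"], tally["fp"], tally["fn"]
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)


class TestMCC:
    @pytest.mark.parametrize(
        "tp, tn, fp, fn, expected",
        [
            (121_569, 4_494, 3_074, 657, 0.706),       # largest pathway category
            (5_853, 121_547, 1_058, 675, 0.864),
            (145_888, 747_972, 8_497, 4_188, 0.950),   # top-level aggregate
            (85_204, 14_085_671, 34_729, 28_996, 0.726),
            (2_775, 1_034_201, 585, 280, 0.866),       # subtree aggregate
        ],
    )
    def test_reproduces_published_values(self, tp, tn, fp, fn, expected):
        assert round(mcc(ConfusionCounts(tp, tn, fp, fn)), 3) == expected

    def test_perfect_prediction(self):
        assert mcc(ConfusionCounts(10, 10, 0, 0)) == 1.0

    def test_undefined_on_zero_marginal(self):
        assert mcc(ConfusionCounts(tp=0, tn=5, fp=0, fn=0)) is None
        assert mcc(ConfusionCounts(tp=5, tn=0, fp=0, fn=0)) is None

    def test_no_overflow_at_huge_counts(self):
        # marginal products far beyond 2**63
        big = ConfusionCounts(10**8, 6 * 10**7, 10**6, 10**6)
        value = mcc(big)
        assert value is not None and 0.9 < value <= 1.0

    @given(tp=counts, tn=counts, fp=counts, fn=counts)
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_negation(self, tp, tn, fp, fn):
        c = ConfusionCounts(tp, tn, fp, fn)
        swapped = ConfusionCounts(tn, tp, fn, fp)  # tp<->tn, fp<->fn
        negated = ConfusionCounts(fn, fp, tn, tp)  # predictions inverted
        m = mcc(c)
        if m is None:
            assert mcc(swapped) is None
        else:
            assert mcc(swapped) == pytest.approx(m, abs=1e-12)
            if mcc(negated) is not None:
                assert mcc(negated) == pytest.approx(-m, abs=1e-12)

    @given(tp=counts, tn=counts, fp=counts, fn=counts)
    @settings(max_examples=200, deadline=None)
    def test_range_and_float_agreement(self, tp, tn, fp, fn):
        m = mcc(ConfusionCounts(tp, tn, fp, fn))
        if m is not None:
            assert -1.0 <= m <= 1.0 + 1e-12
            denom = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            naive = (tp * tn - fp * fn) / np.sqrt(denom)
            assert m == pytest.approx(naive, rel=1e-9)


class TestDerivedMetrics:
    def test_published_row(self):
        m = derived_metrics(ConfusionCounts(121_569, 4_494, 3_074, 657))
        assert round(m.specificity, 3) == 0.594
        assert round(m.precision, 3) == 0.975
        assert round(m.recall, 3) == 0.995
        assert round(m.f1, 3) == 0.985

    def test_balanced_unit_counts(self):
        m = derived_metrics(ConfusionCounts(1, 1, 1, 1))
        assert m.accuracy == 0.5 and m.precision == 0.5 and m.recall == 0.5

    def test_undefined_precision(self):
        m = derived_metrics(ConfusionCounts(tp=0, tn=3, fp=0, fn=2))
        assert m.precision is None
        assert m.recall == 0.0

    def test_metrics_from_pooled_counts_match_pooled_predictions(self):
        rng = np.random.default_rng(7)
        y1, p1 = rng.integers(0, 2, 500), rng.integers(0, 2, 500)
        y2, p2 = rng.integers(0, 2, 500), rng.integers(0, 2, 500)
        summed = confusion(y1, p1) + confusion(y2, p2)
        pooled = confusion(np.concatenate([y1, y2]), np.concatenate([p1, p2]))
        assert summed == pooled
        assert derived_metrics(summed) == derived_metrics(pooled)


@pytest.fixture(scope="module")
def cv_result(tiny_dataset):
    return run_cv(tiny_dataset, CV_CONFIG, n_iterations=3, base_seed=10,
                  test_fraction=0.2)


class TestRunCV:
    def test_iteration_count_and_seeds(self, cv_result):
        assert cv_result.n_iterations == 3
        assert cv_result.seeds == [10, 11, 12]

    def test_per_pathway_conservation(self, cv_result):
        total = ConfusionCounts()
        for c in cv_result.per_pathway.values():
            total = total + c
        assert total == cv_result.pooled_overall()

    def test_per_compound_conservation(self, cv_result):
        total = ConfusionCounts()
        for c in cv_result.per_compound.values():
            total = total + c
        assert total == cv_result.pooled_overall()

    def test_entry_budget(self, cv_result, tiny_dataset):
        n_test = int(round(tiny_dataset.n_entries * 0.2))
        for c in cv_result.per_iteration_overall:
            assert c.total == n_test

    def test_reproducible(self, tiny_dataset, cv_result):
        again = run_cv(tiny_dataset, CV_CONFIG, n_iterations=3, base_seed=10,
                       test_fraction=0.2)
        assert again.per_iteration_overall == cv_result.per_iteration_overall
        assert again.per_pathway == cv_result.per_pathway

    def test_per_entity_matches_recount_oracle(self, tiny_dataset):
        """Accumulated per-entity counts equal a naive per-iteration recount."""
        ds = tiny_dataset
        cv = run_cv(ds, CV_CONFIG, n_iterations=2, base_seed=20, test_fraction=0.2)
        from pathassoc.model import AssociationMLP

        expect = {p: [0, 0, 0, 0] for p in ds.pathway_ids}
        for i in range(2):
            plan = stratified_split(ds, 0.2, 20 + i, iteration=i)
            cfg = MLPConfig(**{**CV_CONFIG.__dict__, "seed": 20 + i})
            model = AssociationMLP(ds, cfg).fit(plan)
            _, pred = model.predict(ds, plan.test_indices)
            y = ds.entry_labels(plan.test_indices)
            _, i_p = ds.entry_pairs(plan.test_indices)
            for yj, pj, pw in zip(y, pred, i_p):
                slot = 0 if (yj and pj) else 1 if (not yj and not pj) else 2 if pj else 3
                expect[ds.pathway_ids[pw]][slot] += 1
        for p, (tp, tn, fp, fn) in expect.items():
            assert cv.per_pathway[p] == ConfusionCounts(tp, tn, fp, fn)


class TestAggregation:
    def test_identical_iterations_zero_std(self):
        from pathassoc.evaluation import CVResult

        c = ConfusionCounts(5, 5, 2, 2)
        cv = CVResult([c, c, c], {}, {}, [0, 1, 2])
        mean, median, std = aggregate_overall(cv, "mcc")
        assert std == 0.0 and mean == median == mcc(c)

    def test_mean_median_of_three(self):
        from pathassoc.evaluation import CVResult

        # three iterations with accuracies 0.7, 0.8, 0.9 over 10 entries
        cvs = [ConfusionCounts(tp=k, tn=0, fp=0, fn=10 - k) for k in (7, 8, 9)]
        cv = CVResult(cvs, {}, {}, [0, 1, 2])
        mean, median, _ = aggregate_overall(cv, "accuracy")
        assert mean == pytest.approx(0.8)
        assert median == pytest.approx(0.8)

    def test_all_undefined_rejected(self):
        from pathassoc.evaluation import CVResult

        cv = CVResult([ConfusionCounts(0, 5, 0, 0)], {}, {}, [0])
        with pytest.raises(ValueError):
            aggregate_overall(cv, "mcc")

    def test_group_of_one_equals_own_metrics(self, tiny_dataset):
        cv = run_cv(tiny_dataset, CV_CONFIG, n_iterations=1, base_seed=0,
                    test_fraction=0.2)
        by_pathway = aggregate_by_group(cv, "pathway")
        some_id = tiny_dataset.pathway_ids[0]
        assert by_pathway[some_id] == derived_metrics(cv.per_pathway[some_id])

    def test_level_grouping_matches_regroup_oracle(self, tiny_dataset):
        cv = run_cv(tiny_dataset, CV_CONFIG, n_iterations=1, base_seed=0,
                    test_fraction=0.2)
        by_level = aggregate_by_group(cv, "level")
        for level in ("L1", "L2", "L3"):
            members = [
                p for p, lv in cv.pathway_levels.items() if lv == level
            ]
            if not members:
                continue
            total = ConfusionCounts()
            for p in members:
                total = total + cv.per_pathway[p]
            assert by_level[level] == derived_metrics(total)

    def test_l1_subtree_grouping(self, tiny_study, tiny_dataset):
        cv = run_cv(tiny_dataset, CV_CONFIG, n_iterations=1, base_seed=0,
                    test_fraction=0.2)
        by_subtree = aggregate_by_group(cv, "l1_subtree", tiny_study.hierarchy)
        for l1, metrics in by_subtree.items():
            members = tiny_study.hierarchy.subtree(l1)
            total = ConfusionCounts()
            for p in members:
                if p in cv.per_pathway:
                    total = total + cv.per_pathway[p]
            assert metrics == derived_metrics(total)

    def test_unknown_grouping(self, tiny_dataset):
        cv = run_cv(tiny_dataset, CV_CONFIG, n_iterations=1, base_seed=0,
                    test_fraction=0.2)
        with pytest.raises(ValueError):
            aggregate_by_group(cv, "nonsense")


class TestSizeMCCCorrelation:
    def test_perfectly_linear(self):
        sizes = {f"p{i}": i for i in range(1, 6)}
        mccs = {f"p{i}": 0.1 * i for i in range(1, 6)}
        r, p = size_mcc_correlation(sizes, mccs)
        assert r == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        sizes = {"a": 1, "b": 2, "c": 3}
        mccs = {"a": 0.2, "b": 0.4, "c": 0.5}
        r, _ = size_mcc_correlation(sizes, mccs)
        # closed form: r = 0.3 / sqrt(2 * 0.0466667)
        assert r == pytest.approx(0.981981, abs=1e-6)

    def test_undefined_mcc_excluded(self):
        sizes = {"a": 1, "b": 2, "c": 3, "d": 9}
        mccs = {"a": 0.2, "b": 0.4, "c": 0.5, "d": None}
        r, _ = size_mcc_correlation(sizes, mccs)
        assert r == pytest.approx(0.981981, abs=1e-6)

    def test_constant_sizes_rejected(self):
        with pytest.raises(ValueError):
            size_mcc_correlation({"a": 1, "b": 1, "c": 1},
                                 {"a": 0.1, "b": 0.2, "c": 0.3})

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            size_mcc_correlation({"a": 1, "b": 2}, {"a": 0.1, "b": 0.2})


class TestReports:
    def test_report_files_written(self, tmp_path, tiny_study, tiny_dataset):
        cv = run_cv(tiny_dataset, CV_CONFIG, n_iterations=2, base_seed=0,
                    test_fraction=0.2)
        write_reports(cv, tmp_path, tiny_study.hierarchy)
        for name in (
            "overall_iterations.tsv",
            "level_metrics.tsv",
            "l1_subtree_metrics.tsv",
            "per_pathway_counts.tsv",
            "per_compound_counts.tsv",
            "cv_summary.json",
        ):
            assert (tmp_path / name).exists()
        summary = json.loads((tmp_path / "cv_summary.json").read_text())
        assert summary["n_iterations"] == 2
        header = (tmp_path / "per_pathway_counts.tsv").read_text().splitlines()[0]
        assert header.split("\t")[:5] == ["id", "tp", "tn", "fp", "fn"]
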