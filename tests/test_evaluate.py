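import numpy as np
import pytest
from statsmodels.stats.proportion import proportion_confint

from barcodeid import evaluate as ev
from barcodeid.errors import UndefinedRateError
from barcodeid.io import BarcodeRecord, Dataset
from barcodeid.simulate import SimulationConfig, simulate_dataset


def make_dataset(sizes):
    records = []
    for k, n in enumerate(sizes):
        for i in range(n):
            records.append(BarcodeRecord(f"R{k}_{i}", f"sp{k}", "ACGT"))
    return Dataset(records)


class TestSpeciesLevelSplit:
    @pytest.mark.parametrize("n, expected_ref", [(1, 1), (3, 3), (4, 3), (6, 4), (9, 6)])
    def test_per_species_reference_counts(self, n, expected_ref):
        ds = make_dataset([n])
        plan = ev.species_level_split(ds, repetitions=1, seed=0)
        ref, qry = plan.splits[0]
        assert len(ref) == expected_ref
        assert len(qry) == n - expected_ref

    def test_partition_and_balanced_coverage(self):
        ds = make_dataset([1, 2, 3, 4, 5, 8, 13])
        plan = ev.species_level_split(ds, repetitions=5, seed=42)
        all_species = set(ds.species_table)
        for ref, qry in plan.splits:
            assert set(ref) | set(qry) == set(range(len(ds)))
            assert set(ref) & set(qry) == set()
            ref_species = {ds.records[i].species for i in ref}
            assert ref_species == all_species

    def test_repetitions_differ_but_are_seed_deterministic(self):
        ds = make_dataset([10, 10, 10])
        plan_a = ev.species_level_split(ds, repetitions=3, seed=7)
        plan_b = ev.species_level_split(ds, repetitions=3, seed=7)
        assert plan_a.splits == plan_b.splits
        assert len({tuple(r) for r, _ in plan_a.splits}) > 1


class TestKFoldSplit:
    def test_766_records_give_canonical_fold_sizes(self):
        ds = make_dataset([766])
        plan = ev.k_fold_split(ds, k=5, seed=0)
        sizes = sorted((len(q) for _, q in plan.splits), reverse=True)
        assert sizes == [154, 153, 153, 153, 153]
        queried = sorted(i for _, q in plan.splits for i in q)
        assert queried == list(range(766))

    @pytest.mark.parametrize("n, k, sizes", [(10, 5, [2] * 5), (3, 2, [2, 1])])
    def test_small_fold_arithmetic(self, n, k, sizes):
        plan = ev.k_fold_split(make_dataset([n]), k=k, seed=1)
        assert sorted((len(q) for _, q in plan.splits), reverse=True) == sizes

    def test_each_fold_complements_its_reference(self):
        ds = make_dataset([7, 6])
        plan = ev.k_fold_split(ds, k=4, seed=3)
        for ref, qry in plan.splits:
            assert sorted(ref + qry) == list(range(len(ds)))

    def test_k_larger_than_dataset_rejected(self):
        with pytest.raises(ValueError):
            ev.k_fold_split(make_dataset([3]), k=5, seed=0)


class TestSuccessRate:
    @pytest.mark.parametrize(
        "k, n, expected", [(1295, 1295, 1.0), (3, 4, 0.75), (0, 5, 0.0)]
    )
    def test_values(self, k, n, expected):
        assert ev.success_rate(k, n) == expected

    def test_zero_denominator_is_undefined(self):
        with pytest.raises(UndefinedRateError):
            ev.success_rate(0, 0)


class TestWilsonCi:
    @pytest.mark.parametrize(
        "k, n, lower, upper",
        [
            (1295, 1295, "99.70%", "100.00%"),
            (1585, 1585, "99.75%", "100.00%"),
            (335, 340, "96.60%", "99.37%"),
            (130, 135, "91.62%", "98.40%"),
            (1240, 1295, "94.51%", "96.72%"),
        ],
    )
    def test_printed_bounds_from_reported_counts(self, k, n, lower, upper):
        lo, hi = ev.wilson_ci(k, n, 0.95)
        assert ev.format_percent_trunc(lo) == lower
        assert ev.format_percent_trunc(hi) == upper

    def test_agrees_with_statsmodels_wilson(self):
        for k, n in [(0, 10), (5, 10), (130, 135), (1295, 1295), (50, 1000)]:
            lo, hi = ev.wilson_ci(k, n, 0.95)
            slo, shi = proportion_confint(k, n, alpha=0.05, method="wilson")
            assert lo == pytest.approx(slo, abs=1e-10)
            assert hi == pytest.approx(shi, abs=1e-10)

    def test_agrees_with_score_test_inversion(self):
        # brute force: the interval endpoints solve
        # (p_hat - p)^2 = z^2 p (1 - p) / n, a quadratic in p
        from scipy.stats import norm

        z = norm.ppf(0.975)
        for k, n in [(1, 7), (13, 29), (130, 135), (999, 1000)]:
            p = k / n
            a = 1 + z**2 / n
            b = -(2 * p + z**2 / n)
            c = p**2
            roots = np.roots([a, b, c])
            lo, hi = ev.wilson_ci(k, n, 0.95)
            assert lo == pytest.approx(min(roots.real), abs=1e-10)
            assert hi == pytest.approx(max(roots.real), abs=1e-10)

    def test_symmetric_about_half_for_even_counts(self):
        lo, hi = ev.wilson_ci(500, 1000, 0.95)
        assert lo + hi == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_successes_and_shrinking_in_n(self):
        lowers = [ev.wilson_ci(k, 50)[0] for k in range(51)]
        assert all(a <= b for a, b in zip(lowers, lowers[1:]))
        widths = [np.diff(ev.wilson_ci(n // 2, n))[0] for n in (10, 100, 1000, 100000)]
        assert all(a > b for a, b in zip(widths, widths[1:]))


class TestPercentTruncation:
    @pytest.mark.parametrize(
        "x, printed",
        [
            (130 / 135, "96.29%"),  # 96.296... truncates, never rounds up
            (1.0, "100.00%"),
            (0.984075, "98.40%"),
            (0.0, "0.00%"),
        ],
    )
    def test_examples(self, x, printed):
        assert ev.format_percent_trunc(x) == printed


class TestRunIdentification:
    def test_fully_clustered_dataset_identifies_perfectly(self):
        # zero within-species divergence: every query coincides with a
        # reference exemplar, so the zero-training-error property forces a
        # perfect pooled success rate for both encoders
        cfg = SimulationConfig(
            n_species=5,
            records_per_species=6,
            seq_length=200,
            between_divergence=0.2,
            within_divergence=0.0,
            seed=11,
        )
        ds = simulate_dataset(cfg)
        plan = ev.species_level_split(ds, repetitions=2, seed=1)
        for encoder in ("dv", "fj"):
            report = ev.run_identification(ds, plan, encoder=encoder)
            assert report.n_excluded_singletons == 0
            assert report.success_rate == 1.0
            assert report.ci_lower <= 1.0 <= report.ci_upper

    def test_well_separated_dataset_identifies_most_queries(self, small_dataset):
        plan = ev.species_level_split(small_dataset, repetitions=2, seed=1)
        report = ev.run_identification(small_dataset, plan, encoder="fj")
        assert report.n_excluded_singletons == 0
        assert report.success_rate >= 0.9

    def test_kfold_singleton_is_excluded_from_denominator(self):
        cfg = SimulationConfig(
            n_species=4,
            records_per_species=8,
            seq_length=120,
            between_divergence=0.15,
            within_divergence=0.005,
            seed=2,
        )
        ds = simulate_dataset(cfg)
        rng = np.random.default_rng(99)
        lone_seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=120)])
        ds.records.append(BarcodeRecord("LONE1", "Loner species", lone_seq))
        plan = ev.k_fold_split(ds, k=3, seed=0)
        report = ev.run_identification(ds, plan, encoder="dv")
        assert report.n_excluded_singletons == 1
        statuses = [row[3] for row in report.rows if row[0] == "LONE1"]
        assert statuses == ["excluded_singleton"]
        assert report.n_counted == len(ds) - 1

    def test_empty_query_round_contributes_nothing(self):
        ds = make_dataset([2, 3])  # all species <= 3 records: reference only
        plan = ev.species_level_split(ds, repetitions=2, seed=0)
        report = ev.run_identification(ds, plan, encoder="dv")
        assert report.rows == []
        assert np.isnan(report.success_rate)

    def test_pooled_rate_is_weighted_mean_of_round_rates(self, small_dataset):
        plan = ev.species_level_split(small_dataset, repetitions=3, seed=9)
        report = ev.run_identification(small_dataset, plan, encoder="dv")
        n_rounds = [len(q) for _, q in plan.splits]
        assert report.n_counted == sum(n_rounds)
        # per-round accounting recombines into the pooled rate
        per_round_correct = []
        offset = 0
        for n in n_rounds:
            chunk = report.rows[offset : offset + n]
            per_round_correct.append(sum(r[3] == "correct" for r in chunk))
            offset += n
        assert sum(per_round_correct) / sum(n_rounds) == pytest.approx(
            report.success_rate
        )

    def test_report_summary_and_json_roundtrip(self, small_dataset, tmp_path):
        plan = ev.species_level_split(small_dataset, repetitions=1, seed=4)
        report = ev.run_identification(small_dataset, plan, encoder="dv")
        text = report.summary()
        assert "success rate" in text and "%" in text
        jp, tp = tmp_path / "r.json", tmp_path / "r.tsv"
        report.save(jp, tp)
        import json

        doc = json.loads(jp.read_text())
        assert doc["n_counted"] == report.n_counted
        assert tp.read_text().count("\n") == len(report.rows) + 1
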