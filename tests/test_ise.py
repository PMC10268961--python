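"""Range catalog, filter evaluation, combination counting, elimination,
exhaustive enumeration and full model builds."""

import itertools
import math

import numpy as np
import pytest

from isevs.chem_io import DescriptorTable
from isevs.ise import (
    DescriptorRange,
    Filter,
    IseConfig,
    IseError,
    Model,
    RangeCatalog,
    build_range_catalog,
    count_combinations,
    evaluate_filter,
    exhaustive_search,
    run_ise,
    stochastic_iteration,
)
from isevs.synthetic import generate_planted_fixture


def brute_force_rank(catalog, table, labels, filter_size=5):
    """Independent oracle: enumerate every filter combination, score each
    with its own confusion-count code, sort by (−MCC, lexicographic key)."""
    labels = np.asarray(labels)
    results = []
    names = catalog.descriptors
    for subset in itertools.combinations(names, filter_size):
        pools = [catalog.ranges_by_descriptor[n] for n in subset]
        for combo in itertools.product(*pools):
            mask = np.ones(table.n_molecules, dtype=bool)
            for r in combo:
                col = table.column(r.descriptor)
                mask &= (col >= r.low) & (col <= r.high)
            tp = int((mask & (labels == 1)).sum())
            fp = int((mask & (labels == 0)).sum())
            fn = int((labels == 1).sum()) - tp
            tn = int((labels == 0).sum()) - fp
            den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            mcc = (tp * tn - fp * fn) / math.sqrt(den) if den else 0.0
            key = tuple((r.descriptor, r.low, r.high) for r in combo)
            results.append((mcc, key, (tp, fp, tn, fn)))
    results.sort(key=lambda t: t[1])
    results.sort(key=lambda t: -t[0])
    return results


class TestRangeCatalog:
    def test_bin_count_formula(self, tiny_table):
        table, labels = tiny_table
        catalog = build_range_catalog(table, labels, n_bins=3)
        for name in table.descriptor_names:
            assert len(catalog.ranges_by_descriptor[name]) == 6  # 3·4/2

    def test_separated_classes_give_perfect_single_range(self):
        values = np.concatenate([np.linspace(10, 20, 8), np.linspace(30, 40, 8)])
        table = DescriptorTable([f"m{i}" for i in range(16)], ["d0"], values[:, None])
        labels = np.array([1] * 8 + [0] * 8)
        catalog = build_range_catalog(table, labels, n_bins=4)
        best = max(r.single_mcc for r in catalog.ranges_by_descriptor["d0"])
        assert best == 1.0

    def test_one_class_errors(self, tiny_table):
        table, _ = tiny_table
        with pytest.raises(IseError):
            build_range_catalog(table, np.ones(table.n_molecules, dtype=int))

    def test_constant_descriptor_degenerate(self):
        table = DescriptorTable(
            ["a", "b", "c", "d"], ["d0"], np.array([[5.0], [5.0], [5.0], [7.0]])
        )
        catalog = build_range_catalog(table, np.array([1, 1, 0, 0]), n_bins=4)
        (rng,) = catalog.ranges_by_descriptor["d0"]
        assert rng.degenerate and rng.low == rng.high == 5.0


class TestEvaluateFilter:
    def test_perfect_filter(self, tiny_table):
        table, labels = tiny_table
        f = Filter(
            ranges=tuple(DescriptorRange(f"d{i}", 0.0, 20.0) for i in range(5))
        )
        out = evaluate_filter(f, table, labels)
        assert (out.tp, out.fp, out.tn, out.fn) == (3, 0, 3, 0)
        assert out.mcc == 1.0

    def test_known_confusion_value(self):
        # tp=4, fp=1, tn=95, fn=0 → (4·95−0)/√(5·4·96·95)
        expected = 380 / math.sqrt(5 * 4 * 96 * 95)
        n = 100
        values = np.zeros((n, 5))
        values[:5] = 1.0  # 4 actives + 1 decoy inside the box
        table = DescriptorTable([f"m{i}" for i in range(n)], [f"d{i}" for i in range(5)], values)
        labels = np.array([1, 1, 1, 1, 0] + [0] * 95)
        f = Filter(ranges=tuple(DescriptorRange(f"d{i}", 0.5, 1.5) for i in range(5)))
        out = evaluate_filter(f, table, labels)
        assert (out.tp, out.fp, out.tn, out.fn) == (4, 1, 95, 0)
        assert out.mcc == pytest.approx(expected, abs=1e-12)
        assert out.mcc == pytest.approx(0.890, abs=5e-4)

    def test_filter_passing_nothing_scores_zero(self, tiny_table):
        table, labels = tiny_table
        f = Filter(
            ranges=tuple(DescriptorRange(f"d{i}", -10.0, -5.0) for i in range(5))
        )
        assert evaluate_filter(f, table, labels).mcc == 0.0

    def test_missing_descriptor_errors(self, tiny_table):
        table, labels = tiny_table
        f = Filter(
            ranges=tuple(
                DescriptorRange(n, 0, 1) for n in ["d0", "d1", "d2", "d3", "zz"]
            )
        )
        with pytest.raises(IseError, match="zz"):
            evaluate_filter(f, table, labels)

    def test_counts_sum_to_set_size(self, small_fixture):
        f = small_fixture.planted_filters[0]
        out = evaluate_filter(f, small_fixture.table, small_fixture.labels)
        assert out.tp + out.fp + out.tn + out.fn == small_fixture.table.n_molecules

    def test_duplicate_descriptors_rejected(self):
        with pytest.raises(ValueError):
            Filter(ranges=tuple(DescriptorRange("d0", 0, 1) for _ in range(5)))


def _catalog(counts: list[int]) -> RangeCatalog:
    return RangeCatalog(
        {
            f"d{i}": [DescriptorRange(f"d{i}", float(j), float(j)) for j in range(c)]
            for i, c in enumerate(counts)
        }
    )


class TestCountCombinations:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([2] * 6, 192),  # C(6,5)·2^5
            ([1] * 5, 1),
            ([3] * 4, 0),  # fewer than five descriptors
            ([3, 1, 2, 1, 1, 4], 3 * 2 * 4 * (1 + 1) + 3 * 2 * 4 + 2 * 4 + 3 * 4 + 3 * 2),
        ],
    )
    def test_closed_form(self, counts, expected):
        if counts == [3, 1, 2, 1, 1, 4]:
            # recompute the oracle explicitly rather than trusting arithmetic
            expected = sum(
                np.prod([counts[i] for i in sub])
                for sub in itertools.combinations(range(6), 5)
            )
        assert count_combinations(_catalog(counts)) == expected

    def test_matches_enumeration_on_random_catalogs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(1, 5, size=rng.integers(5, 9)).tolist()
            catalog = _catalog(counts)
            brute = sum(
                int(np.prod([counts[i] for i in sub]))
                for sub in itertools.combinations(range(len(counts)), 5)
            )
            assert count_combinations(catalog) == brute


class TestExhaustive:
    def test_full_enumeration_matches_oracle(self, small_fixture):
        table, labels = small_fixture.table, small_fixture.labels
        sub = table.select_columns([f"d{i:02d}" for i in range(7)])
        catalog = build_range_catalog(sub, labels, n_bins=2)
        filters = exhaustive_search(catalog, sub, labels)
        oracle = brute_force_rank(catalog, sub, labels)
        assert len(filters) == len(oracle) == count_combinations(catalog)
        for f, (mcc, key, counts) in zip(filters, oracle):
            assert f.sort_key() == key
            assert f.mcc == pytest.approx(mcc, abs=1e-12)
            assert (f.tp, f.fp, f.tn, f.fn) == counts

    def test_threshold_violation_names_count(self):
        catalog = _catalog([10] * 10)
        n = count_combinations(catalog)
        table = DescriptorTable(
            ["a", "b"], [f"d{i}" for i in range(10)], np.zeros((2, 10))
        )
        with pytest.raises(IseError, match=str(n)):
            exhaustive_search(catalog, table, np.array([1, 0]), exhaustive_threshold=100)


class TestStochasticIteration:
    def test_zero_elim_fraction_keeps_catalog(self, small_fixture):
        table, labels = small_fixture.table, small_fixture.labels
        catalog = build_range_catalog(table, labels, n_bins=4)
        rng = np.random.default_rng(0)
        out, rep = stochastic_iteration(
            catalog, table, labels, 2000, elim_fraction=0.0,
            min_observations=5, rng=rng, mode="mean",
        )
        assert rep.n_eliminated == 0
        assert out.counts() == catalog.counts()

    def test_invalid_sample_size(self, small_fixture):
        table, labels = small_fixture.table, small_fixture.labels
        catalog = build_range_catalog(table, labels, n_bins=4)
        with pytest.raises(IseError):
            stochastic_iteration(
                catalog, table, labels, 0, 0.2, 5, np.random.default_rng(0)
            )

    def test_planted_ranges_survive_elimination(self):
        """Ranges of a perfectly separating filter are never eliminated:
        their mean filter MCC strictly dominates the field."""
        fx = generate_planted_fixture(40, 400, n_descriptors=10, n_planted=1, seed=5)
        planted_keys = {
            r.key() for r in fx.planted_filters[0].ranges
        }
        for seed in range(50):
            rng = np.random.default_rng(seed)
            catalog = build_range_catalog(fx.table, fx.labels, n_bins=4)
            for mode in ("mean", "mean"):
                catalog, _ = stochastic_iteration(
                    catalog, fx.table, fx.labels, 5000, 0.2, 10, rng, mode=mode
                )
            surviving = {r.key() for r in catalog.all_ranges()}
            assert planted_keys <= surviving


class TestRunIse:
    def test_small_catalog_skips_stochastic_phase(self, small_fixture):
        table, labels = small_fixture.table, small_fixture.labels
        sub = table.select_columns([f"d{i:02d}" for i in range(6)])
        cfg = IseConfig(n_bins=2, seed=0)
        model = run_ise(sub, labels, cfg)
        assert model.iteration_summary == []  # already below the threshold
        assert model.n_enumerated == count_combinations(
            build_range_catalog(sub, labels, 2)
        )

    def test_matches_brute_force_without_elimination(self, small_fixture):
        table, labels = small_fixture.table, small_fixture.labels
        sub = table.select_columns([f"d{i:02d}" for i in range(7)])
        cfg = IseConfig(n_bins=2, seed=1, max_filters=None, retain_fraction=None)
        model = run_ise(sub, labels, cfg)
        oracle = brute_force_rank(build_range_catalog(sub, labels, 2), sub, labels)
        assert len(model.filters) == len(oracle)
        for f, (mcc, key, _) in zip(model.filters, oracle):
            assert f.sort_key() == key
            assert f.mcc == pytest.approx(mcc, abs=1e-12)

    def test_mcc_non_increasing(self, small_fixture):
        table, labels = small_fixture.table, small_fixture.labels
        model = run_ise(table, labels, IseConfig(n_bins=3, seed=2))
        mccs = [f.mcc for f in model.filters]
        assert all(a >= b for a, b in zip(mccs, mccs[1:]))

    def test_retention_cap_min_rule(self, small_fixture):
        table, labels = small_fixture.table, small_fixture.labels
        sub = table.select_columns([f"d{i:02d}" for i in range(6)])
        cfg = IseConfig(n_bins=2, seed=0)  # 6·3^5 = 1458 enumerated
        model = run_ise(sub, labels, cfg)
        assert model.n_enumerated == 1458
        assert len(model.filters) == math.ceil(0.2 * 1458)  # 20% < 1000 cap

    def test_deterministic_json(self, small_fixture):
        table, labels = small_fixture.table, small_fixture.labels
        cfg = IseConfig(n_bins=3, seed=9)
        a = run_ise(table, labels, cfg).to_json()
        b = run_ise(table, labels, cfg).to_json()
        assert a == b

    def test_json_round_trip_bit_exact(self, small_fixture):
        table, labels = small_fixture.table, small_fixture.labels
        model = run_ise(table, labels, IseConfig(n_bins=2, seed=4))
        text = model.to_json()
        assert Model.from_json(text).to_json() == text

    def test_too_few_descriptors_errors(self, small_fixture):
        table, labels = small_fixture.table, small_fixture.labels
        sub = table.select_columns([f"d{i:02d}" for i in range(4)])
        with pytest.raises(IseError):
            run_ise(sub, labels, IseConfig(seed=0))

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config"):
            IseConfig.from_dict({"seed": 1, "bogus": 2})
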