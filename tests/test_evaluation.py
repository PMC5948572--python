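import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from fallban import evaluation as ev
from fallban.types import DEFAULT_EXECUTIONS, FEATURE_NAMES, MOVEMENT_TYPES, Position


def _meta_frame():
    """Trial metadata matching the default design (no traces needed)."""
    rows = []
    for mtype, n in DEFAULT_EXECUTIONS.items():
        for i in range(n):
            rows.append({"trial_id": f"{mtype}-{i}", "movement_type": mtype})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- metrics


def test_binary_metrics_hand_example():
    se, sp, m = ev.binary_metrics(ev.ConfusionCounts(tp=9, fn=1, tn=8, fp=2))
    assert (se, sp) == (0.9, 0.8)
    assert m == pytest.approx(np.sqrt(0.72))


def test_binary_metrics_perfect_and_degenerate_detectors():
    assert ev.binary_metrics(ev.ConfusionCounts(5, 0, 5, 0)) == (1.0, 1.0, 1.0)
    assert ev.binary_metrics(ev.ConfusionCounts(0, 5, 5, 0)) == (0.0, 1.0, 0.0)


def test_binary_metrics_empty_class_error():
    with pytest.raises(ValueError, match="empty"):
        ev.binary_metrics(ev.ConfusionCounts(0, 0, 5, 0))


@settings(deadline=None, derandomize=True)
@given(
    tp=st.integers(0, 50), fn=st.integers(0, 50),
    tn=st.integers(0, 50), fp=st.integers(0, 50),
)
def test_metric_bounded_by_se_and_sp(tp, fn, tn, fp):
    assume(tp + fn > 0 and tn + fp > 0)
    se, sp, m = ev.binary_metrics(ev.ConfusionCounts(tp, fn, tn, fp))
    assert min(se, sp) - 1e-12 <= m <= max(se, sp) + 1e-12
    assert 0.0 <= m <= 1.0


def test_average_over_sensor_combos():
    assert ev.average_over_sensor_combos([(0.7, 0.9)] * 4) == (0.7, 0.9)
    assert ev.average_over_sensor_combos([(0.8, 0.8), (1.0, 1.0)]) == (0.9, 0.9)
    # all 31 combinations supplied -> divisor 31
    pairs = [(1.0, 1.0)] + [(0.0, 0.0)] * 30
    se, sp = ev.average_over_sensor_combos(pairs)
    assert se == pytest.approx(1 / 31)
    with pytest.raises(ValueError):
        ev.average_over_sensor_combos([])


# ---------------------------------------------------------------- masks & grids


def test_subset_enumeration_sizes():
    assert len(ev.all_feature_subsets()) == 63
    assert len(ev.all_sensor_subsets()) == 31


def test_mask_round_trip():
    subset = ("awdiff_max", "mu_ap")
    mask = ev.feature_mask(subset)
    assert mask == "010001"
    assert ev.mask_to_features(mask) == subset
    smask = ev.sensor_mask((Position.CHEST, Position.ANKLE))
    assert smask == "01001"
    assert ev.mask_to_positions(smask) == (Position.CHEST, Position.ANKLE)


def test_grid_rejects_empty_and_duplicate_subsets():
    with pytest.raises(ValueError, match="non-empty"):
        ev.ExperimentGrid(feature_subsets=((),))
    with pytest.raises(ValueError, match="unique"):
        ev.ExperimentGrid(
            feature_subsets=(("mu_smv",), ("mu_smv",)),
        )


# ---------------------------------------------------------------- split


def test_default_split_sizes():
    split = ev.split_dataset(_meta_frame(), ev.SplitPlan(seed=3))
    assert len(split.train_ids) == 183
    assert len(split.test_ids) == 563
    assert len(split.blocks) == 6
    assert sum(len(b) for b in split.blocks) == 563
    assert all(90 <= len(b) <= 97 for b in split.blocks)
    # per-type block counts as balanced as integrality allows
    meta = _meta_frame().set_index("trial_id")["movement_type"]
    for mtype in MOVEMENT_TYPES:
        per_block = [sum(meta[tid] == mtype for tid in b) for b in split.blocks]
        assert max(per_block) - min(per_block) <= 1


def test_split_is_deterministic_and_seed_sensitive():
    meta = _meta_frame()
    a = ev.split_dataset(meta, ev.SplitPlan(seed=3))
    b = ev.split_dataset(meta, ev.SplitPlan(seed=3))
    c = ev.split_dataset(meta, ev.SplitPlan(seed=4))
    assert a.train_ids == b.train_ids and a.blocks == b.blocks
    assert set(a.train_ids) != set(c.train_ids)
    assert len(c.train_ids) == 183  # same per-type counts regardless of seed


def test_split_infeasible_plan_rejected():
    meta = _meta_frame()
    plan = ev.SplitPlan(training_counts={"Jogging": 1000}, seed=0)
    with pytest.raises(ValueError, match="Jogging"):
        ev.split_dataset(meta, plan)


def test_split_partitions_without_overlap():
    split = ev.split_dataset(_meta_frame(), ev.SplitPlan(seed=11))
    all_ids = split.train_ids + split.test_ids
    assert len(all_ids) == len(set(all_ids)) == 746


# ---------------------------------------------------------------- ANOVA


def _toy_2x2():
    # 2 factors x 2 replicates; hand-computed sums of squares:
    # SS_A = 32, SS_B = 8, SS_AB = 0, SS_within = 2, SS_total = 42
    rows = []
    values = {(0, 0): [1, 2], (0, 1): [3, 4], (1, 0): [5, 6], (1, 1): [7, 8]}
    for (a, b), ys in values.items():
        for y in ys:
            rows.append({"A": a, "B": b, "metric": float(y)})
    return pd.DataFrame(rows)


def test_anova_matches_hand_computed_toy_exactly():
    table = ev.anova_decomposition(_toy_2x2(), ["A", "B"])
    ss = dict(zip(table.terms["term"], table.terms["ss"]))
    assert ss["A"] == pytest.approx(32.0, abs=1e-12)
    assert ss["B"] == pytest.approx(8.0, abs=1e-12)
    assert ss["A&B"] == pytest.approx(0.0, abs=1e-12)
    assert table.error_ss == pytest.approx(2.0, abs=1e-12)
    assert table.ss_total == pytest.approx(42.0, abs=1e-12)
    assert table.error_percent == pytest.approx(100 * 2 / 42)
    assert table.remainder_percent == pytest.approx(0.0, abs=1e-9)


def test_anova_agrees_with_statsmodels_on_balanced_design(rng):
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rows = []
    for a, b, c in itertools.product((0, 1), repeat=3):
        for _ in range(4):
            y = 1.0 + 2 * a - b + 0.5 * a * b + rng.normal(0, 0.3)
            rows.append({"A": a, "B": b, "C": c, "metric": y})
    df = pd.DataFrame(rows)
    ours = ev.anova_decomposition(df, ["A", "B", "C"])
    fit = ols("metric ~ A * B * C", data=df).fit()
    ref = sm.stats.anova_lm(fit, typ=1)
    mapping = {"A": "A", "B": "B", "C": "C", "A&B": "A:B", "A&C": "A:C",
               "B&C": "B:C", "A&B&C": "A:B:C"}
    ss = dict(zip(ours.terms["term"], ours.terms["ss"]))
    for term, ref_term in mapping.items():
        assert ss[term] == pytest.approx(ref["sum_sq"][ref_term], rel=1e-9), term
    assert ours.error_ss == pytest.approx(ref["sum_sq"]["Residual"], rel=1e-9)


def test_anova_single_source_of_variance():
    rows = []
    for a, b in itertools.product((0, 1), repeat=2):
        for _ in range(3):
            rows.append({"A": a, "B": b, "metric": 10.0 * a})
    table = ev.anova_decomposition(pd.DataFrame(rows), ["A", "B"])
    pct = dict(zip(table.terms["term"], table.terms["percent"]))
    assert pct["A"] == pytest.approx(100.0, abs=1e-9)
    assert table.error_percent == pytest.approx(0.0, abs=1e-9)


def test_anova_percent_conservation(rng):
    rows = []
    for a, b, c in itertools.product((0, 1), repeat=3):
        for _ in range(3):
            rows.append({"A": a, "B": b, "C": c, "metric": rng.normal()})
    table = ev.anova_decomposition(pd.DataFrame(rows), ["A", "B", "C"])
    total = table.terms["percent"].sum() + table.error_percent + table.remainder_percent
    assert total == pytest.approx(100.0, abs=1e-9)


def test_anova_handles_incomplete_factorial_design(rng):
    # all-absent cell missing (63 of 64 cells), as in a non-empty-subset grid
    rows = []
    for levels in itertools.product((0, 1), repeat=6):
        if sum(levels) == 0:
            continue
        for _ in range(2):
            rows.append(
                dict(zip("ABCDEF", levels), metric=levels[2] + rng.normal(0, 0.1))
            )
    table = ev.anova_decomposition(pd.DataFrame(rows), list("ABCDEF"))
    pct = dict(zip(table.terms["term"], table.terms["percent"]))
    assert max(pct, key=pct.get) == "C"
    total = table.terms["percent"].sum() + table.error_percent + table.remainder_percent
    assert total == pytest.approx(100.0, abs=1e-6)


def test_anova_degenerate_when_all_responses_equal():
    rows = [
        {"A": a, "B": b, "metric": 5.0}
        for a, b in itertools.product((0, 1), repeat=2)
        for _ in range(2)
    ]
    table = ev.anova_decomposition(pd.DataFrame(rows), ["A", "B"])
    assert table.degenerate


def test_anova_rejects_unbalanced_design():
    df = _toy_2x2().iloc[:-1]
    with pytest.raises(ValueError, match="unbalanced"):
        ev.anova_decomposition(df, ["A", "B"])


def test_anova_rejects_single_level_factor():
    df = _toy_2x2()
    df["B"] = 0
    with pytest.raises(ValueError, match="fewer than 2 levels"):
        ev.anova_decomposition(df, ["A", "B"])


# ---------------------------------------------------------------- post-hoc


def _series(cells: dict[str, list[float]]) -> pd.DataFrame:
    rows = [
        {"cell": cid, "metric": v} for cid, vals in cells.items() for v in vals
    ]
    return pd.DataFrame(rows)


def test_posthoc_identical_series_overlap():
    ph = ev.posthoc_compare(
        _series({"10": [0.8, 0.9, 0.85], "01": [0.8, 0.9, 0.85]}), "cell"
    )
    assert set(ph["flag"]) <= {"optimal", "equivalent"}
    assert (ph["flag"] == "optimal").sum() == 1


def test_posthoc_separated_cells_flag_worse():
    ph = ev.posthoc_compare(
        _series({"10": [0.95, 0.96, 0.94], "01": [0.30, 0.31, 0.29]}), "cell"
    )
    flags = dict(zip(ph["cell"], ph["flag"]))
    assert flags["10"] == "optimal"
    assert flags["01"] == "worse"


def test_posthoc_interval_width_shrinks_with_replicates(rng):
    def width(n_rep):
        cells = {c: list(rng.normal(0.8, 0.05, n_rep)) for c in ("10", "01", "11")}
        ph = ev.posthoc_compare(_series(cells), "cell")
        return float((ph["hi"] - ph["lo"]).iloc[0])

    assert width(24) < width(6)


def test_posthoc_requires_two_cells():
    with pytest.raises(ValueError, match="at least 2"):
        ev.posthoc_compare(_series({"10": [1.0, 1.0]}), "cell")


def test_optimal_prefers_lower_dimension_among_equivalents():
    # sizes 4 and 6 statistically indistinguishable -> size 4 wins
    ph = ev.posthoc_compare(
        _series({"111111": [0.90, 0.92, 0.91], "111100": [0.90, 0.91, 0.92]}),
        "cell",
    )
    flags = dict(zip(ph["cell"], ph["flag"]))
    assert flags["111100"] == "optimal"
    assert flags["111111"] == "equivalent"


def test_optimal_tie_on_dimension_goes_to_higher_mean():
    ph = ev.posthoc_compare(
        _series({"110000": [0.90, 0.91, 0.92], "001100": [0.91, 0.92, 0.93]}),
        "cell",
    )
    assert dict(zip(ph["cell"], ph["flag"]))["001100"] == "optimal"


def test_unique_best_without_overlap_wins():
    ph = ev.posthoc_compare(
        _series({"1": [0.99, 0.98, 0.99], "0": [0.50, 0.51, 0.49]}), "cell"
    )
    assert dict(zip(ph["cell"], ph["flag"]))["1"] == "optimal"


# ---------------------------------------------------------------- diagnostics


def test_diagnostics_identical_series_pass_vacuously():
    diag = ev.residual_diagnostics(
        _series({"10": [0.9, 0.9, 0.9], "01": [0.8, 0.8, 0.8]}), "cell"
    )
    np.testing.assert_allclose(diag.residuals, 0.0, atol=1e-12)
    assert diag.homoscedastic


def test_diagnostics_variance_ratio_above_four_fails(rng):
    cells = {
        "10": list(rng.normal(0, 1.0, 30)),
        "01": list(rng.normal(0, np.sqrt(5.0), 30)),
    }
    diag = ev.residual_diagnostics(_series(cells), "cell")
    assert diag.variance_ratio > 4.0
    assert not diag.homoscedastic


def test_diagnostics_gaussian_residuals_track_normal_quantiles(rng):
    vals = rng.normal(0.0, 1.0, 186)
    cells = {"only": list(vals), "other": list(rng.normal(0.0, 1.0, 186))}
    diag = ev.residual_diagnostics(_series(cells), "cell")
    corr = np.corrcoef(diag.qq_theoretical, diag.qq_sample)[0, 1]
    assert corr > 0.99


def test_power_transform_hook():
    df = _series({"10": [0.25, 0.36], "01": [0.49, 0.64]})
    out = ev.power_transform(df, 0.5)
    np.testing.assert_allclose(out["metric"], np.sqrt(df["metric"]))
    with pytest.raises(ValueError):
        ev.power_transform(df, -1.0)


# ---------------------------------------------------------------- experiment


def test_factorial_experiment_shapes_and_fusion_behavior(small_dataset):
    from fallban import features as ft

    table = ft.feature_table(small_dataset)
    counts = {m: 1 for m in MOVEMENT_TYPES}
    plan = ev.SplitPlan(training_counts=counts, n_blocks=2, seed=0)
    split = ev.split_dataset(table, plan)
    grid = ev.ExperimentGrid(
        algorithms=("decision_tree",),
        feature_subsets=(("sigma_smv", "mu_ap"),),
        sensor_subsets=(
            (Position.CHEST,),
            (Position.CHEST, Position.ANKLE),
        ),
    )
    res = ev.run_factorial_experiment(table, grid, split)
    assert len(res) == 2 * 2  # 2 sensor subsets x 2 blocks
    assert set(res["block"]) == {0, 1}
    # AND fusion: adding ankle can only lower Se and raise Sp per block
    single = res[res.sensor_mask == "01000"].set_index("block")
    fused = res[res.sensor_mask == "01001"].set_index("block")
    assert (fused["se"] <= single["se"] + 1e-12).all()
    assert (fused["sp"] >= single["sp"] - 1e-12).all()


def test_feature_study_series_aggregates_before_geometric_mean():
    res = pd.DataFrame(
        {
            "algorithm": ["svm"] * 2,
            "feature_mask": ["100000"] * 2,
            "sensor_mask": ["01000", "00100"],
            "block": [0, 0],
            "se": [1.0, 0.5],
            "sp": [0.5, 1.0],
            "metric": [np.sqrt(0.5), np.sqrt(0.5)],
        }
    )
    agg = ev.feature_study_series(res)
    assert len(agg) == 1
    assert agg["metric"].iloc[0] == pytest.approx(0.75)  # sqrt(0.75 * 0.75)


def test_expand_mask_factors():
    df = pd.DataFrame({"feature_mask": ["101010", "010101"]})
    out = ev.expand_mask_factors(df, "feature_mask", list(FEATURE_NAMES))
    assert out["mu_smv"].tolist() == [1, 0]
    assert out["mu_ap"].tolist() == [0, 1]
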