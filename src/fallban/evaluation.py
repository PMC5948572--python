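"""Split design, detection metrics, factorial experiments and ANOVA.

The evaluation follows a blocked factorial protocol: trials are split
into a stratified training set and six test blocks; every combination
of (algorithm, feature subset, sensor subset) is trained and scored per
block with the geometric mean sqrt(Se * Sp) of sensitivity and
specificity; the resulting metric series are decomposed by a 2^k
factorial ANOVA into percent-of-variance contributions, compared post
hoc with Tukey-style 95% intervals, and checked with residual
diagnostics (normal-quantile pairs and the 4:1 max/min cell-variance
heuristic for balanced designs).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from fallban import detectors
from fallban.types import (
    DEFAULT_TRAINING_COUNTS,
    FEATURE_NAMES,
    MOVEMENT_TYPES,
    POSITIONS,
    Position,
)

# --------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")


def binary_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Sensitivity, specificity and their geometric mean.

    Se = TP/(TP+FN), Sp = TN/(TN+FP), metric = sqrt(Se * Sp).
    """
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValueError("metric undefined: a class is empty in the test set")
    se = counts.tp / (counts.tp + counts.fn)
    sp = counts.tn / (counts.tn + counts.fp)
    return se, sp, float(np.sqrt(se * sp))


def average_over_sensor_combos(pairs) -> tuple[float, float]:
    """Unweighted mean (Se, Sp) over the supplied sensor combinations."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no sensor-combination metrics supplied")
    se = float(np.mean([p[0] for p in pairs]))
    sp = float(np.mean([p[1] for p in pairs]))
    return se, sp


# --------------------------------------------------------------------------
# subset masks


def feature_mask(subset) -> str:
    """Canonical '0'/'1' mask over the six features (A..F order)."""
    names = set(subset)
    unknown = names - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature(s): {sorted(unknown)}")
    return "".join("1" if f in names else "0" for f in FEATURE_NAMES)


def sensor_mask(subset) -> str:
    """Canonical '0'/'1' mask over the five positions."""
    pos = {Position(p) for p in subset}
    return "".join("1" if p in pos else "0" for p in POSITIONS)


def mask_to_features(mask: str) -> tuple[str, ...]:
    return tuple(f for f, b in zip(FEATURE_NAMES, mask) if b == "1")


def mask_to_positions(mask: str) -> tuple[Position, ...]:
    return tuple(p for p, b in zip(POSITIONS, mask) if b == "1")


def all_feature_subsets() -> list[tuple[str, ...]]:
    """All 63 non-empty subsets of the six features."""
    out = []
    for r in range(1, len(FEATURE_NAMES) + 1):
        out.extend(itertools.combinations(FEATURE_NAMES, r))
    return out


def all_sensor_subsets() -> list[tuple[Position, ...]]:
    """All 31 non-empty subsets of the five positions."""
    out = []
    for r in range(1, len(POSITIONS) + 1):
        out.extend(itertools.combinations(POSITIONS, r))
    return out


# --------------------------------------------------------------------------
# split design


@dataclass
class SplitPlan:
    """Stratified train/test split with blocked test replicates."""

    training_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TRAINING_COUNTS)
    )
    n_blocks: int = 6
    seed: int = 0


@dataclass
class Split:
    train_ids: list[str]
    blocks: list[list[str]]

    @property
    def test_ids(self) -> list[str]:
        return [tid for block in self.blocks for tid in block]


def split_dataset(trials, plan: SplitPlan) -> Split:
    """Assign trials to a training set and ``n_blocks`` test blocks.

    Stratified by movement type: exactly the planned number of training
    trials per type; the remainder is dealt round-robin across blocks
    (rotating the starting block per type) so per-type block counts
    differ by at most one.
    """
    if isinstance(trials, pd.DataFrame):
        meta = trials[["trial_id", "movement_type"]].drop_duplicates()
        pairs = list(meta.itertuples(index=False, name=None))
    else:
        pairs = [(t.trial_id, t.movement_type) for t in trials]
    by_type: dict[str, list[str]] = {}
    for tid, mtype in pairs:
        by_type.setdefault(mtype, []).append(tid)

    train_ids: list[str] = []
    blocks: list[list[str]] = [[] for _ in range(plan.n_blocks)]
    for type_index, mtype in enumerate(MOVEMENT_TYPES):
        ids = by_type.get(mtype, [])
        if not ids:
            continue
        n_train = plan.training_counts.get(mtype, 0)
        if n_train > len(ids):
            raise ValueError(
                f"plan requests {n_train} training trials of {mtype!r}, "
                f"only {len(ids)} available"
            )
        rng = np.random.default_rng([plan.seed, type_index])
        perm = rng.permutation(len(ids))
        shuffled = [ids[i] for i in perm]
        train_ids.extend(shuffled[:n_train])
        rest = shuffled[n_train:]
        offset = type_index % plan.n_blocks
        for j, tid in enumerate(rest):
            blocks[(offset + j) % plan.n_blocks].append(tid)
    return Split(train_ids=train_ids, blocks=blocks)


# --------------------------------------------------------------------------
# factorial experiment


@dataclass
class ExperimentGrid:
    """The factorial design: algorithms x feature subsets x sensor subsets."""

    algorithms: tuple[str, ...] = detectors.ALGORITHMS
    feature_subsets: tuple = ()
    sensor_subsets: tuple = ()
    policy: str = "AND"

    def __post_init__(self) -> None:
        if not self.feature_subsets:
            self.feature_subsets = tuple(all_feature_subsets())
        if not self.sensor_subsets:
            self.sensor_subsets = tuple(all_sensor_subsets())
        for fs in self.feature_subsets:
            if not fs:
                raise ValueError("feature subsets must be non-empty")
        for ss in self.sensor_subsets:
            if not ss:
                raise ValueError("sensor subsets must be non-empty")
        fmasks = [feature_mask(fs) for fs in self.feature_subsets]
        smasks = [sensor_mask(ss) for ss in self.sensor_subsets]
        if len(set(fmasks)) != len(fmasks) or len(set(smasks)) != len(smasks):
            raise ValueError("grid cells must be unique")


def run_factorial_experiment(
    table: pd.DataFrame, grid: ExperimentGrid, split: Split
) -> pd.DataFrame:
    """Score every grid cell on every test block.

    ``table`` is a feature table (one row per trial x position). For
    each (algorithm, feature subset, position) a detector is trained
    once on the training rows and its per-trial decisions are cached;
    each cell then fuses the decisions of its sensor subset with the
    grid policy and is scored per block.

    Returns a tidy frame with columns ``algorithm``, ``feature_mask``,
    ``sensor_mask``, ``block``, ``se``, ``sp``, ``metric``.
    """
    train_set = set(split.train_ids)
    test_ids = split.test_ids
    test_index = {tid: i for i, tid in enumerate(test_ids)}
    n_test = len(test_ids)
    block_masks = []
    for block in split.blocks:
        m = np.zeros(n_test, dtype=bool)
        m[[test_index[tid] for tid in block]] = True
        block_masks.append(m)

    labels = (
        table[["trial_id", "label"]].drop_duplicates().set_index("trial_id")["label"]
    )
    y_true = labels.reindex(test_ids).to_numpy() == detectors.FALL

    positions_needed = sorted(
        {Position(p) for ss in grid.sensor_subsets for p in ss},
        key=list(Position).index,
    )
    by_pos = {
        pos: g.set_index("trial_id")
        for pos, g in (
            (Position(p), g) for p, g in table.groupby("position", sort=False)
        )
        if pos in positions_needed
    }
    missing = [p.value for p in positions_needed if p not in by_pos]
    if missing:
        raise ValueError(f"feature table lacks position(s): {missing}")

    cache: dict[tuple[str, str, Position], np.ndarray] = {}
    for alg in grid.algorithms:
        for fs in grid.feature_subsets:
            fmask = feature_mask(fs)
            for pos in positions_needed:
                rows = by_pos[pos]
                train_rows = rows.loc[rows.index.isin(train_set)]
                test_rows = rows.reindex(test_ids)
                try:
                    det = detectors.train_detector(alg, train_rows, fs, position=pos)
                    pred = det.predict(test_rows) == detectors.FALL
                except Exception as exc:
                    raise RuntimeError(
                        f"training failed for cell (algorithm={alg}, "
                        f"features={fmask}, position={pos.value}): {exc}"
                    ) from exc
                cache[(alg, fmask, pos)] = pred

    records = []
    for alg in grid.algorithms:
        for fs in grid.feature_subsets:
            fmask = feature_mask(fs)
            for ss in grid.sensor_subsets:
                smask = sensor_mask(ss)
                preds = [cache[(alg, fmask, Position(p))] for p in ss]
                fused = (
                    np.logical_and.reduce(preds)
                    if grid.policy == "AND"
                    else np.logical_or.reduce(preds)
                )
                for b, bm in enumerate(block_masks):
                    yt, yp = y_true[bm], fused[bm]
                    counts = ConfusionCounts(
                        tp=int(np.sum(yt & yp)),
                        fn=int(np.sum(yt & ~yp)),
                        tn=int(np.sum(~yt & ~yp)),
                        fp=int(np.sum(~yt & yp)),
                    )
                    se, sp, metric = binary_metrics(counts)
                    records.append(
                        (alg, fmask, smask, b, se, sp, metric)
                    )
    return pd.DataFrame(
        records,
        columns=["algorithm", "feature_mask", "sensor_mask", "block", "se", "sp", "metric"],
    )


def feature_study_series(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate over sensor combinations for the feature study.

    For each (algorithm, feature_mask, block), Se and Sp are averaged
    over the sensor combinations present and the metric is the
    geometric mean of the averaged pair.
    """
    g = results.groupby(["algorithm", "feature_mask", "block"], as_index=False).agg(
        se=("se", "mean"), sp=("sp", "mean")
    )
    g["metric"] = np.sqrt(g["se"] * g["sp"])
    return g


def expand_mask_factors(
    df: pd.DataFrame, mask_col: str, factor_names
) -> pd.DataFrame:
    """Add one 0/1 column per factor from a '0'/'1' mask column."""
    out = df.copy()
    for i, name in enumerate(factor_names):
        out[name] = df[mask_col].str[i].astype(int)
    return out


# --------------------------------------------------------------------------
# ANOVA decomposition


@dataclass
class AnovaTable:
    """Percent-of-variance decomposition of a balanced factorial design.

    ``terms`` has one row per factorial term (name, order, ss, percent);
    ``error_percent`` is the within-cell residual share and
    ``remainder_percent`` any between-cell share not captured by the
    included terms (non-zero only when ``max_order`` truncates the
    decomposition or aliasing is present).
    """

    terms: pd.DataFrame
    ss_total: float
    error_ss: float
    error_percent: float
    remainder_percent: float
    degenerate: bool = False

    def display(self, floor: float = 1.0) -> pd.DataFrame:
        """Main effects, interactions above ``floor`` percent, and error."""
        t = self.terms
        keep = t[(t["order"] == 1) | (t["percent"] >= floor)].copy()
        err = pd.DataFrame(
            [{"term": "Error", "order": 0, "ss": self.error_ss,
              "percent": self.error_percent}]
        )
        return pd.concat([keep, err], ignore_index=True)


def anova_decomposition(
    values: pd.DataFrame,
    factors: list[str],
    response: str = "metric",
    max_order: int | None = None,
) -> AnovaTable:
    """Decompose total variance over 2^k factorial terms plus residual.

    ``values`` must hold a balanced design: one 0/1 column per factor
    and an equal number of replicate rows for every factor-level cell.
    Sums of squares are computed by sequentially orthogonalizing the
    +/-1-coded contrast columns (mains first, then interactions by
    ascending order); for a complete balanced design the columns are
    already orthogonal and the decomposition is the classical one.
    Percent contribution = SS_term / SS_total * 100.
    """
    if len(factors) < 1:
        raise ValueError("at least one factor required")
    for f in factors:
        if values[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    counts = values.groupby(factors).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal replicates per cell")

    y = values[response].to_numpy(dtype=float)
    n = y.size
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    cell_means = values.groupby(factors)[response].transform("mean").to_numpy()
    error_ss = float(((y - cell_means) ** 2).sum())

    if ss_total <= 1e-30:
        empty = pd.DataFrame(columns=["term", "order", "ss", "percent"])
        return AnovaTable(empty, ss_total, error_ss, 0.0, 0.0, degenerate=True)

    coded = {f: 2.0 * values[f].to_numpy(dtype=float) - 1.0 for f in factors}
    max_order = len(factors) if max_order is None else max_order
    term_defs = []
    for r in range(1, max_order + 1):
        term_defs.extend(itertools.combinations(factors, r))

    # sequential (modified Gram-Schmidt) projection; centered response
    yc = y - grand
    basis: list[np.ndarray] = []
    rows = []
    ss_terms_sum = 0.0
    for term in term_defs:
        c = np.ones(n)
        for f in term:
            c = c * coded[f]
        c = c - c.mean()
        norm0 = np.linalg.norm(c)
        for _ in range(2):  # re-orthogonalize for stability
            for q in basis:
                c = c - (q @ c) * q
        norm = np.linalg.norm(c)
        if norm0 == 0 or norm / max(norm0, 1.0) < 1e-10:
            ss = 0.0  # aliased with earlier terms
        else:
            q = c / norm
            basis.append(q)
            ss = float((q @ yc) ** 2)
        ss_terms_sum += ss
        rows.append(
            {
                "term": "&".join(term),
                "order": len(term),
                "ss": ss,
                "percent": 100.0 * ss / ss_total,
            }
        )
    terms = pd.DataFrame(rows, columns=["term", "order", "ss", "percent"])
    error_percent = 100.0 * error_ss / ss_total
    remainder = ss_total - error_ss - ss_terms_sum
    remainder_percent = 100.0 * remainder / ss_total
    return AnovaTable(
        terms=terms,
        ss_total=ss_total,
        error_ss=error_ss,
        error_percent=error_percent,
        remainder_percent=remainder_percent,
    )


# --------------------------------------------------------------------------
# post-hoc comparison


def posthoc_compare(
    values: pd.DataFrame,
    cell_col: str,
    response: str = "metric",
    alpha: float = 0.05,
    dimension=None,
) -> pd.DataFrame:
    """Per-cell means with Tukey-style 95% comparison intervals.

    Interval half-width is q(1-alpha, k, df) * sqrt(s2/n) / 2 with s2
    the pooled within-cell variance, so two cells differ significantly
    exactly when their intervals do not overlap. Flags: ``optimal`` for
    the lowest-dimension cell statistically equivalent to the best
    mean, ``equivalent`` for other cells overlapping the optimum, and
    ``worse`` otherwise. ``dimension`` maps a cell id to its size
    (default: number of '1's in the mask string).
    """
    groups = values.groupby(cell_col)[response]
    k = groups.ngroups
    if k < 2:
        raise ValueError("post-hoc comparison needs at least 2 cells")
    sizes = groups.size()
    if sizes.nunique() != 1:
        raise ValueError("unbalanced design: unequal replicates per cell")
    n_rep = int(sizes.iloc[0])
    means = groups.mean()
    df_err = k * (n_rep - 1)
    if df_err > 0:
        s2 = float(groups.apply(lambda g: ((g - g.mean()) ** 2).sum()).sum() / df_err)
        q = stats.studentized_range.ppf(1 - alpha, k, df_err) if s2 > 0 else 0.0
        half = 0.5 * q * np.sqrt(s2 / n_rep)
    else:
        half = 0.0
    out = pd.DataFrame(
        {
            "cell": means.index,
            "mean": means.to_numpy(),
            "lo": means.to_numpy() - half,
            "hi": means.to_numpy() + half,
        }
    ).reset_index(drop=True)
    if dimension is None:
        dimension = lambda cell: str(cell).count("1")
    out["dimension"] = [dimension(c) for c in out["cell"]]

    best = out.loc[out["mean"].idxmax()]
    overlaps = (out["hi"] >= best["lo"]) & (out["lo"] <= best["hi"])
    optimal_cell = select_optimal_combo(out[overlaps])
    out["flag"] = np.where(overlaps, "equivalent", "worse")
    out.loc[out["cell"] == optimal_cell, "flag"] = "optimal"
    return out


def select_optimal_combo(posthoc: pd.DataFrame) -> str:
    """Lowest-dimension cell among those equivalent to the best mean.

    Ties broken by higher mean, then lexicographic cell id.
    """
    if posthoc.empty:
        raise ValueError("empty post-hoc table")
    t = posthoc
    if "flag" in t.columns:
        t = t[t["flag"].isin(("optimal", "equivalent"))]
        if t.empty:
            t = posthoc
    ranked = t.sort_values(
        by=["dimension", "mean", "cell"], ascending=[True, False, True]
    )
    return str(ranked.iloc[0]["cell"])


# --------------------------------------------------------------------------
# residual diagnostics


@dataclass
class DiagnosticsReport:
    residuals: np.ndarray
    fitted: np.ndarray
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    cell_variances: pd.Series
    variance_ratio: float
    homoscedastic: bool


def residual_diagnostics(
    values: pd.DataFrame,
    cell_col: str,
    response: str = "metric",
    var_floor: float = 1e-6,
) -> DiagnosticsReport:
    """Residuals, normal-quantile pairs and the 4:1 variance-ratio check.

    Residuals are observation minus cell mean. Cells with variance
    below ``var_floor`` (degenerate, e.g. metric pinned at a bound)
    are excluded from the max/min variance ratio; the design is deemed
    homoscedastic when the ratio does not exceed 4 (vacuously true if
    fewer than two cells remain).
    """
    groups = values.groupby(cell_col)[response]
    fitted = groups.transform("mean").to_numpy()
    residuals = values[response].to_numpy(dtype=float) - fitted
    n = residuals.size
    order = np.argsort(residuals)
    qq_sample = residuals[order]
    probs = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    qq_theoretical = stats.norm.ppf(probs)
    cell_var = groups.var(ddof=1)
    live = cell_var[cell_var >= var_floor]
    if len(live) >= 2:
        ratio = float(live.max() / live.min())
        homoscedastic = ratio <= 4.0
    else:
        ratio = 1.0
        homoscedastic = True
    return DiagnosticsReport(
        residuals=residuals,
        fitted=fitted,
        qq_theoretical=qq_theoretical,
        qq_sample=qq_sample,
        cell_variances=cell_var,
        variance_ratio=ratio,
        homoscedastic=homoscedastic,
    )


# --------------------------------------------------------------------------
# optional response transformation


def power_transform(values: pd.DataFrame, alpha: float, response: str = "metric") -> pd.DataFrame:
    """Exploratory y^alpha pre-ANOVA transformation (off by default)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    out = values.copy()
    out[response] = out[response] ** alpha
    return out
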