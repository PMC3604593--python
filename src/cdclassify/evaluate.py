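"""Confusion counting, the empirical FDR, and the threshold-sweep study.

The FDR here is a descriptive accuracy measure of a finished
classification, not a multiple-testing adjustment: over the genes assigned
to either condition, FDR = Fp/(Fp+Tp), and 0 when nothing was assigned.
Genes put in the "no differential expression" group do not enter the
ratio.

The threshold sweep repeats, per simulation replicate: simulate → fit the
PC space → classify at every threshold of a grid → FDR per threshold →
keep the *largest* threshold attaining the minimal FDR (the best
threshold).  Replicates are pooled into mean / sd / 2.5-50-97.5 percentile
summaries for both the FDR (at each replicate's best threshold) and the
best thresholds themselves, the latter reported on the 1−C_d scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as cls
from .cd import apply_norm_filter, compute_cd
from .classify import ClassificationResult
from .dapc import map_clusters_to_conditions, run_dapc
from .datamodel import ExpressionMatrix, TruthLabels, UNASSIGNED
from .pcspace import PCSpace, Direction, build_directions, fit_pca
from .simulate import ScenarioConfig, scenario_defaults, simulate

logger = logging.getLogger(__name__)

FDR_COLUMNS = ["Mean FDR", "FDR Sd", "FDR p_2.5", "FDR p_50", "FDR p_97.5"]
THRESHOLD_COLUMNS = [
    "Mean threshold", "Threshold Sd",
    "Threshold p_2.5", "Threshold p_50", "Threshold p_97.5",
]


@dataclass
class ConfusionCounts:
    """Tp/Fp/Tn/Fn of a two-condition classification against truth."""

    Tp: int
    Fp: int
    Tn: int
    Fn: int

    def __post_init__(self) -> None:
        if min(self.Tp, self.Fp, self.Tn, self.Fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def R(self) -> int:
        """Total genes declared to belong to a condition."""
        return self.Tp + self.Fp

    @property
    def total(self) -> int:
        return self.Tp + self.Fp + self.Tn + self.Fn


def confusion(labels: ClassificationResult, truth: TruthLabels) -> ConfusionCounts:
    """Count Tp/Fp/Tn/Fn.

    Tp: condition-labeled genes whose true condition matches; Fp:
    condition-labeled genes whose truth differs (wrong condition or truly
    null); Tn/Fn: unlabeled genes that are truly null / truly DE.
    """
    t = truth.as_series()
    missing = [g for g in labels.gene_ids if g not in t.index]
    if missing:
        raise ValueError(f"gene {missing[0]!r} missing from truth labels")
    true = t.loc[labels.gene_ids].to_numpy(dtype=object)
    pred = labels.labels
    pos = pred != UNASSIGNED
    tp = int(np.sum(pos & (pred == true)))
    fp = int(np.sum(pos & (pred != true)))
    tn = int(np.sum(~pos & (true == UNASSIGNED)))
    fn = int(np.sum(~pos & (true != UNASSIGNED)))
    return ConfusionCounts(tp, fp, tn, fn)


def fdr(counts: ConfusionCounts) -> float:
    """Fp/(Fp+Tp); by convention 0 when no gene was declared positive."""
    if counts.R == 0:
        return 0.0
    return counts.Fp / counts.R


def default_threshold_grid() -> np.ndarray:
    """0.970 to 0.998 in steps of 0.004, with 0.999 appended."""
    grid = np.round(np.arange(0.970, 0.9981, 0.004), 3)
    return np.append(grid, 0.999)


# ---------------------------------------------------------------------------
# simulation → classification plumbing shared by the sweep and benchmarks


@dataclass
class SimInstance:
    """One simulated data set with its fitted PC space and filtered C_d."""

    config: ScenarioConfig
    matrix: ExpressionMatrix
    truth: TruthLabels
    space: PCSpace
    directions: list[Direction]
    cd: "object"  # CdResult
    _dapc_labels: ClassificationResult | None = field(default=None, repr=False)

    def dapc_classification(self, seed: int) -> ClassificationResult:
        """k = 3 DAPC on the full gene set (cached per instance)."""
        if self._dapc_labels is None:
            mapped = map_clusters_to_conditions(
                run_dapc(self.space, k=3, seed=seed), self.directions
            )
            self._dapc_labels = cls.classify_dapc_only(mapped)
        return self._dapc_labels


def prepare_instance(
    config: ScenarioConfig,
    n_components: int = 2,
    filter_quantile: float = 0.25,
) -> SimInstance:
    matrix, truth = simulate(config)
    space = fit_pca(matrix, n_components=n_components)
    directions = build_directions(space, matrix)
    cd = apply_norm_filter(compute_cd(space, directions), filter_quantile)
    return SimInstance(config, matrix, truth, space, directions, cd)


def method_labels(
    inst: SimInstance,
    method: str,
    threshold: float,
    seed: int = 0,
    k_subset: int = 2,
) -> ClassificationResult:
    """Run one strategy on a prepared instance."""
    if method == cls.STRATEGY_DAPC:
        return inst.dapc_classification(seed)
    if method == cls.STRATEGY_CD:
        return cls.classify_cd_only(inst.cd, threshold)
    if method == cls.STRATEGY_CD_WITH_DAPC:
        return cls.classify_cd_with_dapc(
            inst.cd, inst.space, inst.directions, threshold,
            k=k_subset, seed=seed,
        )
    if method == cls.STRATEGY_CD_INTER_DAPC:
        return cls.classify_cd_inter_dapc(
            cls.classify_cd_only(inst.cd, threshold),
            inst.dapc_classification(seed),
        )
    raise ValueError(f"unknown method {method!r}")


def method_fdr(
    inst: SimInstance, method: str, threshold: float, seed: int = 0,
    k_subset: int = 2,
) -> float:
    return fdr(confusion(method_labels(inst, method, threshold, seed, k_subset), inst.truth))


def _replicate_seeds(seed: int, reps: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(reps)]


def replicate_fdrs(
    mode: str,
    scenario: str,
    method: str,
    threshold: float,
    reps: int,
    seed: int = 0,
    k_subset: int = 2,
    config_overrides: dict | None = None,
    max_failure_fraction: float = 0.2,
) -> np.ndarray:
    """Per-replicate FDR of one strategy at one fixed threshold.

    Each replicate simulates a fresh data set (seed derived from ``seed``),
    fits the space and evaluates the method against truth.  Replicates
    where the method cannot run (e.g. too few genes pass the threshold)
    are dropped with a warning; more than ``max_failure_fraction`` failures
    is an error.
    """
    overrides = config_overrides or {}
    out: list[float] = []
    failures = 0
    for rep_seed in _replicate_seeds(seed, reps):
        config = scenario_defaults(mode, scenario, seed=rep_seed, **overrides)
        inst = prepare_instance(config)
        try:
            out.append(method_fdr(inst, method, threshold, seed=rep_seed, k_subset=k_subset))
        except ValueError as exc:
            failures += 1
            logger.warning("WARN: replicate failed and was excluded: %s", exc)
    if failures > max_failure_fraction * reps:
        raise RuntimeError(
            f"{failures}/{reps} replicates failed; results would be unreliable"
        )
    return np.asarray(out)


def _summary(values: np.ndarray, columns: list[str]) -> dict[str, float]:
    p = np.percentile(values, [2.5, 50, 97.5])
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return dict(zip(columns, [float(np.mean(values)), sd, *map(float, p)]))


@dataclass
class EvalReport:
    """Pooled replicate summaries of a threshold sweep."""

    mode: str
    scenario: str
    method: str
    grid: np.ndarray
    n_replicates: int
    seed: int
    fdr_values: np.ndarray
    best_thresholds: np.ndarray
    n_failures: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.fdr_values = np.asarray(self.fdr_values, dtype=float)
        self.best_thresholds = np.asarray(self.best_thresholds, dtype=float)

    @property
    def name(self) -> str:
        return f"{self.method}-{self.scenario}"

    def fdr_summary(self) -> dict[str, float]:
        return _summary(self.fdr_values, FDR_COLUMNS)

    def threshold_summary(self) -> dict[str, float]:
        """Best-threshold summary on the 1−C_d scale."""
        return _summary(1.0 - self.best_thresholds, THRESHOLD_COLUMNS)

    def fdr_table(self) -> pd.DataFrame:
        return pd.DataFrame([{"Method and scenario": self.name, **self.fdr_summary()}])

    def threshold_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"Method and scenario": self.name, **self.threshold_summary()}]
        )

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "scenario": self.scenario,
            "method": self.method,
            "grid": self.grid.tolist(),
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "fdr_values": self.fdr_values.tolist(),
            "best_thresholds": self.best_thresholds.tolist(),
            "n_failures": self.n_failures,
        }

    @classmethod
    def from_dict(cls_, d: dict) -> "EvalReport":
        return cls_(**d)


def _sweep_fdrs(
    inst: SimInstance, method: str, grid: np.ndarray, seed: int, k_subset: int
) -> np.ndarray:
    """FDR over the grid; NaN where the method could not run."""
    out = np.full(len(grid), np.nan)
    for i, t in enumerate(grid):
        try:
            out[i] = method_fdr(inst, method, float(t), seed=seed, k_subset=k_subset)
        except ValueError:
            continue
    return out


def best_threshold_index(fdrs: np.ndarray) -> int:
    """Index of the largest grid threshold attaining the minimal FDR."""
    valid = ~np.isnan(fdrs)
    if not valid.any():
        raise ValueError("method failed at every threshold of the grid")
    m = np.nanmin(fdrs)
    return int(np.flatnonzero(valid & (fdrs == m))[-1])


def threshold_sweep(
    mode: str,
    scenario: str,
    method: str,
    grid: np.ndarray | list[float] | None = None,
    reps: int = 100,
    seed: int = 0,
    k_subset: int = 2,
    config_overrides: dict | None = None,
    max_failure_fraction: float = 0.2,
) -> EvalReport:
    """Best-threshold study of one strategy in one scenario.

    Per replicate the best threshold is the *maximum* grid value that
    minimizes the FDR; the report pools the per-replicate FDRs at their
    best thresholds and the best thresholds themselves.
    """
    grid = default_threshold_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a non-empty strictly increasing sequence")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("grid thresholds must lie in (0, 1)")
    if reps < 2:
        raise ValueError("at least 2 replicates are required")
    overrides = config_overrides or {}
    fdr_vals: list[float] = []
    best_thr: list[float] = []
    failures = 0
    for rep_seed in _replicate_seeds(seed, reps):
        config = scenario_defaults(mode, scenario, seed=rep_seed, **overrides)
        inst = prepare_instance(config)
        fdrs = _sweep_fdrs(inst, method, grid, rep_seed, k_subset)
        try:
            i = best_threshold_index(fdrs)
        except ValueError as exc:
            failures += 1
            logger.warning("WARN: replicate failed and was excluded: %s", exc)
            continue
        fdr_vals.append(float(fdrs[i]))
        best_thr.append(float(grid[i]))
    if failures > max_failure_fraction * reps:
        raise RuntimeError(
            f"{failures}/{reps} sweep replicates failed; results would be unreliable"
        )
    return EvalReport(
        mode=mode, scenario=scenario, method=method, grid=grid,
        n_replicates=reps, seed=seed,
        fdr_values=np.asarray(fdr_vals),
        best_thresholds=np.asarray(best_thr),
        n_failures=failures,
    )


def benchmark_scenarios(
    mode: str,
    scenarios: tuple[str, ...] = ("F", "N", "U", "B"),
    methods: tuple[str, ...] = cls.STRATEGIES,
    reps: int = 20,
    seed: int = 0,
    grid: np.ndarray | None = None,
    k_subset: int = 2,
    config_overrides: dict | None = None,
) -> pd.DataFrame:
    """Mean best-threshold FDR of each method across scenarios.

    Uses common random numbers: the same replicate seeds are reused in
    every scenario, so scenario-to-scenario comparisons of a method are
    paired.  DAPC has no threshold; its FDR is constant across the grid.
    Returns a scenarios × methods table of mean FDRs.
    """
    grid = default_threshold_grid() if grid is None else np.asarray(grid, dtype=float)
    overrides = config_overrides or {}
    rep_seeds = _replicate_seeds(seed, reps)
    table = pd.DataFrame(index=list(scenarios), columns=list(methods), dtype=float)
    for scenario in scenarios:
        sums = {m: [] for m in methods}
        for rep_seed in rep_seeds:
            config = scenario_defaults(mode, scenario, seed=rep_seed, **overrides)
            inst = prepare_instance(config)
            for m in methods:
                if m == cls.STRATEGY_DAPC:
                    sums[m].append(method_fdr(inst, m, float(grid[0]), seed=rep_seed))
                    continue
                fdrs = _sweep_fdrs(inst, m, grid, rep_seed, k_subset)
                try:
                    i = best_threshold_index(fdrs)
                except ValueError:
                    continue
                sums[m].append(float(fdrs[i]))
        for m in methods:
            table.loc[scenario, m] = float(np.mean(sums[m])) if sums[m] else np.nan
    table.index.name = "scenario"
    return table
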