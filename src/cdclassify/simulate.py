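"""Synthetic two-condition expression matrices with ground truth.

Two confusion regimes are generated, mirroring the two failure modes seen
in real microarray data:

* **Sim1** progressively confounds the *gene* groups: every cell starts as
  correlated Gaussian noise (correlation ≈ identity) and each block of
  differentially expressed genes receives an extra block effect on its own
  condition's replicate columns.  The per-gene block effect mixes a
  positive per-gene amplitude shared across the block's columns (weight
  ``sqrt(rho)``, pushing the group coherently along its condition) with
  idiosyncratic Gaussian noise (weight ``sqrt(1-rho)``); lowering ``rho``
  and the effect scale melts the gene groups into the background cloud.

* **Sim2** progressively confounds the *replicates* of the two conditions:
  each DE gene draws a positive effect size from a zero-truncated normal,
  adds it to its own condition's columns and a per-gene fraction λ_g of it
  to the other condition's columns.  λ_g is drawn around the scenario's
  ``leak`` level, so genes form a fan of condition-specificity; as leak →
  1 the two conditions' replicate vectors become collinear and no
  direction-based method can separate them.

Scenario codes F / N / U / B (favorable, normal, unfavorable, very bad)
select calibrated parameter sets; the calibration criterion is qualitative
— the F→B sweep must move the first-two-PC picture from cleanly separated
to fully confounded and preserve the expected ordering of the four
classification strategies.  The numeric values are repository constants,
not published ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .datamodel import ExpressionMatrix, TruthLabels, UNASSIGNED

SIM1 = "sim1"
SIM2 = "sim2"
SCENARIOS = ("F", "N", "U", "B")

#: Calibrated Sim1 scenario axis: (rho, block_sd).  rho is the weight of the
#: coherent per-gene amplitude within a DE gene's block effect; block_sd its
#: overall scale in units of the base-noise sd.
SIM1_PARAMS: dict[str, tuple[float, float]] = {
    "F": (0.95, 8.0),
    "N": (0.8, 5.0),
    "U": (0.5, 3.0),
    "B": (0.35, 2.0),
}

#: Calibrated Sim2 scenario axis: mean leak fraction λ of a gene's effect
#: that spills into the other condition's replicates.
SIM2_LEAK: dict[str, float] = {"F": 0.15, "N": 0.35, "U": 0.5, "B": 0.65}


@dataclass
class ScenarioConfig:
    """Full parameter set of one simulation run.

    ``n1``/``n2`` are the DE genes of each condition, ``n0`` the
    non-differential background genes, ``p1``/``p2`` the replicates per
    condition (the default 8 + 8 matches a typical two-condition chip
    design).  ``base_jitter`` perturbs the base correlation matrix away
    from exact identity, setting the noise level.
    """

    mode: str
    scenario: str
    n1: int = 250
    n2: int = 250
    n0: int = 500
    p1: int = 8
    p2: int = 8
    seed: int = 0
    base_jitter: float = 0.05
    base_rho_within: float = 0.0
    # Sim1 block-effect parameters
    rho: float = 0.95
    block_sd: float = 8.0
    amp_sd: float = 0.3
    # Sim2 effect parameters
    leak: float = 0.15
    leak_sd: float = 0.35
    effect_mean: float = 6.0
    effect_sd: float = 2.0
    condition_labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.mode not in (SIM1, SIM2):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in ("n1", "n2", "p1", "p2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n0 < 0:
            raise ValueError("n0 must be non-negative")
        if min(self.p1, self.p2) < 2:
            raise ValueError("each condition needs at least 2 replicates")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if not 0.0 <= self.leak <= 1.0:
            raise ValueError(f"leak must be in [0, 1], got {self.leak}")
        if self.block_sd < 0 or self.effect_sd <= 0 or self.base_jitter < 0:
            raise ValueError("scale parameters must be positive")
        if self.amp_sd <= 0 or self.leak_sd < 0:
            raise ValueError("spread parameters must be positive")
        if not 0.0 <= self.base_rho_within < 1.0:
            raise ValueError("base_rho_within must be in [0, 1)")

    @property
    def n_genes(self) -> int:
        return self.n1 + self.n2 + self.n0

    @property
    def n_replicates(self) -> int:
        return self.p1 + self.p2

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["condition_labels"] = list(self.condition_labels)
        return d


def scenario_defaults(mode: str, scenario: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Calibrated default :class:`ScenarioConfig` for a mode/scenario pair."""
    cfg = ScenarioConfig(mode=mode, scenario=scenario, seed=seed)
    if mode == SIM1:
        rho, sd = SIM1_PARAMS[scenario]
        cfg = replace(cfg, rho=rho, block_sd=sd)
    else:
        cfg = replace(cfg, leak=SIM2_LEAK[scenario])
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def _near_identity_correlation(p: int, jitter: float, rng: np.random.Generator) -> np.ndarray:
    """A valid correlation matrix equal to I plus small symmetric jitter."""
    if jitter == 0:
        return np.eye(p)
    A = rng.uniform(-jitter, jitter, size=(p, p))
    C = np.eye(p) + (A + A.T) / 2.0
    np.fill_diagonal(C, 1.0)
    # project back to positive definite and renormalize the diagonal
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 1e-6, None)
    C = (V * w) @ V.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def _base_matrix(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    C = _near_identity_correlation(cfg.n_replicates, cfg.base_jitter, rng)
    if cfg.base_rho_within > 0:
        # replicates of the same condition share part of their noise
        # (array-batch / biological-replicate correlation)
        for cols in (slice(0, cfg.p1), slice(cfg.p1, cfg.n_replicates)):
            block = C[cols, cols]
            block[:] = np.where(
                np.eye(block.shape[0], dtype=bool), 1.0,
                block + cfg.base_rho_within,
            )
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - projection guards this
        raise ValueError("base correlation matrix is not positive definite") from exc
    return rng.standard_normal((cfg.n_genes, cfg.n_replicates)) @ L.T


def _skeleton(cfg: ScenarioConfig) -> tuple[list[str], list[str], dict[str, str], TruthLabels]:
    a, b = cfg.condition_labels
    gene_ids = [f"g{i + 1:05d}" for i in range(cfg.n_genes)]
    rep_ids = [f"{a}_r{j + 1}" for j in range(cfg.p1)] + [
        f"{b}_r{j + 1}" for j in range(cfg.p2)
    ]
    design = {r: (a if i < cfg.p1 else b) for i, r in enumerate(rep_ids)}
    truth = np.full(cfg.n_genes, UNASSIGNED, dtype=object)
    truth[: cfg.n1] = a
    truth[cfg.n1: cfg.n1 + cfg.n2] = b
    return gene_ids, rep_ids, design, TruthLabels(gene_ids, truth)


def _truncated_normal(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    lower: float = 0.0,
    upper: float = np.inf,
) -> np.ndarray:
    """Truncated-normal draws by inverse CDF (deterministic under seed)."""
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    return stats.truncnorm.ppf(rng.random(n), a, b, loc=mean, scale=sd)


def simulate_sim1(config: ScenarioConfig) -> tuple[ExpressionMatrix, TruthLabels]:
    """Gene-confusion regime: correlated block effects on the DE blocks.

    Rows 1..n1 × condition-1 columns (block X11) and rows n1+1..n1+n2 ×
    condition-2 columns (block X22) each receive, per gene,
    ``block_sd * (sqrt(rho)*a*1 + sqrt(1-rho)*eps)`` where ``a`` is a
    positive per-gene amplitude (normal with mean 1 and sd ``amp_sd``,
    truncated at 0) shared across that gene's block columns and ``eps`` is
    i.i.d. noise.  High ``rho`` makes the block move coherently along its
    condition (separated gene groups); low ``rho`` turns the block effect
    into unstructured extra noise.  Deterministic given the config seed.
    """
    if config.mode != SIM1:
        raise ValueError("config.mode must be 'sim1'")
    rng = np.random.default_rng(config.seed)
    X = _base_matrix(config, rng)
    blocks = (
        (slice(0, config.n1), slice(0, config.p1)),
        (slice(config.n1, config.n1 + config.n2),
         slice(config.p1, config.p1 + config.p2)),
    )
    for rows, cols in blocks:
        n_i = rows.stop - rows.start
        p_i = cols.stop - cols.start
        amp = _truncated_normal(rng, n_i, 1.0, config.amp_sd)
        eps = rng.standard_normal((n_i, p_i))
        X[rows, cols] += config.block_sd * (
            np.sqrt(config.rho) * amp[:, None] + np.sqrt(1.0 - config.rho) * eps
        )
    gene_ids, rep_ids, design, truth = _skeleton(config)
    return ExpressionMatrix(gene_ids, rep_ids, X, design), truth


def simulate_sim2(config: ScenarioConfig) -> tuple[ExpressionMatrix, TruthLabels]:
    """Replicate-confusion regime: leaked positive truncated-normal effects.

    Each DE gene of group i draws an effect size from a
    normal(effect_mean, effect_sd) truncated below at 0 and a leak
    fraction λ_g from a normal(leak, leak_sd) truncated to [0, 1] (both by
    inverse CDF, deterministic under the seed); the effect is added to the
    gene's own condition columns and λ_g times it to the other condition's
    columns.  Raising the scenario ``leak`` drives the per-gene
    condition-specificity fan toward the common axis, correlating the
    replicate vectors of the two conditions.
    """
    if config.mode != SIM2:
        raise ValueError("config.mode must be 'sim2'")
    rng = np.random.default_rng(config.seed)
    X = _base_matrix(config, rng)
    cols1 = slice(0, config.p1)
    cols2 = slice(config.p1, config.p1 + config.p2)
    for rows, own, other in (
        (slice(0, config.n1), cols1, cols2),
        (slice(config.n1, config.n1 + config.n2), cols2, cols1),
    ):
        n_i = rows.stop - rows.start
        eff = _truncated_normal(
            rng, n_i, config.effect_mean, config.effect_sd
        )
        if config.leak_sd > 0:
            lam = _truncated_normal(
                rng, n_i, config.leak, config.leak_sd, 0.0, 1.0
            )
        else:
            lam = np.full(n_i, config.leak)
        X[rows, own] += eff[:, None]
        X[rows, other] += (lam * eff)[:, None]
    gene_ids, rep_ids, design, truth = _skeleton(config)
    return ExpressionMatrix(gene_ids, rep_ids, X, design), truth


def simulate(config: ScenarioConfig) -> tuple[ExpressionMatrix, TruthLabels]:
    """Dispatch on ``config.mode``."""
    if config.mode == SIM1:
        return simulate_sim1(config)
    return simulate_sim2(config)
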