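"""Optimizer-wrapped demons registration.

The tuning loop treats the regularizer hyperparameters of the demons solver
— the Gaussian window (k1, k2) and its spread k3 = sigma — as a search
problem: each candidate triple is plugged into a full registration of the
moving image onto the fixed image, and the Pearson correlation between the
fixed image and the registered result is the fitness to maximize.  By
default the search box is k1, k2 in [20, 100] (integers) and k3 in [0, 20]
(continuous), around the conventional demons defaults (60, 60, 10).

The default triple is injected into the optimizer's initial population, so
the reported optimum can never be worse than the un-tuned baseline — the
"optimized vs original parameters" comparison is then meaningful by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import metrics as _metrics
from .demons import DemonsConfig, register
from .errors import ConfigError, EvaluationError
from .image_io import as_image
from .optimizers import OptimizerRun, SearchSpace, make_optimizer

__all__ = [
    "DEFAULT_PARAMS",
    "DEFAULT_SPACE",
    "TuningProblem",
    "TuningReport",
    "fitness",
    "tune",
    "compare_variants",
    "variant_table",
    "problem_from_config",
    "load_config",
]

#: Conventional demons regularizer defaults: window 60 x 60, sigma 10.
DEFAULT_PARAMS = (60.0, 60.0, 10.0)

#: Search box: window sizes 20-100 px (integer), sigma 0-20 px (continuous).
DEFAULT_SPACE = SearchSpace(
    lower=(20.0, 20.0, 0.0),
    upper=(100.0, 100.0, 20.0),
    kinds=("integer", "integer", "continuous"),
)


@dataclass(frozen=True)
class TuningProblem:
    """One registration-hyperparameter search problem."""

    fixed: np.ndarray
    moving: np.ndarray
    variant: str = "wang"
    alpha: float = 2.5
    balance_k: float = 1.0
    n_iterations: int = 120
    space: SearchSpace = DEFAULT_SPACE
    optimizer: str = "gwo"
    n_pop: int = 15
    n_iter: int = 20
    seed: int = 0
    inject_defaults: bool = True
    n_bins: int = _metrics.DEFAULT_BINS

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed", as_image(self.fixed))
        object.__setattr__(self, "moving", as_image(self.moving))
        if self.fixed.shape != self.moving.shape:
            raise ConfigError(
                f"fixed {self.fixed.shape} and moving {self.moving.shape} shapes differ"
            )
        if self.space.dim != 3:
            raise ConfigError("the tuning space must be 3-dimensional (k1, k2, k3)")

    def demons_config(self, params: tuple[float, float, float]) -> DemonsConfig:
        k1, k2, k3 = params
        return DemonsConfig(
            variant=self.variant,
            alpha=self.alpha,
            balance_k=self.balance_k,
            window=(int(round(k1)), int(round(k2))),
            sigma=float(k3),
            n_iterations=self.n_iterations,
        )


@dataclass(frozen=True)
class TuningReport:
    """Everything the tuning run measured.

    ``convergence`` maps iteration index -> best-so-far fitness;
    ``improvements`` holds, per metric, the (before, after, percent,
    direction) row comparing the default-parameter registration against the
    best-parameter one.
    """

    variant: str
    best_params: tuple[float, float, float]
    best_fitness: float
    convergence: tuple[float, ...]
    n_evaluations: int
    default_report: _metrics.MetricReport
    best_report: _metrics.MetricReport
    improvements: dict[str, tuple[float, float, float, str]]
    seed: int

    def to_dict(self) -> dict[str, Any]:
        return {
            "variant": self.variant,
            "best_params": {
                "k1": self.best_params[0],
                "k2": self.best_params[1],
                "k3": self.best_params[2],
            },
            "best_fitness": self.best_fitness,
            "convergence": list(self.convergence),
            "n_evaluations": self.n_evaluations,
            "default_report": self.default_report.to_dict(),
            "best_report": self.best_report.to_dict(),
            "improvements": {
                k: {"before": v[0], "after": v[1], "percent": v[2], "direction": v[3]}
                for k, v in self.improvements.items()
            },
            "seed": self.seed,
        }


def fitness(params: tuple[float, float, float], problem: TuningProblem) -> float:
    """Registration fitness of one (k1, k2, k3) triple.

    Runs the full demons registration with the candidate regularizer and
    returns the correlation between the fixed image and the final warped
    moving image.  Deterministic per params.
    """
    try:
        result = register(problem.fixed, problem.moving, problem.demons_config(params))
        return _metrics.correlation(problem.fixed, result.warped)
    except (ConfigError, EvaluationError):
        raise
    except Exception as exc:
        raise EvaluationError(f"registration failed at params {tuple(params)}: {exc}") from exc


class _CachedFitness:
    """Memoizes fitness on the quantized parameter key.

    Metaheuristics revisit rounded integer triples constantly; a full demons
    run per revisit would dominate the runtime.  Semantically invisible:
    registration is deterministic per params.
    """

    def __init__(self, problem: TuningProblem):
        self.problem = problem
        self.cache: dict[tuple[float, float, float], float] = {}
        self.log: list[tuple[tuple[float, float, float], float]] = []

    def __call__(self, position: np.ndarray) -> float:
        key = (float(position[0]), float(position[1]), float(position[2]))
        if key not in self.cache:
            self.cache[key] = fitness(key, self.problem)
            self.log.append((key, self.cache[key]))
        return self.cache[key]


def _improvement_rows(
    default: _metrics.MetricReport, best: _metrics.MetricReport
) -> dict[str, tuple[float, float, float, str]]:
    rows: dict[str, tuple[float, float, float, str]] = {}
    for name in ("correlation", "mse", "mje", "nmi"):
        before = getattr(default, name)
        after = getattr(best, name)
        if before == after:
            # covers the already-perfect pair (e.g. MSE 0 -> 0), where the
            # relative-change ratio is undefined
            rows[name] = (before, after, 0.0, "Unchanged")
        else:
            pct, direction = _metrics.improvement_percent(before, after)
            rows[name] = (before, after, pct, direction)
    return rows


def tune(problem: TuningProblem) -> TuningReport:
    """Optimize the demons regularizer for one image pair.

    Runs the configured optimizer over :func:`fitness`, re-registers at the
    best triple and at the defaults, computes both metric reports and the
    per-metric improvement rows.  Fully seeded: identical problems produce
    identical reports.
    """
    objective = _CachedFitness(problem)
    optimizer = make_optimizer(problem.optimizer)
    init = [DEFAULT_PARAMS] if problem.inject_defaults else None
    run: OptimizerRun = optimizer(
        objective,
        problem.space,
        n_pop=problem.n_pop,
        n_iter=problem.n_iter,
        seed=problem.seed,
        init_positions=init,
    )
    best_params = (
        float(run.best_position[0]),
        float(run.best_position[1]),
        float(run.best_position[2]),
    )
    default_res = register(problem.fixed, problem.moving, problem.demons_config(DEFAULT_PARAMS))
    best_res = register(problem.fixed, problem.moving, problem.demons_config(best_params))
    default_report = _metrics.metric_report(problem.fixed, default_res.warped, problem.n_bins)
    best_report = _metrics.metric_report(problem.fixed, best_res.warped, problem.n_bins)
    return TuningReport(
        variant=problem.variant,
        best_params=best_params,
        best_fitness=run.best_fitness,
        convergence=run.history,
        n_evaluations=run.n_evaluations,
        default_report=default_report,
        best_report=best_report,
        improvements=_improvement_rows(default_report, best_report),
        seed=problem.seed,
    )


def compare_variants(
    fixed: np.ndarray,
    moving: np.ndarray,
    variants: tuple[str, ...] = ("wang", "tang", "thirion"),
    **problem_kwargs: Any,
) -> dict[str, TuningReport]:
    """Tune each demons variant on the same pair with a shared seed.

    Returns variant -> TuningReport; the cross-variant table (MSE, MJE, NMI,
    correlation at the tuned optimum) falls out of the ``best_report``
    fields.
    """
    if not variants:
        raise ConfigError("need at least one variant")
    reports = {}
    for variant in variants:
        problem = TuningProblem(fixed=fixed, moving=moving, variant=variant, **problem_kwargs)
        reports[variant] = tune(problem)
    return reports


def variant_table(reports: dict[str, TuningReport]) -> dict[str, dict[str, float]]:
    """Cross-variant metric table: variant -> {mse, mje, nmi, correlation}."""
    return {
        name: {
            "mse": rep.best_report.mse,
            "mje": rep.best_report.mje,
            "nmi": rep.best_report.nmi,
            "correlation": rep.best_report.correlation,
        }
        for name, rep in reports.items()
    }


# ---------------------------------------------------------------------------
# config file support


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML/JSON tuning configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def problem_from_config(
    cfg: dict[str, Any], fixed: np.ndarray, moving: np.ndarray
) -> TuningProblem:
    """Build a TuningProblem from a parsed config mapping.

    Recognized blocks: ``demons`` (variant, alpha, balance_k, n_iterations),
    ``optimizer`` (name, n_pop, n_iter, seed), ``space`` (lower, upper,
    kinds).  Unknown keys raise :class:`ConfigError` naming the key.
    """
    known = {"demons", "optimizer", "space", "seed", "n_bins"}
    unknown = set(cfg) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}; expected subset of {sorted(known)}")
    demons = cfg.get("demons", {})
    opt = cfg.get("optimizer", {})
    space_cfg = cfg.get("space")
    space = (
        SearchSpace(
            lower=tuple(space_cfg["lower"]),
            upper=tuple(space_cfg["upper"]),
            kinds=tuple(space_cfg["kinds"]),
        )
        if space_cfg
        else DEFAULT_SPACE
    )
    return TuningProblem(
        fixed=fixed,
        moving=moving,
        variant=demons.get("variant", "wang"),
        alpha=float(demons.get("alpha", 2.5)),
        balance_k=float(demons.get("balance_k", 1.0)),
        n_iterations=int(demons.get("n_iterations", 120)),
        space=space,
        optimizer=opt.get("name", "gwo"),
        n_pop=int(opt.get("n_pop", 15)),
        n_iter=int(opt.get("n_iter", 20)),
        seed=int(cfg.get("seed", opt.get("seed", 0))),
        n_bins=int(cfg.get("n_bins", _metrics.DEFAULT_BINS)),
    )
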