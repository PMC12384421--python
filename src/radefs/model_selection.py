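"""Experiment grid enumeration and two-stage model selection.

Stage one drops every configuration whose cross-validated mean BACC, AUC or
F1 falls below a floor (default 0.70).  Stage two keeps the Pareto front of
the survivors under four objectives: the three metric means (maximized) and
the feature count (minimized).  The best overall configuration maximizes the
unweighted mean of the three metrics, ties broken by fewer features then
configuration id.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .classifiers import ClassifierSpec
from .cohort import Cohort
from .evaluation import FoldPlan, MetricSummary, TASKS, cross_validate, make_fold_plan
from .selection import SelectionRequest, select

log = logging.getLogger(__name__)

#: the canonical subset-size grid: 2..10 by 1, then 20..90 by 10 (17 sizes)
DEFAULT_SIZE_GRID: tuple[int, ...] = tuple(range(2, 11)) + tuple(range(20, 100, 10))

METRICS = ("bacc", "auc", "f1")


@dataclass(frozen=True)
class ExperimentConfig:
    """One cell of the grid: task x selection request x classifier."""

    task: str
    selection: SelectionRequest
    classifier: ClassifierSpec

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def config_id(self) -> str:
        est = self.selection.estimator
        est_tag = est.kind if isinstance(est, ClassifierSpec) else str(est)
        ndf = "ndf" if self.selection.ndf_only else "all"
        return (
            f"{self.task}|{self.selection.method}({est_tag})"
            f"_{self.selection.p}_{self.classifier.kind}|{ndf}"
        )


@dataclass
class ResultRecord:
    """A grid cell's cross-validated outcome and Pareto objective vector."""

    config: ExperimentConfig
    selected: list[str]
    summary: MetricSummary | None
    error: str | None = None

    @property
    def objectives(self) -> tuple[float, float, float, float]:
        """(bacc, auc, f1, -n_features); all maximized under dominance."""
        s = self.summary
        return (s.mean["bacc"], s.mean["auc"], s.mean["f1"], -float(s.n_features))

    @property
    def metric_mean(self) -> float:
        s = self.summary
        return float(np.mean([s.mean[m] for m in METRICS]))


@dataclass
class GridSpec:
    """Enumerates selection methods x estimators x sizes x classifiers."""

    tasks: tuple[str, ...] = ("three_class",)
    selections: tuple[SelectionRequest, ...] = ()
    classifiers: tuple[ClassifierSpec, ...] = ()
    sizes: tuple[int, ...] = DEFAULT_SIZE_GRID

    def enumerate(self, master_seed: int = 0) -> list[ExperimentConfig]:
        configs = []
        for task in self.tasks:
            for sel in self.selections:
                for p in self.sizes:
                    for clf in self.classifiers:
                        configs.append(
                            ExperimentConfig(
                                task,
                                replace(sel, p=p, seed=master_seed),
                                clf.with_seed(master_seed),
                            )
                        )
        return configs


def run_grid(
    cohort: Cohort,
    grid: GridSpec | list[ExperimentConfig],
    plan: FoldPlan | None = None,
    master_seed: int = 0,
    **selection_kwargs,
) -> list[ResultRecord]:
    """Evaluate every configuration; failures become error records.

    Selection results are cached per (task, selection request) so a subset is
    computed once and evaluated under every classifier.
    """
    plan = plan or make_fold_plan(cohort)
    configs = grid.enumerate(master_seed) if isinstance(grid, GridSpec) else grid
    records: list[ResultRecord] = []
    sel_cache: dict[tuple, list[str]] = {}
    for i, cfg in enumerate(configs):
        log.info("grid %d/%d: %s", i + 1, len(configs), cfg.config_id)
        try:
            key = (cfg.task, repr(cfg.selection))
            if key not in sel_cache:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    result = select(cohort, cfg.selection, task=cfg.task,
                                    **selection_kwargs)
                sel_cache[key] = result.selected
            selected = sel_cache[key]
            summary = cross_validate(cohort, selected, cfg.classifier, plan,
                                     task=cfg.task)
            records.append(ResultRecord(cfg, selected, summary))
        except Exception as e:  # keep the grid running
            log.warning("configuration %s failed: %s", cfg.config_id, e)
            records.append(ResultRecord(cfg, [], None, error=str(e)))
    return records


# --------------------------------------------------------------------------
# Pareto selection


@dataclass
class ParetoReport:
    passing: list[ResultRecord]
    front: list[ResultRecord]
    floor: float

    @property
    def best(self) -> ResultRecord:
        return best_overall(self)


def _dominates(a: tuple[float, ...], b: tuple[float, ...]) -> bool:
    """Weak dominance in every objective plus strict in at least one."""
    return all(x >= y for x, y in zip(a, b)) and any(x > y for x, y in zip(a, b))


def pareto_front(records: list[ResultRecord], floor: float = 0.70) -> ParetoReport:
    """Two-stage filter: metric floor, then non-dominated sorting."""
    if not records:
        raise ValueError("no records to select from")
    ok = [r for r in records if r.summary is not None
          and all(np.isfinite(v) for v in r.objectives)]
    passing = [r for r in ok if min(r.summary.mean[m] for m in METRICS) >= floor]
    if not passing:
        warnings.warn(f"no configuration passes the {floor} floor", stacklevel=2)
        return ParetoReport([], [], floor)
    front = [
        r for r in passing
        if not any(
            _dominates(o.objectives, r.objectives) for o in passing if o is not r
        )
    ]
    return ParetoReport(passing, front, floor)


def best_overall(report: ParetoReport) -> ResultRecord:
    """Front member maximizing the unweighted mean of the three metrics."""
    if not report.front:
        raise ValueError("empty Pareto front")
    return min(
        report.front,
        key=lambda r: (-r.metric_mean, r.summary.n_features, r.config.config_id),
    )
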