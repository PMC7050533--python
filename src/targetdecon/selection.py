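"""Target deconvolution by iterative weight-threshold feature selection.

For one phenotype: train the full-panel phenotype classifier and record
its cross-validated AUC; then repeatedly raise a weight threshold tau
(0, step, 2*step, ...), keep only the proteins whose weight in the
immediately preceding model strictly exceeds tau (so negative-weight
proteins are never selectable), retrain on the restricted panel and
re-measure the CV AUC.  Iteration stops at the first cycle whose AUC
falls below ``retention`` (default 95%) of the full-panel AUC or whose
selection is empty; the proteins of the last cycle that still met the
retention gate are reported as the phenotype's significant targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._glm import DEFAULT_C_GRID, TrainingConfig, fit_logistic
from .cpa import PhenotypeModel, train_cpa_model
from .cpi import TargetProfileSet
from .evaluation import kfold_cv
from .io import PhenotypeTable

__all__ = [
    "SelectionConfig",
    "SelectionCycle",
    "SelectionTrace",
    "select_significant_targets",
    "selection_summary",
    "write_traces",
    "read_traces",
]


@dataclass
class SelectionConfig:
    """Parameters of the iterative selection procedure.

    ``threshold_step`` is the per-cycle increment of the weight
    threshold; ``retention`` is the fraction of the full-panel AUC the
    restricted model must retain.  ``freeze_c`` reuses the full model's
    penalty C in every cycle instead of re-running the C grid.
    """

    threshold_step: float = 0.02
    retention: float = 0.95
    reg_type: str = "l1"
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    cv_folds: int = 5
    seed: int = 0
    standardize: bool = False
    freeze_c: bool = False

    def __post_init__(self) -> None:
        if not self.threshold_step > 0:
            raise ValueError("threshold_step must be > 0")
        if not 0 <= self.retention <= 1:
            raise ValueError("retention must lie in [0, 1]")

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(
            reg_type=self.reg_type,
            c_grid=self.c_grid,
            cv_folds=self.cv_folds,
            seed=self.seed,
            standardize=self.standardize,
        )


@dataclass
class SelectionCycle:
    """One threshold cycle: tau, the surviving proteins, and the
    retrained model's cross-validated AUC vs the retention gate."""

    index: int
    threshold: float
    selected: tuple[str, ...]
    weights: dict[str, float]  # retrained-model weights over `selected`
    auc: float  # NaN when `selected` is empty
    passed: bool


@dataclass
class SelectionTrace:
    """Full record of one phenotype's selection run."""

    phenotype_id: str
    full_protein_ids: tuple[str, ...]
    full_weights: dict[str, float]
    auc_full: float
    cycles: list[SelectionCycle]
    final_selected: tuple[str, ...]
    final_auc: float
    stop_cycle: int
    flagged: bool = False
    config: SelectionConfig | None = field(default=None, repr=False)

    @property
    def n_full(self) -> int:
        return len(self.full_protein_ids)

    @property
    def n_selected(self) -> int:
        return len(self.final_selected)


def _cv_auc_at_fixed_c(X, y, C, config: TrainingConfig, feature_order) -> float:
    cv = kfold_cv(
        X,
        y,
        trainer=lambda Xt, yt: fit_logistic(Xt, yt, feature_order, C, config),
        scorer=lambda m, Xe: m.predict_proba(Xe),
        k=config.cv_folds,
        seed=config.seed,
    )
    return cv.auc


def _selected_cv_auc(report: pd.DataFrame) -> float:
    return float(report.loc[report["selected"], "cv_auc"].iloc[0])


def select_significant_targets(
    profiles: TargetProfileSet,
    phenotypes: PhenotypeTable,
    phenotype_id: str,
    config: SelectionConfig | None = None,
) -> SelectionTrace:
    """Run the iterative weight-threshold selection for one phenotype.

    Returns a :class:`SelectionTrace` whose ``final_selected`` is the
    protein set of the last cycle that retained at least
    ``config.retention`` of the full-panel AUC (the full panel itself if
    even the first cycle fails the gate, the empty set if the full model
    has no positive weights — both flagged).  The failing cycle remains
    visible in ``cycles``.
    """
    config = config or SelectionConfig()
    tc = config.training_config()

    full_pm, full_report = train_cpa_model(profiles, phenotypes, phenotype_id, tc)
    auc_full = _selected_cv_auc(full_report)
    if not np.isfinite(auc_full):
        raise ValueError(
            f"full-panel CV AUC undefined for phenotype {phenotype_id!r} "
            "(degenerate folds)"
        )
    gate = config.retention * auc_full

    labels = phenotypes.labels_for(phenotype_id)
    have = [c for c in labels.index if c in profiles._index]
    labels = labels.loc[have]
    y = labels.to_numpy(dtype=int)

    cycles: list[SelectionCycle] = []
    prev_model: PhenotypeModel = full_pm
    # candidates for "last passing": the full panel always satisfies the gate
    last_passing = (tuple(profiles.protein_ids), auc_full)
    flagged = False
    i = 0
    while True:
        tau = i * config.threshold_step
        wmap = prev_model.model.weight_by_feature()
        selected = tuple(p for p in prev_model.protein_ids if wmap[p] > tau)

        if not selected:
            cycles.append(SelectionCycle(i, tau, (), {}, float("nan"), False))
            if i == 0:
                # no positive weights in the full model at all
                last_passing = ((), float("nan"))
                flagged = True
            break

        if cycles and selected == cycles[-1].selected:
            # identical input set -> identical retrained model; reuse
            prev_cyc = cycles[-1]
            cycles.append(
                SelectionCycle(
                    i, tau, selected, prev_cyc.weights, prev_cyc.auc, prev_cyc.passed
                )
            )
            last_passing = (selected, prev_cyc.auc)
            i += 1
            continue

        sub = profiles.subset_proteins(list(selected)).subset_compounds(list(labels.index))
        if config.freeze_c:
            cyc_auc = _cv_auc_at_fixed_c(
                sub.values, y, full_pm.model.penalty_C, tc, list(selected)
            )
            cfg_c = tc
            model = fit_logistic(
                sub.values, y, list(selected), full_pm.model.penalty_C, cfg_c
            )
            pm = PhenotypeModel(model=model, phenotype_id=str(phenotype_id))
        else:
            pm, report = train_cpa_model(
                profiles.subset_proteins(list(selected)), phenotypes, phenotype_id, tc
            )
            cyc_auc = _selected_cv_auc(report)

        passed = cyc_auc >= gate
        cycles.append(
            SelectionCycle(
                i, tau, selected, pm.model.weight_by_feature(), cyc_auc, passed
            )
        )
        if not passed:
            if i == 0:
                flagged = True  # even the positive-weight set breaks the gate
            break
        last_passing = (selected, cyc_auc)
        prev_model = pm
        i += 1

    trace = SelectionTrace(
        phenotype_id=str(phenotype_id),
        full_protein_ids=tuple(profiles.protein_ids),
        full_weights=full_pm.model.weight_by_feature(),
        auc_full=auc_full,
        cycles=cycles,
        final_selected=last_passing[0],
        final_auc=last_passing[1],
        stop_cycle=cycles[-1].index,
        flagged=flagged,
        config=config,
    )
    _assert_invariants(trace, config)
    return trace


def _assert_invariants(trace: SelectionTrace, config: SelectionConfig) -> None:
    """Structural guarantees checked on every run."""
    prev: set[str] = set(trace.full_protein_ids)
    for cyc in trace.cycles:
        if not set(cyc.selected) <= prev:
            raise AssertionError("selected sets must shrink monotonically")
        prev = set(cyc.selected)
    if trace.final_selected and trace.final_selected != trace.full_protein_ids:
        if not trace.final_auc >= config.retention * trace.auc_full:
            raise AssertionError("returned set violates the AUC retention gate")


def selection_summary(traces: list[SelectionTrace]) -> pd.DataFrame:
    """Per-phenotype reduction table plus mean counts.

    Columns: phenotype_id, n_full, n_selected, auc_full, auc_final.
    A final row labelled ``__mean__`` carries column means.
    """
    if not traces:
        raise ValueError("need at least one trace")
    rows = [
        dict(
            phenotype_id=t.phenotype_id,
            n_full=t.n_full,
            n_selected=t.n_selected,
            auc_full=t.auc_full,
            auc_final=t.final_auc,
        )
        for t in traces
    ]
    df = pd.DataFrame(rows)
    mean_row = dict(
        phenotype_id="__mean__",
        n_full=df["n_full"].mean(),
        n_selected=df["n_selected"].mean(),
        auc_full=df["auc_full"].mean(),
        auc_final=df["auc_final"].mean(),
    )
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


# ---------------------------------------------------------------------------
# trace persistence: long delimited table, re-loadable


def trace_frame(trace: SelectionTrace) -> pd.DataFrame:
    """Long-form view: one row per (cycle, protein); the full model is
    recorded as cycle -1."""
    rows = []
    for p in trace.full_protein_ids:
        rows.append(
            dict(
                phenotype_id=trace.phenotype_id,
                cycle=-1,
                threshold=np.nan,
                protein_id=p,
                weight=trace.full_weights[p],
                auc=trace.auc_full,
                passed=True,
            )
        )
    for cyc in trace.cycles:
        if not cyc.selected:
            rows.append(
                dict(
                    phenotype_id=trace.phenotype_id,
                    cycle=cyc.index,
                    threshold=cyc.threshold,
                    protein_id="",
                    weight=np.nan,
                    auc=cyc.auc,
                    passed=cyc.passed,
                )
            )
        for p in cyc.selected:
            rows.append(
                dict(
                    phenotype_id=trace.phenotype_id,
                    cycle=cyc.index,
                    threshold=cyc.threshold,
                    protein_id=p,
                    weight=cyc.weights[p],
                    auc=cyc.auc,
                    passed=cyc.passed,
                )
            )
    return pd.DataFrame(rows)


def write_traces(traces: list[SelectionTrace], path: str | Path) -> None:
    pd.concat([trace_frame(t) for t in traces], ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_traces(path: str | Path) -> pd.DataFrame:
    """Reload a trace table written by :func:`write_traces` (long form)."""
    return pd.read_csv(path, sep="\t", keep_default_na=True)
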