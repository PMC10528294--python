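"""Monte-Carlo evaluation harness: threshold sweeps, replicated MSE tables,
best-threshold selection and the ratio diagnostics used to compare the
distance-correlation (DC) and Pearson (CC) filters.

One replication draws a fresh train/test pair, computes each method's
dependence profile once on the training split, filters at every threshold
of the grid, grows one forest per *distinct* surviving feature set
(identical selections reuse the identical forest — a pairing device that
removes spurious forest-RNG noise from within-replication comparisons) and
records the test-split MSE.  A study averages the per-replication MSEs
over seeded, independent replications into a table with methods/thresholds
as rows and feature dimensions p as columns; thresholds that empty the
selection in every replication render as NA.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dcor import dcor_profile
from .exceptions import (
    InvalidConfigurationError,
    InvalidInputError,
    NoViableModelError,
)
from .forest import ForestConfig, fit_forest, predict_mse
from .screening import pearson_profile, sweep_thresholds
from .simulate import SimulationSetting, generate

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_THRESHOLDS",
    "ThresholdRecord",
    "SweepResult",
    "MseTable",
    "run_replication",
    "run_study",
    "best_threshold",
    "table_ratios",
    "percent_change",
]

#: The canonical screening grid R* = 0.0, 0.1, ..., 0.6.
DEFAULT_THRESHOLDS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6)

_PROFILES = {"DC": dcor_profile, "CC": pearson_profile}


@dataclass(frozen=True)
class ThresholdRecord:
    """Outcome of one (method, threshold) cell within a replication.

    ``mse`` is None when the threshold emptied the selection (the NA
    marker of the output tables).
    """

    threshold: float
    n_selected: int
    mse: Optional[float]

    @property
    def is_empty(self) -> bool:
        return self.mse is None


@dataclass(frozen=True)
class SweepResult:
    """Per-threshold test MSEs for one method on one dataset."""

    method: str
    records: tuple

    def record_at(self, threshold: float) -> ThresholdRecord:
        for rec in self.records:
            if rec.threshold == threshold:
                return rec
        raise InvalidInputError(f"no record at threshold {threshold}")


def run_replication(
    setting: SimulationSetting,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    cfg: ForestConfig = ForestConfig(),
    methods: Sequence[str] = ("DC", "CC"),
) -> dict[str, SweepResult]:
    """One seeded replication of the threshold-sweep experiment.

    The profile of each method is computed once on the training split and
    reused across thresholds (scores do not depend on the threshold).  The
    pseudo-method ``"none"`` fits the unfiltered forest — equivalent to a
    filter at threshold 0, which always keeps every feature.
    """
    for m in methods:
        if m not in ("DC", "CC", "none"):
            raise InvalidConfigurationError(f"unknown method {m!r}")
    train, test = generate(setting)
    forest_cache: dict[tuple, float] = {}

    def mse_for(indices: tuple) -> float:
        if indices not in forest_cache:
            model = fit_forest(
                train.X[:, indices], train.y, cfg, feature_ids=indices
            )
            forest_cache[indices] = predict_mse(
                model, test.X[:, indices], test.y
            )
        return forest_cache[indices]

    out: dict[str, SweepResult] = {}
    for method in methods:
        if method == "none":
            all_idx = tuple(range(train.p))
            rec = ThresholdRecord(
                threshold=0.0, n_selected=train.p, mse=mse_for(all_idx)
            )
            out[method] = SweepResult(method="none", records=(rec,))
            continue
        profile = _PROFILES[method](train.X, train.y)
        records = []
        for res in sweep_thresholds(profile, thresholds):
            if res.is_empty:
                records.append(
                    ThresholdRecord(res.threshold, 0, None)
                )
            else:
                records.append(
                    ThresholdRecord(
                        res.threshold,
                        res.n_selected,
                        mse_for(res.selected_indices),
                    )
                )
        out[method] = SweepResult(method=method, records=tuple(records))
    return out


@dataclass
class MseTable:
    """Replicated MSE results in long form plus aggregation helpers.

    ``records`` columns: method, threshold, p, replication, n_selected,
    mse (NaN = empty selection).  ``aggregate()`` pivots to the benchmark
    table layout: rows (method, threshold), columns p, cells the mean MSE
    over the replications in which the threshold was feasible; cells
    infeasible in every replication come out NaN (rendered "NA" on disk).
    """

    records: pd.DataFrame
    n_replications: int
    meta: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        return self.records.pivot_table(
            index=["method", "threshold"],
            columns="p",
            values="mse",
            aggfunc="mean",
        )

    def standard_errors(self) -> pd.DataFrame:
        return self.records.pivot_table(
            index=["method", "threshold"],
            columns="p",
            values="mse",
            aggfunc=lambda v: v.std(ddof=1) / np.sqrt(v.notna().sum()),
        )

    def cell(self, method: str, threshold: float, p: int) -> float:
        agg = self.aggregate()
        try:
            return float(agg.loc[(method, threshold), p])
        except KeyError:
            raise InvalidInputError(
                f"table has no cell ({method}, {threshold}, p={p})"
            ) from None

    def sweep(self, method: str, p: int) -> SweepResult:
        """Re-assemble an aggregated SweepResult for one method and p."""
        sub = self.records[
            (self.records["method"] == method) & (self.records["p"] == p)
        ]
        if sub.empty:
            raise InvalidInputError(f"no records for method {method}, p={p}")
        recs = []
        for t, grp in sub.groupby("threshold"):
            mse = grp["mse"].mean()
            recs.append(
                ThresholdRecord(
                    float(t),
                    int(grp["n_selected"].mean()),
                    None if np.isnan(mse) else float(mse),
                )
            )
        recs.sort(key=lambda r: r.threshold)
        return SweepResult(method=method, records=tuple(recs))


def _replication_seed(master_seed: int, p: int, rep: int, salt: int = 0) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(p), int(rep), int(salt)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_study(
    model: int,
    setting: int,
    rho: Optional[float],
    p_list: Sequence[int],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    cfg: ForestConfig = ForestConfig(),
    n_replications: int = 50,
    master_seed: int = 0,
    methods: Sequence[str] = ("DC", "CC"),
    n_train: int = 200,
    n_test: int = 1000,
    checkpoint: Optional[str] = None,
) -> MseTable:
    """Average the threshold-sweep MSEs over seeded replications.

    Replication r at dimension p derives its data seed and forest seed
    from ``(master_seed, p, r)`` sub-streams, so replications are mutually
    independent and any cell can be recomputed in isolation.  With
    ``checkpoint`` set, per-replication rows are appended to a CSV as they
    complete and already-present (p, replication) pairs are skipped on
    resume.
    """
    if n_replications < 1:
        raise InvalidConfigurationError("n_replications must be >= 1")
    if not p_list:
        raise InvalidConfigurationError("p_list must be non-empty")

    ckpt_path = Path(checkpoint) if checkpoint else None
    rows: list[dict] = []
    done: set[tuple[int, int]] = set()
    if ckpt_path is not None and ckpt_path.exists():
        prev = pd.read_csv(ckpt_path)
        rows = prev.to_dict("records")
        done = set(zip(prev["p"].astype(int), prev["replication"].astype(int)))
        logger.info("resuming study from %s (%d rows)", ckpt_path, len(rows))

    for p in p_list:
        for rep in range(n_replications):
            if (int(p), rep) in done:
                continue
            data_seed = _replication_seed(master_seed, p, rep, salt=0)
            forest_seed = _replication_seed(master_seed, p, rep, salt=1)
            sim = SimulationSetting(
                model=model,
                setting=setting,
                p=int(p),
                rho=rho,
                n_train=n_train,
                n_test=n_test,
                seed=data_seed,
            )
            rep_cfg = ForestConfig(
                n_trees=cfg.n_trees,
                mtry_fraction=cfg.mtry_fraction,
                min_node_size=cfg.min_node_size,
                seed=forest_seed,
            )
            sweeps = run_replication(sim, thresholds, rep_cfg, methods)
            new_rows = [
                {
                    "method": method,
                    "threshold": rec.threshold,
                    "p": int(p),
                    "replication": rep,
                    "n_selected": rec.n_selected,
                    "mse": np.nan if rec.mse is None else rec.mse,
                }
                for method, sweep in sweeps.items()
                for rec in sweep.records
            ]
            rows.extend(new_rows)
            if ckpt_path is not None:
                header = not ckpt_path.exists()
                pd.DataFrame(new_rows).to_csv(
                    ckpt_path, mode="a", header=header, index=False
                )
    table = MseTable(
        records=pd.DataFrame(rows),
        n_replications=n_replications,
        meta={
            "model": model,
            "setting": setting,
            "rho": rho,
            "p_list": list(map(int, p_list)),
            "thresholds": list(map(float, thresholds)),
            "n_train": n_train,
            "n_test": n_test,
            "master_seed": master_seed,
            "forest": {
                "n_trees": cfg.n_trees,
                "mtry_fraction": cfg.mtry_fraction,
                "min_node_size": cfg.min_node_size,
            },
        },
    )
    return table


def best_threshold(sweep: SweepResult) -> tuple[float, float]:
    """The (threshold, MSE) record with minimal MSE.

    Ties go to the smaller threshold, which keeps more features.  Raises
    :class:`NoViableModelError` when every threshold emptied the selection.
    """
    viable = [r for r in sweep.records if not r.is_empty]
    if not viable:
        raise NoViableModelError(
            f"every threshold of the {sweep.method} sweep emptied the selection"
        )
    best = min(viable, key=lambda r: (r.mse, r.threshold))
    return best.threshold, best.mse


def percent_change(table, method: str, t_from: float, t_to: float, p: int) -> float:
    """Percent change in mean MSE when the threshold moves t_from -> t_to.

    Positive values are decreases (improvements), e.g. 44.7 means the MSE
    dropped by 44.7%.  ``table`` is an :class:`MseTable` or an aggregated
    DataFrame indexed by (method, threshold) with p-valued columns.
    """
    a = _lookup(table, method, t_from, p)
    b = _lookup(table, method, t_to, p)
    return 100.0 * (a - b) / a


def table_ratios(table, p_values: Optional[Sequence[int]] = None) -> pd.DataFrame:
    """The DC-vs-CC threshold-ratio diagnostic, per feature dimension p.

    For each p, computes

        MSE_DC(0.5, p) / MSE_DC(0.4, p)  -  MSE_CC(0.2, p) / MSE_CC(0.1, p)

    i.e. how much of its error the DC filter sheds across its critical
    threshold step compared with the CC filter across its own.  Returns a
    DataFrame with columns ``dc_ratio``, ``cc_ratio``, ``difference`` and
    ``abs_difference`` indexed by p.  Missing cells raise an error naming
    the cell.
    """
    agg = table.aggregate() if isinstance(table, MseTable) else table
    if p_values is None:
        p_values = list(agg.columns)
    rows = {}
    for p in p_values:
        dc = _lookup(agg, "DC", 0.5, p) / _lookup(agg, "DC", 0.4, p)
        cc = _lookup(agg, "CC", 0.2, p) / _lookup(agg, "CC", 0.1, p)
        rows[p] = {
            "dc_ratio": dc,
            "cc_ratio": cc,
            "difference": dc - cc,
            "abs_difference": abs(dc - cc),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("p")


def _lookup(table, method: str, threshold: float, p: int) -> float:
    if isinstance(table, MseTable):
        return table.cell(method, threshold, p)
    try:
        val = table.loc[(method, float(threshold)), p]
    except KeyError:
        raise InvalidInputError(
            f"missing cell ({method}, {threshold}, p={p})"
        ) from None
    val = float(val)
    if np.isnan(val):
        raise InvalidInputError(f"cell ({method}, {threshold}, p={p}) is NA")
    return val


def summary_json(table: MseTable) -> str:
    """JSON summary: per-(method, p) best thresholds plus the ratio report."""
    best = {}
    for method in table.records["method"].unique():
        for p in sorted(table.records["p"].unique()):
            try:
                t, mse = best_threshold(table.sweep(method, int(p)))
                best[f"{method},p={int(p)}"] = {"threshold": t, "mse": mse}
            except NoViableModelError:
                best[f"{method},p={int(p)}"] = None
    try:
        ratios = table_ratios(table).to_dict(orient="index")
    except (InvalidInputError, KeyError):
        ratios = None
    return json.dumps(
        {"meta": table.meta, "best_thresholds": best, "ratio_report": ratios},
        indent=2,
        default=float,
    )
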