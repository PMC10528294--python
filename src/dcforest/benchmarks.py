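"""Published reference results for the linear AR(1) benchmark.

``LINEAR_BENCHMARK_MSE`` holds the reported prediction-MSE table for
Model 1 under Setting 1 with rho = 0.5 (200 train / 1000 test samples,
200 replications): the unfiltered ("Traditional RF") forest and the CC and
DC filters over the canonical threshold grid, at p = 80, 100, 300 and 500.
It is the reference surface for the ratio diagnostics
(:func:`dcforest.experiments.table_ratios`) and for regression tests of the
replication harness; it is an input, not something this package computes.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["LINEAR_BENCHMARK_MSE", "TRADITIONAL_RF_MSE"]

_P = [80, 100, 300, 500]

#: Reported mean prediction MSE of the unfiltered forest, by p.
TRADITIONAL_RF_MSE = pd.Series(
    [30.4468, 32.3146, 37.0157, 39.9092], index=pd.Index(_P, name="p")
)

_CC = {
    0.0: [30.4568, 32.3099, 36.9560, 39.9454],
    0.1: [22.8696, 24.6372, 29.9454, 33.0442],
    0.2: [16.5787, 16.7887, 16.9566, 18.2652],
    0.3: [15.9218, 15.8904, 15.7830, 15.7455],
    0.4: [13.3106, 13.4890, 13.0326, 13.0766],
    0.5: [12.5500, 12.8932, 12.4917, 12.5678],
    0.6: [16.4444, 16.9558, 16.4051, 15.5541],
}

_DC = {
    0.0: [30.5103, 32.2662, 36.9264, 39.9739],
    0.1: [30.4394, 32.3129, 36.9792, 39.9157],
    0.2: [30.4860, 32.2304, 37.0245, 39.8639],
    0.3: [30.2126, 32.1138, 37.0334, 39.8655],
    0.4: [20.8794, 22.2660, 27.2499, 30.5149],
    0.5: [16.7517, 16.6341, 16.3208, 16.6678],
    0.6: [13.7511, 13.8123, 13.5889, 13.3938],
}


def _build() -> pd.DataFrame:
    rows = {("none", 0.0): TRADITIONAL_RF_MSE.tolist()}
    rows.update({("CC", t): v for t, v in _CC.items()})
    rows.update({("DC", t): v for t, v in _DC.items()})
    df = pd.DataFrame.from_dict(rows, orient="index", columns=_P)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["method", "threshold"])
    df.columns.name = "p"
    return df


#: Aggregated benchmark table: rows (method, threshold), columns p.
LINEAR_BENCHMARK_MSE = _build()
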