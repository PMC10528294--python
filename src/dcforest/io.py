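"""Tabular I/O and run provenance.

CSV/TSV readers for regression tables (named feature columns plus one
response column), writers for filter results and MSE tables, and the
:class:`RunManifest` every CLI run records so outputs can be regenerated
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "TabularInput",
    "RunManifest",
    "MissingResponseError",
    "NonNumericColumnError",
    "EmptyTableError",
    "read_table",
    "write_results",
]


class MissingResponseError(InvalidInputError):
    """The named response column is absent (or present more than once)."""


class NonNumericColumnError(InvalidInputError):
    """A retained column could not be interpreted as numeric."""


class EmptyTableError(InvalidInputError):
    """The file parsed to zero usable rows."""


@dataclass(frozen=True)
class TabularInput:
    """A validated numeric regression table.

    ``X`` preserves the file's column order (response column removed);
    rows containing non-finite values have been dropped with a counted
    warning.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple
    response_name: str
    n_dropped_rows: int = 0

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def read_table(path, response_name: str, delimiter: str | None = None) -> TabularInput:
    """Read a delimited text table with a header into a :class:`TabularInput`.

    The delimiter is auto-detected between comma and tab from the header
    line; anything else must be passed explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        if not header.strip():
            raise EmptyTableError(f"{path} is empty")
        delimiter = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=delimiter)
    if df.shape[0] == 0:
        raise EmptyTableError(f"{path} has a header but no data rows")
    matches = [c for c in df.columns if c == response_name]
    if len(matches) != 1:
        raise MissingResponseError(
            f"response column {response_name!r} occurs {len(matches)} times in {path}"
        )
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().all():
                raise NonNumericColumnError(f"column {col!r} is not numeric")
            df[col] = coerced
    values = df.to_numpy(dtype=float)
    finite = np.isfinite(values).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.warning("read_table: dropped %d row(s) with non-finite values", n_dropped)
        df = df.loc[finite]
    if df.shape[0] == 0:
        raise EmptyTableError(f"{path}: every row contained non-finite values")
    y = df[response_name].to_numpy(dtype=float)
    Xdf = df.drop(columns=[response_name])
    return TabularInput(
        X=Xdf.to_numpy(dtype=float),
        y=y,
        feature_names=tuple(Xdf.columns),
        response_name=response_name,
        n_dropped_rows=n_dropped,
    )


@dataclass
class RunManifest:
    """Everything needed to re-run a CLI invocation bit-identically."""

    command: str
    config: dict
    master_seed: int
    model_parse: dict = dataclasses.field(
        default_factory=lambda: {
            "model2": "y = X1^2 + X20 + X33^3 + X55^2 + eps",
            "model3": "y = 100*(X1-0.5)^2*(X2-0.25)_+ + eps",
        }
    )
    versions: dict = dataclasses.field(default_factory=dict)
    timestamp: str = ""

    def __post_init__(self):
        if not self.versions:
            import sklearn

            self.versions = {
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
            }
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def write_results(results, path, format: str | None = None) -> None:
    """Write filter/experiment results to disk.

    DataFrame-like tables go to CSV (NaN rendered as ``NA``); everything
    else is serialized as JSON.  ``format`` overrides the inference
    (``"csv"`` or ``"json"``).
    """
    from .experiments import MseTable
    from .screening import FilterResult

    path = Path(path)
    if isinstance(results, MseTable):
        results = results.aggregate()
    if isinstance(results, pd.DataFrame):
        if format == "json":
            path.write_text(results.to_json(orient="split", double_precision=15))
        else:
            results.to_csv(path, na_rep="NA")
        return
    if isinstance(results, FilterResult):
        results = {
            "threshold": results.threshold,
            "selected": list(results.selected),
            "ranking": list(results.ranking),
            "scores": [float(s) for s in results.scores],
        }
    try:
        path.write_text(json.dumps(results, indent=2, default=_jsonify))
    except OSError as exc:
        raise InvalidInputError(f"cannot write {path}: {exc}") from exc


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
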