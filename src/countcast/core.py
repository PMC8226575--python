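"""Shared containers, CSV/config I/O and the seeding contract.

Count series are stored as a plain ``T x n`` integer matrix with series
labels; all stochastic operations take a :class:`numpy.random.Generator`
(or a seed) so that a single root seed makes every downstream draw
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CountSeries",
    "SummaryStats",
    "RunConfig",
    "read_counts_csv",
    "write_counts_csv",
    "summarize",
    "spawn_rngs",
    "as_rng",
]


class CountDataError(ValueError):
    """Raised when input data violate the count-series contract."""


@dataclass(frozen=True)
class CountSeries:
    """A multivariate time series of counts.

    Parameters
    ----------
    values : ndarray of shape (T, n)
        Non-negative integer observations, one row per time point.
    labels : sequence of str
        Unique names for the n series.
    """

    values: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2 or arr.size == 0:
            raise CountDataError("count series must be a non-empty T x n matrix")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise CountDataError("count series entries must be integers")
            arr = np.round(arr).astype(np.int64)
        if (arr < 0).any():
            t, i = np.argwhere(arr < 0)[0]
            raise CountDataError(f"negative count at row {t}, column {i}")
        labels = tuple(self.labels) or tuple(f"x{i + 1}" for i in range(arr.shape[1]))
        if len(labels) != arr.shape[1]:
            raise CountDataError("number of labels must match number of series")
        if len(set(labels)) != len(labels):
            raise CountDataError("series labels must be unique")
        object.__setattr__(self, "values", arr.astype(np.int64))
        object.__setattr__(self, "labels", labels)

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_series(self) -> int:
        return self.values.shape[1]

    @property
    def time_index(self) -> np.ndarray:
        return np.arange(1, self.n_obs + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.labels))

    def __eq__(self, other: object) -> bool:  # pragma: no cover - trivial
        if not isinstance(other, CountSeries):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.values, other.values)


@dataclass(frozen=True)
class SummaryStats:
    """Per-series descriptive statistics (count units)."""

    labels: tuple[str, ...]
    mean: np.ndarray
    median: np.ndarray
    std: np.ndarray
    minimum: np.ndarray
    maximum: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": self.mean,
                "median": self.median,
                "st.d.": self.std,
                "minimum": self.minimum,
                "maximum": self.maximum,
            },
            index=list(self.labels),
        ).T


@dataclass
class RunConfig:
    """Model / estimation / forecast settings for a reproducible run.

    ``seed`` is the single root seed: every stochastic stage derives its own
    independent stream from it (see :func:`spawn_rngs`), so a fixed seed
    reproduces a run bit-for-bit on one platform.
    """

    model: str = "ssm"
    params: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)
    seed: int = 0
    estimation: dict = field(default_factory=dict)
    forecast: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = {
            "model": self.model,
            "params": self.params,
            "priors": self.priors,
            "seed": self.seed,
            "estimation": self.estimation,
            "forecast": self.forecast,
        }
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data))


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce a seed or generator to a :class:`numpy.random.Generator`."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one root seed.

    Uses :class:`numpy.random.SeedSequence` spawning, so streams are
    statistically independent and the derivation is fixed across runs.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def read_counts_csv(path: str | Path) -> CountSeries:
    """Read a count series from CSV.

    The file must have one header row of unique series labels and integer
    cells.  An optional first column named ``t`` is treated as the time
    index and dropped.  Missing, negative or non-integer cells are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CountDataError(f"empty counts file: {path}") from exc
    if df.shape[0] == 0:
        raise CountDataError(f"no data rows in counts file: {path}")
    if df.columns[0] == "t":
        df = df.drop(columns="t")
    if df.isna().any().any():
        row, col = next(
            (r, c) for c in df.columns for r in df.index[df[c].isna()]
        )
        raise CountDataError(f"missing value at row {row}, column {col!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0])
            raise CountDataError(f"non-numeric cell at row {row}, column {col!r}")
        if not np.allclose(vals, np.round(vals)):
            row = int(df.index[~np.isclose(vals, np.round(vals))][0])
            raise CountDataError(f"non-integer cell at row {row}, column {col!r}")
        if (vals < 0).any():
            row = int(df.index[vals < 0][0])
            raise CountDataError(f"negative count at row {row}, column {col!r}")
    return CountSeries(df.to_numpy(dtype=np.int64), tuple(df.columns))


def write_counts_csv(x: CountSeries, path: str | Path) -> None:
    """Write a count series to CSV (header row of labels, integer body)."""
    x.to_frame().to_csv(path, index=False)


def summarize(x: CountSeries | np.ndarray) -> SummaryStats:
    """Per-series mean, median, standard deviation, minimum and maximum.

    The standard deviation uses the n-1 denominator (sample form), as is
    conventional for descriptive tables of observed counts.
    """
    if not isinstance(x, CountSeries):
        x = CountSeries(np.asarray(x))
    v = x.values
    ddof = 1 if v.shape[0] > 1 else 0
    return SummaryStats(
        labels=x.labels,
        mean=v.mean(axis=0),
        median=np.median(v, axis=0),
        std=v.std(axis=0, ddof=ddof),
        minimum=v.min(axis=0),
        maximum=v.max(axis=0),
    )
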