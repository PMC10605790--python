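"""Right-censored survival data container and CSV loading.

A dataset is a cohort of subjects, each with a positive follow-up time, an
event indicator (1 = event observed, 0 = right-censored at that time) and a
row of covariates. Only complete cases are kept; no imputation is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("bpsurv")

#: feature kinds understood by the pipeline
CONTINUOUS = "continuous"
BINARY = "binary"


@dataclass
class SurvivalData:
    """Times, event indicators and covariates for one cohort.

    Parameters
    ----------
    times : array of shape (n,)
        Strictly positive follow-up times, all in the same unit.
    events : array of shape (n,)
        1 where the event was observed, 0 where the subject was
        right-censored at ``times``.
    covariates : array of shape (n, d)
        Feature matrix; no missing values.
    feature_names : list of str
    feature_kinds : list of str
        ``"continuous"``, ``"binary"`` or ``"onehot:<source>"`` per column.
    """

    times: np.ndarray
    events: np.ndarray
    covariates: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    feature_kinds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.times.shape[0] and self.covariates.size == 0:
            self.covariates = np.empty((self.times.shape[0], 0))
        n = self.times.shape[0]
        if self.events.shape[0] != n or self.covariates.shape[0] != n:
            raise ValueError(
                f"row mismatch: times {n}, events {self.events.shape[0]}, "
                f"covariates {self.covariates.shape[0]}"
            )
        if np.any(self.times <= 0):
            raise ValueError("all survival times must be strictly positive")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("events must be 0 (censored) or 1 (event)")
        self.events = self.events.astype(int)
        if np.isnan(self.covariates).any():
            raise ValueError("covariates contain missing values; only complete cases are supported")
        if not self.feature_names:
            self.feature_names = [f"x{i}" for i in range(self.covariates.shape[1])]
        if not self.feature_kinds:
            self.feature_kinds = [CONTINUOUS] * self.covariates.shape[1]
        if len(self.feature_names) != self.covariates.shape[1]:
            raise ValueError("feature_names length does not match covariate columns")
        if len(self.feature_kinds) != self.covariates.shape[1]:
            raise ValueError("feature_kinds length does not match covariate columns")

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def n_features(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def subset(self, idx) -> "SurvivalData":
        """Row-subset (copy) keeping column metadata."""
        idx = np.asarray(idx)
        if idx.dtype != bool:
            idx = idx.astype(np.intp)
        return replace(
            self,
            times=self.times[idx],
            events=self.events[idx],
            covariates=self.covariates[idx],
            feature_names=list(self.feature_names),
            feature_kinds=list(self.feature_kinds),
        )

    def select_features(self, cols) -> "SurvivalData":
        cols = list(cols)
        return replace(
            self,
            times=self.times.copy(),
            events=self.events.copy(),
            covariates=self.covariates[:, cols],
            feature_names=[self.feature_names[c] for c in cols],
            feature_kinds=[self.feature_kinds[c] for c in cols],
        )

    def to_frame(self, time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
        df = pd.DataFrame(self.covariates, columns=self.feature_names)
        df.insert(0, event_col, self.events)
        df.insert(0, time_col, self.times)
        return df


def _infer_kind(col: pd.Series) -> str:
    vals = col.dropna().unique()
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        return "categorical"
    if len(vals) <= 2:
        return BINARY
    return CONTINUOUS


def load_dataset_csv(
    path,
    time_col: str,
    event_col: str,
    schema: dict[str, str] | None = None,
) -> SurvivalData:
    """Load a survival dataset from CSV.

    Rows with any missing value are dropped (complete-case rule) and rows
    with non-positive times are rejected; both are logged. Binary columns
    are coerced to {0, 1}; categorical columns are one-hot encoded keeping
    all levels, tagged ``onehot:<source>`` in ``feature_kinds``.

    Parameters
    ----------
    schema : dict, optional
        Maps a covariate column to ``"continuous"``, ``"binary"`` or
        ``"categorical"``. Unlisted columns have their kind inferred from
        the data (two distinct values -> binary, text -> categorical,
        otherwise continuous).
    """
    df = pd.read_csv(path)
    for col in (time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} not in {sorted(df.columns)}")

    n_raw = len(df)
    df = df.dropna()
    if len(df) < n_raw:
        logger.info("dropped %d incomplete rows of %d", n_raw - len(df), n_raw)
    bad_t = df[time_col] <= 0
    if bad_t.any():
        logger.info("rejected %d rows with non-positive times", int(bad_t.sum()))
        df = df[~bad_t]

    feat_cols = [c for c in df.columns if c not in (time_col, event_col)]
    schema = dict(schema or {})
    cols: list[np.ndarray] = []
    names: list[str] = []
    kinds: list[str] = []
    for c in feat_cols:
        kind = schema.get(c) or _infer_kind(df[c])
        if kind == "categorical":
            levels = pd.unique(df[c])
            for lev in levels:  # all levels kept: priors regularize the redundancy
                cols.append((df[c] == lev).to_numpy(dtype=float))
                names.append(f"{c}_{lev}")
                kinds.append(f"onehot:{c}")
        elif kind == BINARY:
            vals = np.sort(pd.unique(df[c]))
            if len(vals) > 2:
                raise ValueError(f"column {c!r} declared binary but has {len(vals)} levels")
            cols.append((df[c] == vals[-1]).to_numpy(dtype=float))
            names.append(c)
            kinds.append(BINARY)
        else:
            cols.append(df[c].to_numpy(dtype=float))
            names.append(c)
            kinds.append(CONTINUOUS)

    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return SurvivalData(
        times=df[time_col].to_numpy(dtype=float),
        events=df[event_col].to_numpy(),
        covariates=X,
        feature_names=names,
        feature_kinds=kinds,
    )
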