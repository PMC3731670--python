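"""Loading and writing trial tables.

The on-disk format is a plain comma-separated file with a mandatory header
row.  Columns ``subj_idx`` (subject identifier), ``rt`` (response time in
seconds, > 0) and ``response`` (binary choice: 1 = upper boundary, 0 =
lower) are required; any additional column is preserved and may serve as a
condition label (categorical string) or a trial-level covariate (real
valued).  Response times are taken to be in seconds — no millisecond
auto-detection is attempted, but a median above 10 s triggers a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Dataset", "load_csv", "write_csv"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subj_idx", "rt", "response")


@dataclass
class Dataset:
    """A validated trial table plus a registry of column roles."""

    trials: pd.DataFrame
    condition_columns: list[str] = field(default_factory=list)
    covariate_columns: list[str] = field(default_factory=list)

    def __len__(self):
        return len(self.trials)

    @property
    def n_subjects(self) -> int:
        return self.trials["subj_idx"].nunique()

    def __getattr__(self, name):
        # delegate column access to the underlying frame
        trials = object.__getattribute__(self, "trials")
        if name in trials.columns:
            return trials[name]
        raise AttributeError(name)


def _validate(df: pd.DataFrame, source: str = "<data>") -> Dataset:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{source}: empty dataset (header only)")

    rt = pd.to_numeric(df["rt"], errors="coerce")
    bad_rt = df.index[rt.isna() | (rt <= 0)].tolist()
    if bad_rt:
        raise ValueError(f"{source}: non-positive or non-numeric rt in "
                         f"row(s) {bad_rt[:10]}")
    resp = pd.to_numeric(df["response"], errors="coerce")
    bad_resp = df.index[~resp.isin([0, 1])].tolist()
    if bad_resp:
        raise ValueError(f"{source}: response must be 0 or 1; offending "
                         f"row(s) {bad_resp[:10]}")
    df = df.copy()
    df["rt"] = rt.astype(float)
    df["response"] = resp.astype(int)
    if df["rt"].median() > 10:
        logger.warning("%s: median rt exceeds 10 s — response times are "
                       "expected in seconds, not milliseconds", source)

    conditions, covariates = [], []
    for col in df.columns:
        if col in REQUIRED_COLUMNS:
            continue
        as_num = pd.to_numeric(df[col], errors="coerce")
        if as_num.notna().all():
            df[col] = as_num.astype(float)
            covariates.append(col)
        else:
            df[col] = df[col].astype(str)
            conditions.append(col)
    return Dataset(df, conditions, covariates)


def load_csv(path) -> Dataset:
    """Load and validate a trial table from a comma-separated file.

    Requires a header row with at least subj_idx, rt and response; extra
    columns are kept and classified as covariates (fully numeric) or
    condition labels (anything else).  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=",", encoding="utf-8")
    return _validate(df, source=str(path))


def write_csv(dataset, path) -> None:
    """Write a trial table ('.' decimal, ',' separator, UTF-8, header row)
    such that :func:`load_csv` round-trips values and column order."""
    df = dataset.trials if isinstance(dataset, Dataset) else dataset
    df.to_csv(path, index=False, encoding="utf-8")
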