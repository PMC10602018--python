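"""Dataset ingestion, validation, and result serialisation.

The canonical in-memory container is :class:`MetaDataset`, a thin wrapper
around a long-format pandas DataFrame with one row per subject:

    trial, subject, z (0/1), x [x1..xp], s, t (NaN = missing true endpoint)

Files are plain delimited text (comma or tab, sniffed from the extension or
content).  Missing true endpoints are encoded as an empty field or "NA";
any other non-numeric entry is an error, never silently treated as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("sprisk")

__all__ = ["MetaDataset", "read_dataset", "write_dataset", "write_results", "format_display"]

_REQUIRED = ("trial", "subject", "z", "s")


@dataclass
class MetaDataset:
    """Long-format individual-patient meta-analytic data."""

    df: pd.DataFrame
    x_cols: tuple = ("x",)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in (*_REQUIRED, *self.x_cols) if c not in df.columns]
        if missing:
            raise ValueError(f"dataset is missing required columns: {missing}")
        if "t" not in df.columns:
            df = df.assign(t=np.nan)
            self.df = df
        dup = df.duplicated(subset=["trial", "subject"])
        if dup.any():
            rows = (df.index[dup] + 1).tolist()[:5]
            raise ValueError(
                f"duplicated (trial, subject) keys at rows {rows}"
            )
        bad_z = ~df["z"].isin([0, 1])
        if bad_z.any():
            rows = (df.index[bad_z] + 1).tolist()[:5]
            raise ValueError(f"z must be 0 or 1; offending rows {rows}")
        if df["s"].isna().any():
            rows = (df.index[df["s"].isna()] + 1).tolist()[:5]
            raise ValueError(f"surrogate s may not be missing; rows {rows}")

    @property
    def n_covariates(self) -> int:
        return len(self.x_cols)

    @property
    def trials(self) -> list:
        return list(pd.unique(self.df["trial"]))

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trial_frame(self, trial) -> pd.DataFrame:
        return self.df[self.df["trial"] == trial]

    def complete_case(self) -> "MetaDataset":
        """Subset to trials with every true endpoint observed (for fitting)."""
        has_miss = self.df.groupby("trial")["t"].apply(lambda s: s.isna().any())
        drop = list(has_miss[has_miss].index)
        if drop:
            logger.warning(
                "dropping %d trial(s) with missing true endpoints from the fit: %s",
                len(drop), drop,
            )
        return MetaDataset(
            self.df[~self.df["trial"].isin(drop)].reset_index(drop=True),
            x_cols=self.x_cols,
        )

    def summary(self) -> pd.DataFrame:
        g = self.df.groupby("trial")
        out = pd.DataFrame(
            {
                "n": g.size(),
                "n_treated": g["z"].sum().astype(int),
                "n_control": (g.size() - g["z"].sum()).astype(int),
                "n_missing_t": g["t"].apply(lambda s: int(s.isna().sum())),
            }
        )
        return out.reset_index()


def _sniff_sep(path: str) -> str:
    if str(path).endswith((".tsv", ".tab")):
        return "\t"
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") > head.count(",") else ","


def read_dataset(
    path,
    column_map: Optional[dict] = None,
    x_cols: Optional[tuple] = None,
) -> MetaDataset:
    """Read and validate a delimited dataset.

    ``column_map`` renames file columns onto the canonical schema, e.g.
    ``{"center": "trial", "sbp": "s"}``.  ``x_cols`` names the covariate
    columns after mapping (default: the single column "x" if present, else
    no covariates is an error for covariate-adjusted commands and the caller
    should pass ``x_cols=()``).
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""], keep_default_na=False,
                     float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    for col in ("z", "s"):
        if col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                rows = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
                raise ValueError(f"non-numeric values in column {col!r} at file rows {rows}")
            df[col] = pd.to_numeric(df[col])
    if "t" in df.columns:
        coerced = pd.to_numeric(df["t"], errors="coerce")
        bad = coerced.isna() & df["t"].notna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:5]
            raise ValueError(
                f"non-numeric, non-NA values in column 't' at file rows {rows}"
            )
        df["t"] = coerced
    if x_cols is None:
        x_cols = ("x",) if "x" in df.columns else ()
    ds = MetaDataset(df.reset_index(drop=True), x_cols=tuple(x_cols))
    for _, row in ds.summary().iterrows():
        logger.debug(
            "trial %s: n=%d (%d treated / %d control), %d missing T",
            row["trial"], row["n"], row["n_treated"], row["n_control"],
            row["n_missing_t"],
        )
    return ds


def write_dataset(data: MetaDataset, path) -> None:
    data.df.to_csv(path, index=False, na_rep="NA", float_format="%.17g")


def format_display(value: float, cap: float = 0.99, decimals: int = 3) -> str:
    """Journal-style display: three decimals, probabilities above 0.99 as '>0.99'."""
    if value > cap and value <= 1.0:
        return f">{cap:g}"
    return f"{value:.{decimals}f}"


def write_results(results: pd.DataFrame, path, display_cols=()) -> None:
    """Write a result table as delimited text.

    Full-precision values are kept; for each column named in
    ``display_cols`` an extra ``<col>_display`` column with the journal-style
    3-decimal / '>0.99' rendering is appended.
    """
    out = results.copy()
    for col in display_cols:
        if col in out.columns:
            out[f"{col}_display"] = out[col].map(format_display)
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    out.to_csv(path, sep=sep, index=False, float_format="%.17g")
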