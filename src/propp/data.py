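"""Subject-level data container shared by all analyses.

A :class:`SubjectTable` holds one row per patient with a source indicator
``z`` (1 = internal trial, 0 = external cohort), a binary outcome ``y`` and
an arbitrary set of covariate columns.  Categorical covariates are one-hot
encoded on demand; the encoding (column order, reference levels) is recorded
so that refits — e.g. inside a bootstrap — reuse exactly the same design
matrix layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SubjectTable", "CovariateEncoding"]


@dataclass(frozen=True)
class CovariateEncoding:
    """Frozen one-hot encoding of the covariate columns.

    ``columns`` are the encoded design-matrix column names (excluding the
    intercept); ``reference_levels`` maps each categorical source column to
    the level dropped as reference (the first level observed in the data).
    """

    source_columns: tuple[str, ...]
    columns: tuple[str, ...]
    categories: dict[str, tuple] = field(default_factory=dict)

    @property
    def reference_levels(self) -> dict[str, object]:
        return {c: lv[0] for c, lv in self.categories.items()}


class SubjectTable:
    """Per-patient table of (z, y, covariates) for both data sources.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain integer-coded ``z`` and ``y`` columns (0/1).  Remaining
        columns are treated as covariates unless ``covariates`` is given.
    covariates : sequence of str, optional
        Explicit covariate column names.
    subject_id : str, optional
        Name of an identifier column; generated as ``s0..s{N-1}`` if absent.
    """

    def __init__(self, df: pd.DataFrame, covariates=None, subject_id: str | None = None):
        df = df.copy()
        if len(df) == 0:
            raise ValueError("empty subject table")
        for col in ("z", "y"):
            if col not in df.columns:
                raise ValueError(f"required column '{col}' missing")
            vals = df[col].to_numpy()
            bad = ~np.isin(vals, (0, 1))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"column '{col}' must be coded 0/1; row {row} has value {vals[row]!r}"
                )
            df[col] = df[col].astype(int)
        if subject_id is not None and subject_id in df.columns:
            ids = df[subject_id].astype(str)
            df = df.drop(columns=[subject_id])
        else:
            ids = pd.Series([f"s{i}" for i in range(len(df))])
        if covariates is None:
            covariates = [c for c in df.columns if c not in ("z", "y")]
        missing = [c for c in covariates if c not in df.columns]
        if missing:
            raise ValueError(f"covariate columns not in table: {missing}")
        cov_df = df[list(covariates)]
        if cov_df.isna().any().any():
            bad_cols = list(cov_df.columns[cov_df.isna().any()])
            raise ValueError(
                f"missing covariate values in columns {bad_cols}; "
                "imputation is not supported — clean the data first"
            )
        self._df = df.reset_index(drop=True)
        self._df.insert(0, "subject_id", ids.to_numpy())
        self.covariates = list(covariates)
        if self.n_trial < 1:
            raise ValueError("no contrast in membership: need at least one trial subject")

    # -- basic accessors ---------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def z(self) -> np.ndarray:
        return self._df["z"].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self._df["y"].to_numpy()

    @property
    def subject_id(self) -> np.ndarray:
        return self._df["subject_id"].to_numpy()

    @property
    def n(self) -> int:
        return len(self._df)

    @property
    def n_trial(self) -> int:
        return int(self.z.sum())

    @property
    def n_external(self) -> int:
        return self.n - self.n_trial

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        return (
            f"SubjectTable(n={self.n}, n_trial={self.n_trial}, "
            f"n_external={self.n_external}, covariates={self.covariates})"
        )

    # -- design matrix -----------------------------------------------------
    def encoding(self) -> CovariateEncoding:
        """Derive the one-hot encoding from this table's covariate columns."""
        columns: list[str] = []
        categories: dict[str, tuple] = {}
        for c in self.covariates:
            s = self._df[c]
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
                levels = tuple(pd.unique(s))
                categories[c] = levels
                columns.extend(f"{c}[{lv}]" for lv in levels[1:])
            else:
                columns.append(c)
        return CovariateEncoding(tuple(self.covariates), tuple(columns), categories)

    def design_matrix(self, encoding: CovariateEncoding | None = None) -> pd.DataFrame:
        """Numeric design matrix (without intercept) under ``encoding``.

        Passing the encoding of another table guarantees column alignment,
        which is what bootstrap refits need.
        """
        enc = encoding or self.encoding()
        cols: dict[str, np.ndarray] = {}
        for c in enc.source_columns:
            if c in enc.categories:
                s = self._df[c]
                for lv in enc.categories[c][1:]:
                    cols[f"{c}[{lv}]"] = (s == lv).to_numpy(dtype=float)
            else:
                cols[c] = self._df[c].to_numpy(dtype=float)
        return pd.DataFrame(cols, columns=list(enc.columns))

    # -- convenience -------------------------------------------------------
    @classmethod
    def from_arrays(cls, z, y, x=None, covariate_names=None) -> "SubjectTable":
        """Build a table from plain arrays; ``x`` is an (N, K) matrix."""
        data = {"z": np.asarray(z), "y": np.asarray(y)}
        if x is not None:
            x = np.atleast_2d(np.asarray(x, dtype=float))
            if x.shape[0] != len(data["z"]):
                x = x.T
            names = covariate_names or [f"x{j + 1}" for j in range(x.shape[1])]
            for j, name in enumerate(names):
                data[name] = x[:, j]
        return cls(pd.DataFrame(data))

    def subset(self, mask) -> "SubjectTable":
        sub = self._df.loc[np.asarray(mask)].drop(columns=["subject_id"])
        return SubjectTable(sub, covariates=self.covariates)
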