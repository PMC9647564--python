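"""Gradient-study data container.

A :class:`GradientDataset` holds one row per site/observation: a response
(foliar N:P ratio in the motivating application), atmospheric nitrogen
deposition (kg N ha^-1 a^-1), zero or more continuous confounding covariates
(e.g. mean annual temperature), and a categorical grouping factor (tree
species or genus) that receives a random intercept in the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GradientDataset"]

#: default CSV column names
RESPONSE_COL = "response"
DEPOSITION_COL = "ndep"
GROUP_COL = "group"


@dataclass
class GradientDataset:
    """Observations along a nitrogen-deposition gradient.

    Parameters
    ----------
    response : array of shape (n,)
        Response variable (foliar N:P ratio; dimensionless).
    deposition : array of shape (n,)
        Nitrogen deposition in kg N ha^-1 a^-1; finite and non-negative.
    covariates : array of shape (n, K)
        Continuous confounding covariates; ``K`` may be 0.
    group : int array of shape (n,)
        Zero-based group index into ``group_labels``.
    group_labels : list of str
        One label per group (S labels).
    covariate_labels : list of str
        One label per covariate column.

    Notes
    -----
    ``n = 0`` is permitted: an empty dataset turns posterior sampling into
    prior sampling (the likelihood contributes nothing) and is used for
    prior-recovery checks.  File readers and the simulator never produce
    empty datasets.
    """

    response: np.ndarray
    deposition: np.ndarray
    covariates: np.ndarray
    group: np.ndarray
    group_labels: list[str]
    covariate_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.deposition = np.asarray(self.deposition, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.group = np.asarray(self.group, dtype=np.int64)
        self.group_labels = [str(g) for g in self.group_labels]
        self.covariate_labels = [str(c) for c in self.covariate_labels]
        n = self.response.shape[0]
        if self.covariates.ndim == 1:
            self.covariates = self.covariates.reshape(n, -1)
        if self.covariates.size == 0:
            self.covariates = self.covariates.reshape(n, len(self.covariate_labels))
        if self.deposition.shape != (n,) or self.group.shape != (n,):
            raise ValueError("response, deposition and group must share length n")
        if self.covariates.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
        if self.covariates.shape[1] != len(self.covariate_labels):
            raise ValueError("covariate_labels must match covariate columns")
        if n:
            if not np.all(np.isfinite(self.response)):
                raise ValueError("non-finite response values")
            if not np.all(np.isfinite(self.deposition)):
                raise ValueError("non-finite deposition values")
            if np.any(self.deposition < 0):
                raise ValueError("deposition must be non-negative")
            if self.covariates.size and not np.all(np.isfinite(self.covariates)):
                raise ValueError("non-finite covariate values")
            if self.group.min() < 0 or self.group.max() >= len(self.group_labels):
                raise ValueError("group index outside 0..S-1")
        if not self.group_labels:
            raise ValueError("at least one group label is required")

    # ------------------------------------------------------------------ #
    @property
    def n(self) -> int:
        return self.response.shape[0]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_labels)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n

    # ------------------------------------------------------------------ #
    @classmethod
    def empty(
        cls,
        group_labels: list[str] | None = None,
        covariate_labels: list[str] | None = None,
    ) -> "GradientDataset":
        """Zero-observation dataset for prior-only sampling."""
        group_labels = group_labels or ["g1"]
        covariate_labels = covariate_labels or []
        return cls(
            response=np.empty(0),
            deposition=np.empty(0),
            covariates=np.empty((0, len(covariate_labels))),
            group=np.empty(0, dtype=np.int64),
            group_labels=list(group_labels),
            covariate_labels=list(covariate_labels),
        )

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        response_col: str = RESPONSE_COL,
        deposition_col: str = DEPOSITION_COL,
        group_col: str = GROUP_COL,
        covariate_cols: list[str] | None = None,
        exclude_cols: tuple[str, ...] = (),
    ) -> "GradientDataset":
        """Build a dataset from a data frame.

        Required columns: ``response_col``, ``deposition_col``, ``group_col``.
        If ``covariate_cols`` is None, every other numeric column (minus
        ``exclude_cols``) is treated as a covariate.  Missing values in any
        used column are an error, never silently dropped.
        """
        for col in (response_col, deposition_col, group_col):
            if col not in df.columns:
                raise ValueError(f"required column {col!r} is missing")
        if len(df) == 0:
            raise ValueError("input table has no rows")
        if covariate_cols is None:
            covariate_cols = [
                c
                for c in df.columns
                if c not in (response_col, deposition_col, group_col)
                and c not in exclude_cols
                and pd.api.types.is_numeric_dtype(df[c])
            ]
        else:
            for c in covariate_cols:
                if c not in df.columns:
                    raise ValueError(f"covariate column {c!r} is missing")
        used = [response_col, deposition_col, group_col, *covariate_cols]
        for col in used:
            bad = df[col].isna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(f"missing value in column {col!r} at row {row}")
        labels = sorted(df[group_col].astype(str).unique())
        index = {lab: i for i, lab in enumerate(labels)}
        group = df[group_col].astype(str).map(index).to_numpy(dtype=np.int64)
        return cls(
            response=df[response_col].to_numpy(dtype=float),
            deposition=df[deposition_col].to_numpy(dtype=float),
            covariates=df[covariate_cols].to_numpy(dtype=float).reshape(len(df), -1),
            group=group,
            group_labels=labels,
            covariate_labels=list(covariate_cols),
        )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "GradientDataset":
        """Read a comma-separated table (UTF-8, '.' decimal, header row)."""
        # round_trip parsing keeps write->read bit-exact at 17 sig. digits
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"), **kwargs)

    # ------------------------------------------------------------------ #
    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                RESPONSE_COL: self.response,
                DEPOSITION_COL: self.deposition,
                GROUP_COL: [self.group_labels[i] for i in self.group],
            }
        )
        for k, lab in enumerate(self.covariate_labels):
            out[lab] = self.covariates[:, k]
        return out

    def to_csv(self, path) -> None:
        # 17 significant digits so the CSV round-trips bit-for-bit
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    def fingerprint(self) -> str:
        """Short stable hash of the data arrays (for provenance logging)."""
        import hashlib

        h = hashlib.sha256()
        for arr in (self.response, self.deposition, self.covariates, self.group):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update("|".join(self.group_labels).encode())
        h.update("|".join(self.covariate_labels).encode())
        return h.hexdigest()[:16]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GradientDataset):
            return NotImplemented
        return (
            np.array_equal(self.response, other.response)
            and np.array_equal(self.deposition, other.deposition)
            and np.array_equal(self.covariates, other.covariates)
            and np.array_equal(self.group, other.group)
            and self.group_labels == other.group_labels
            and self.covariate_labels == other.covariate_labels
        )
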