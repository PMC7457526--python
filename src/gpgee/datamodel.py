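"""Domain types and long-format I/O for subject-clustered multilevel responses.

The data of interest are responses measured on each subject under every
combination of J experimental conditions and K channels (e.g. ERP peak
amplitudes recorded under standard/oddball stimuli at K scalp electrodes).
Within a subject the m = J*K observations are stored *condition-major*:

    (j=1,k=1), (j=1,k=2), ..., (j=1,k=K), (j=2,k=1), ..., (j=J,k=K)

All correlation code in this package assumes that ordering; the loader
enforces it regardless of row order in the input file.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BalanceError",
    "ColumnMap",
    "ConfigurationError",
    "DesignMatrix",
    "GroupStructure",
    "LongitudinalDataset",
    "ModelSpec",
    "ScreeningError",
    "build_design",
    "load_long_table",
    "prescreen_correlated",
    "write_long_table",
]


class ConfigurationError(ValueError):
    """A required column, factor level or option is missing or invalid."""


class BalanceError(ValueError):
    """A subject's (condition, channel) grid is incomplete or duplicated."""


class ScreeningError(ValueError):
    """Predictor prescreening cannot proceed (e.g. zero-variance column)."""


@dataclass(frozen=True)
class ColumnMap:
    """Names of the identifier columns in a long-format table."""

    subject: str = "subject"
    condition: str = "condition"
    channel: str = "channel"
    response: str = "response"


@dataclass(frozen=True)
class ModelSpec:
    """Marginal model family: link g, variance function v, dispersion phi.

    Only the Gaussian family with identity link is exercised; the variance
    function and link hooks are retained so the estimating equations keep
    their general form.  The dispersion is fixed at phi = 1; residual scale
    is absorbed by the unit-diagonal normalisation of the working
    correlation.
    """

    family: str = "gaussian"
    link: str = "identity"
    dispersion: float = 1.0

    def __post_init__(self) -> None:
        if self.family != "gaussian" or self.link != "identity":
            raise ConfigurationError(
                "only the gaussian family with identity link is supported"
            )
        if self.dispersion != 1.0:
            raise ConfigurationError("dispersion is fixed at 1")

    def variance(self, mu: np.ndarray) -> np.ndarray:
        """Variance function v(mu); constant 1 for the Gaussian family."""
        return np.ones_like(mu)

    def inverse_link(self, eta: np.ndarray) -> np.ndarray:
        return eta


@dataclass
class LongitudinalDataset:
    """Balanced subject-clustered responses on a J x K factor grid.

    Attributes
    ----------
    subjects : ndarray, shape (n,)
        Unique subject identifiers, in first-appearance order.
    conditions, channels : list
        Factor levels, in first-appearance order (J and K levels).
    response : ndarray, shape (n, J*K)
        One row per subject, condition-major within the row.
    covariates : DataFrame, shape (n*J*K, p)
        Observation-level covariates, rows aligned with ``response.ravel()``.
    """

    subjects: np.ndarray
    conditions: list
    channels: list
    response: np.ndarray
    covariates: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def cluster_size(self) -> int:
        return self.n_conditions * self.n_channels

    @property
    def dims(self) -> tuple[int, int]:
        return self.n_conditions, self.n_channels

    def validate(self) -> None:
        n, m = self.response.shape
        if n != self.n_subjects or m != self.cluster_size:
            raise BalanceError(
                f"response shape {self.response.shape} does not match "
                f"{self.n_subjects} subjects x {self.cluster_size} cells"
            )
        if len(self.covariates) != n * m:
            raise BalanceError("covariate rows do not match n * J * K")
        if not np.all(np.isfinite(self.response)):
            raise ConfigurationError("non-finite response values")
        if not np.all(np.isfinite(self.covariates.to_numpy(dtype=float))):
            raise ConfigurationError("non-finite covariate values")

    def to_long_frame(self, columns: ColumnMap = ColumnMap()) -> pd.DataFrame:
        """Tidy long-format frame in the canonical condition-major order."""
        n, J, K = self.n_subjects, self.n_conditions, self.n_channels
        frame = pd.DataFrame(
            {
                columns.subject: np.repeat(self.subjects, J * K),
                columns.condition: np.tile(np.repeat(self.conditions, K), n),
                columns.channel: np.tile(self.channels, n * J),
                columns.response: self.response.ravel(),
            }
        )
        return pd.concat([frame, self.covariates.reset_index(drop=True)], axis=1)


@dataclass(frozen=True)
class GroupStructure:
    """Partition of penalized coefficient indices into selection groups.

    ``groups[g]`` lists the coefficient indices of group g (all selected or
    dropped together); ``unpenalized`` lists indices never penalized (e.g.
    intercept and condition effects).  Together they must cover every
    coefficient exactly once.
    """

    groups: tuple[tuple[int, ...], ...]
    unpenalized: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "groups", tuple(tuple(int(i) for i in g) for g in self.groups)
        )
        object.__setattr__(
            self, "unpenalized", tuple(int(i) for i in self.unpenalized)
        )
        seen: set[int] = set()
        for g, idx in enumerate(self.groups):
            if len(idx) == 0:
                raise ConfigurationError(f"group {g} is empty")
            if seen.intersection(idx):
                raise ConfigurationError("groups are not pairwise disjoint")
            seen.update(idx)
        if seen.intersection(self.unpenalized):
            raise ConfigurationError("unpenalized overlaps a penalty group")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_coefficients(self) -> int:
        return len(self.unpenalized) + sum(len(g) for g in self.groups)

    def covered_indices(self) -> set[int]:
        out = set(self.unpenalized)
        for g in self.groups:
            out.update(g)
        return out

    def check_covers(self, p: int) -> None:
        if self.covered_indices() != set(range(p)):
            raise ConfigurationError(
                f"group structure does not cover coefficients 0..{p - 1} exactly"
            )

    @staticmethod
    def singletons(p: int, unpenalized: Sequence[int] = ()) -> "GroupStructure":
        """One group per coefficient: individual (non-group) selection."""
        un = set(int(i) for i in unpenalized)
        return GroupStructure(
            groups=tuple((j,) for j in range(p) if j not in un),
            unpenalized=tuple(sorted(un)),
        )

    @staticmethod
    def contiguous(p: int, group_size: int) -> "GroupStructure":
        """Consecutive equally sized groups covering coefficients 0..p-1."""
        if p % group_size:
            raise ConfigurationError("p is not a multiple of group_size")
        return GroupStructure(
            groups=tuple(
                tuple(range(s, s + group_size)) for s in range(0, p, group_size)
            )
        )

    @staticmethod
    def from_json(path: str | os.PathLike, column_names: Sequence[str]) -> "GroupStructure":
        """Read ``{"groups": [[name, ...], ...], "unpenalized": [name, ...]}``."""
        with open(path) as fh:
            raw = json.load(fh)
        index = {name: j for j, name in enumerate(column_names)}

        def lookup(name: str) -> int:
            if name not in index:
                raise ConfigurationError(f"unknown column in group file: {name!r}")
            return index[name]

        return GroupStructure(
            groups=tuple(tuple(lookup(n) for n in g) for g in raw.get("groups", [])),
            unpenalized=tuple(lookup(n) for n in raw.get("unpenalized", [])),
        )


# ---------------------------------------------------------------------------
# Long-format I/O
# ---------------------------------------------------------------------------

def _delimiter_for(path: str | os.PathLike) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    return "\t" if ext in {".tsv", ".txt"} else ","


def load_long_table(
    path: str | os.PathLike,
    columns: ColumnMap = ColumnMap(),
    covariate_columns: Sequence[str] | None = None,
) -> LongitudinalDataset:
    """Load a delimited long-format table into a balanced dataset.

    One input row per (subject, condition, channel) observation.  Rows may
    appear in any order; they are re-sorted condition-major within subject,
    with factor levels recorded in order of first appearance in the file.

    Parameters
    ----------
    path
        CSV (``.csv``) or TSV (``.tsv``/``.txt``) file with a header row.
    columns
        Names of the subject / condition / channel / response columns.
    covariate_columns
        Covariates to keep; default: every remaining column.

    Raises
    ------
    ConfigurationError
        If a named column is missing.
    BalanceError
        If any subject's (condition, channel) grid is incomplete or has
        duplicate cells.
    """
    table = pd.read_csv(path, sep=_delimiter_for(path))
    for name in dataclasses.astuple(columns):
        if name not in table.columns:
            raise ConfigurationError(f"missing required column {name!r}")
    if covariate_columns is None:
        covariate_columns = [
            c for c in table.columns if c not in set(dataclasses.astuple(columns))
        ]
    else:
        for name in covariate_columns:
            if name not in table.columns:
                raise ConfigurationError(f"missing covariate column {name!r}")

    response = pd.to_numeric(table[columns.response], errors="raise")
    if response.isna().any():
        raise ConfigurationError("missing values in response column")
    covariates = table[list(covariate_columns)].apply(
        pd.to_numeric, errors="raise"
    )
    if covariates.isna().to_numpy().any():
        raise ConfigurationError("missing values in covariate columns")

    subjects = list(dict.fromkeys(table[columns.subject]))
    conditions = list(dict.fromkeys(table[columns.condition]))
    channels = list(dict.fromkeys(table[columns.channel]))
    J, K = len(conditions), len(channels)
    m = J * K

    cond_code = table[columns.condition].map({c: i for i, c in enumerate(conditions)})
    chan_code = table[columns.channel].map({c: i for i, c in enumerate(channels)})
    subj_code = table[columns.subject].map({s: i for i, s in enumerate(subjects)})
    cell = cond_code.to_numpy() * K + chan_code.to_numpy()

    n = len(subjects)
    resp = np.full((n, m), np.nan)
    cov_rows = np.full(n * m, -1, dtype=int)
    for row, (s, c) in enumerate(zip(subj_code.to_numpy(), cell)):
        if cov_rows[s * m + c] != -1:
            raise BalanceError(
                f"duplicate (condition, channel) cell for subject {subjects[s]!r}"
            )
        resp[s, c] = response.iloc[row]
        cov_rows[s * m + c] = row
    if (cov_rows == -1).any():
        bad = subjects[int(np.argmax(cov_rows == -1)) // m]
        raise BalanceError(f"incomplete condition x channel grid for subject {bad!r}")

    dataset = LongitudinalDataset(
        subjects=np.asarray(subjects),
        conditions=conditions,
        channels=channels,
        response=resp,
        covariates=covariates.iloc[cov_rows].reset_index(drop=True),
    )
    dataset.validate()
    return dataset


def write_long_table(
    dataset: LongitudinalDataset,
    path: str | os.PathLike,
    columns: ColumnMap = ColumnMap(),
) -> None:
    """Write the dataset back to delimited text in canonical order."""
    frame = dataset.to_long_frame(columns)
    frame.to_csv(path, sep=_delimiter_for(path), index=False)


# ---------------------------------------------------------------------------
# Design-matrix assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignMatrix:
    """Stacked design matrix with named columns and a penalty grouping.

    ``matrix`` has one row per observation in condition-major subject order;
    ``groups`` indexes its columns.  Condition dummies and the intercept are
    unpenalized; the K-1 channel dummies form a single penalty group so the
    multi-level channel factor is selected or dropped as a whole.
    """

    matrix: np.ndarray
    column_names: tuple[str, ...]
    groups: GroupStructure


def build_design(
    dataset: LongitudinalDataset,
    include_intercept: bool = True,
    condition_effects: bool = True,
    channel_effects: bool = True,
    covariate_groups: Sequence[Sequence[str]] | None = None,
    unpenalized_covariates: Sequence[str] = (),
) -> DesignMatrix:
    """Assemble [intercept | condition dummies | channel dummies | covariates].

    Factors use reference-cell coding with the first-appearance level as
    reference.  By default each covariate is its own singleton penalty
    group; ``covariate_groups`` assigns named covariates to shared groups
    and ``unpenalized_covariates`` exempts columns from selection.
    """
    n, (J, K) = dataset.n_subjects, dataset.dims
    m = J * K
    if condition_effects and J < 2:
        raise ConfigurationError("condition effects need at least 2 conditions")
    if channel_effects and K < 2:
        raise ConfigurationError("channel effects need at least 2 channels")

    blocks: list[np.ndarray] = []
    names: list[str] = []
    unpen: list[int] = []
    groups: list[tuple[int, ...]] = []

    if include_intercept:
        blocks.append(np.ones((n * m, 1)))
        names.append("intercept")
        unpen.append(0)
    if condition_effects:
        cond_of_row = np.tile(np.repeat(np.arange(J), K), n)
        for j in range(1, J):
            blocks.append((cond_of_row == j).astype(float)[:, None])
            unpen.append(len(names))
            names.append(f"condition_{dataset.conditions[j]}")
    if channel_effects:
        chan_of_row = np.tile(np.arange(K), n * J)
        start = len(names)
        for k in range(1, K):
            blocks.append((chan_of_row == k).astype(float)[:, None])
            names.append(f"channel_{dataset.channels[k]}")
        groups.append(tuple(range(start, start + K - 1)))

    cov_names = list(dataset.covariates.columns)
    offset = len(names)
    if cov_names:
        blocks.append(dataset.covariates.to_numpy(dtype=float))
        names.extend(cov_names)
    col_of = {c: offset + j for j, c in enumerate(cov_names)}
    unpen_cov = set(unpenalized_covariates)
    for c in unpen_cov:
        if c not in col_of:
            raise ConfigurationError(f"unknown unpenalized covariate {c!r}")
        unpen.append(col_of[c])
    if covariate_groups is None:
        covariate_groups = [[c] for c in cov_names if c not in unpen_cov]
    grouped: set[str] = set()
    for g in covariate_groups:
        idx = []
        for c in g:
            if c not in col_of:
                raise ConfigurationError(f"unknown covariate in group: {c!r}")
            if c in unpen_cov or c in grouped:
                raise ConfigurationError(f"covariate {c!r} assigned twice")
            grouped.add(c)
            idx.append(col_of[c])
        groups.append(tuple(idx))
    leftovers = [c for c in cov_names if c not in grouped and c not in unpen_cov]
    for c in leftovers:
        groups.append((col_of[c],))

    matrix = np.hstack(blocks) if blocks else np.empty((n * m, 0))
    structure = GroupStructure(groups=tuple(groups), unpenalized=tuple(unpen))
    structure.check_covers(matrix.shape[1])
    return DesignMatrix(
        matrix=matrix, column_names=tuple(names), groups=structure
    )


# ---------------------------------------------------------------------------
# Predictor prescreening
# ---------------------------------------------------------------------------

def prescreen_correlated(
    covariates: pd.DataFrame | np.ndarray,
    threshold: float = 0.7,
) -> tuple[list[int], list[tuple[int, int, float]]]:
    """Drop near-duplicate predictors by pairwise Pearson correlation.

    A single greedy pass over column pairs (in listed order): whenever
    ``|r| > threshold`` the *later-listed* column is dropped and takes no
    further part in comparisons.  Deterministic and idempotent.

    Returns
    -------
    retained : list of int
        Column indices kept, in original order.
    dropped : list of (kept, dropped, r) triples
        For each removed column, the earlier column that triggered the
        removal and their sample correlation.
    """
    X = np.asarray(
        covariates.to_numpy(dtype=float)
        if isinstance(covariates, pd.DataFrame)
        else covariates,
        dtype=float,
    )
    if X.ndim != 2 or X.shape[1] < 2:
        raise ScreeningError("prescreening needs at least two columns")
    if not 0 < threshold < 1:
        raise ScreeningError("threshold must lie in (0, 1)")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        names = (
            list(covariates.columns)
            if isinstance(covariates, pd.DataFrame)
            else list(range(X.shape[1]))
        )
        bad = names[int(np.argmax(sd == 0))]
        raise ScreeningError(f"zero-variance column {bad!r}")
    corr = np.corrcoef(X, rowvar=False)

    p = X.shape[1]
    retained: list[int] = []
    dropped: list[tuple[int, int, float]] = []
    removed = np.zeros(p, dtype=bool)
    for j in range(p):
        if removed[j]:
            continue
        retained.append(j)
        for k in range(j + 1, p):
            if not removed[k] and abs(corr[j, k]) > threshold:
                removed[k] = True
                dropped.append((j, k, float(corr[j, k])))
    return retained, dropped
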