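"""Trial data model, validation, and readers/writers.

The universal input object is :class:`TrialDataset`: one row per randomized
participant, with a possibly-missing outcome ``y``, a binary treatment
assignment ``t``, an observation indicator ``s`` (1 exactly when the outcome
was measured), and named baseline covariates.  All estimators in this package
consume this object.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialDataset",
    "AnalysisConfig",
    "ForestSettings",
    "TreeSettings",
    "TrialValidationError",
    "DegenerateDesignError",
    "TreatmentCodingError",
    "read_trial_table",
    "write_trial_table",
    "apply_covariate_missing_policy",
]

_ROLE_COLUMNS = ("participant_id", "outcome", "treatment", "observed")


class TrialValidationError(ValueError):
    """The table violates a TrialDataset invariant."""


class DegenerateDesignError(TrialValidationError):
    """One of the two arms is empty (or has no observed outcomes where required)."""


class TreatmentCodingError(TrialValidationError):
    """Treatment column cannot be coded to {0, 1} without an explicit reference level."""


@dataclass(frozen=True)
class TrialDataset:
    """Per-participant two-arm trial table.

    Parameters
    ----------
    frame
        DataFrame with columns ``participant_id``, ``outcome`` (float, NaN when
        unobserved), ``treatment`` (0/1 int), ``observed`` (0/1 int), followed
        by the covariate columns.
    covariates
        Names of the baseline covariate columns, in order.  Covariates are
        baseline (pre-assignment) by contract; nothing here is ever derived
        from the outcome.
    """

    frame: pd.DataFrame
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _ROLE_COLUMNS if c not in df.columns]
        if missing:
            raise TrialValidationError(f"missing required columns: {missing}")
        for cov in self.covariates:
            if cov not in df.columns:
                raise TrialValidationError(f"covariate column not in frame: {cov!r}")
        if df["participant_id"].duplicated().any():
            dups = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
            raise TrialValidationError(f"duplicate participant_id values: {dups[:5]}")
        t = df["treatment"].to_numpy()
        if not np.isin(t, (0, 1)).all():
            raise TreatmentCodingError("treatment must be coded 0/1 for every row")
        if (t == 1).sum() == 0 or (t == 0).sum() == 0:
            raise DegenerateDesignError("both treatment arms must be non-empty")
        s = df["observed"].to_numpy()
        y_present = df["outcome"].notna().to_numpy()
        if not np.array_equal(s.astype(bool), y_present):
            raise TrialValidationError(
                "observed indicator must be 1 exactly when the outcome is present"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def y(self) -> np.ndarray:
        """Outcome vector (NaN where unobserved)."""
        return self.frame["outcome"].to_numpy(dtype=float)

    @property
    def t(self) -> np.ndarray:
        """Treatment assignment vector in {0, 1}."""
        return self.frame["treatment"].to_numpy(dtype=int)

    @property
    def s(self) -> np.ndarray:
        """Observation indicator in {0, 1}; 0 marks attrition."""
        return self.frame["observed"].to_numpy(dtype=int)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def n_treated(self) -> int:
        return int((self.t == 1).sum())

    @property
    def n_control(self) -> int:
        return int((self.t == 0).sum())

    def covariate_frame(self) -> pd.DataFrame:
        return self.frame[list(self.covariates)]

    def observed_outcomes(self, arm: int) -> np.ndarray:
        """Observed outcome values for one arm (0 = control, 1 = treated)."""
        m = (self.t == arm) & (self.s == 1)
        return self.y[m]

    @classmethod
    def from_arrays(
        cls,
        outcome: Sequence[float],
        treatment: Sequence[int],
        covariates: Mapping[str, Sequence] | None = None,
        participant_id: Sequence | None = None,
    ) -> "TrialDataset":
        """Build a dataset from raw vectors; NaN outcomes mark attrition."""
        y = np.asarray(outcome, dtype=float)
        t = np.asarray(treatment)
        ids = (
            np.asarray(participant_id)
            if participant_id is not None
            else np.arange(1, len(y) + 1)
        )
        df = pd.DataFrame(
            {
                "participant_id": ids,
                "outcome": y,
                "treatment": t,
                "observed": (~np.isnan(y)).astype(int),
            }
        )
        names: tuple[str, ...] = ()
        if covariates:
            for name, values in covariates.items():
                df[name] = np.asarray(values) if not isinstance(values, pd.Series) else values.to_numpy()
            names = tuple(covariates)
        return cls(df, names)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        treatment: str,
        covariates: Sequence[str] = (),
        participant_id: str | None = None,
        treatment_reference: object | None = None,
    ) -> "TrialDataset":
        """Build a dataset from an arbitrary DataFrame by naming the role columns."""
        out = pd.DataFrame(
            {
                "participant_id": (
                    df[participant_id].to_numpy()
                    if participant_id is not None
                    else np.arange(1, len(df) + 1)
                ),
                "outcome": pd.to_numeric(df[outcome], errors="coerce").to_numpy(dtype=float),
                "treatment": _code_treatment(df[treatment], treatment_reference),
            }
        )
        out["observed"] = out["outcome"].notna().astype(int)
        for cov in covariates:
            out[cov] = df[cov].to_numpy() if not isinstance(df[cov].dtype, pd.CategoricalDtype) else df[cov].values
        return cls(out, tuple(covariates))


def _code_treatment(col: pd.Series, reference: object | None) -> np.ndarray:
    """Code a treatment column to {0,1}.

    Accepts 0/1 numerics, booleans, or any two-level column when an explicit
    reference (control) level is given.  Arm identity is never inferred from
    the data.
    """
    vals = col.to_numpy()
    uniq = pd.unique(col.dropna())
    if col.isna().any():
        raise TreatmentCodingError("treatment column contains missing values")
    if pd.api.types.is_bool_dtype(col):
        return vals.astype(int)
    if pd.api.types.is_numeric_dtype(col) and set(np.unique(vals)) <= {0, 1}:
        return vals.astype(int)
    if len(uniq) != 2:
        raise TreatmentCodingError(
            f"treatment column has {len(uniq)} levels; exactly two required"
        )
    if reference is None:
        raise TreatmentCodingError(
            "non-binary treatment coding requires an explicit reference (control) "
            f"level; levels found: {sorted(map(str, uniq))}"
        )
    if reference not in set(uniq):
        raise TreatmentCodingError(f"reference level {reference!r} not among {list(uniq)}")
    return (vals != reference).astype(int)


# ---------------------------------------------------------------------------
# Analysis configuration


@dataclass(frozen=True)
class ForestSettings:
    """Random-forest hyperparameters for the attrition importance screen."""

    n_trees: int = 500
    max_features: str | int | float = "sqrt"
    min_leaf: int = 5
    cv_folds: int = 5
    n_permutations: int = 10  # full-length permutation repeats
    benchmark_probes: int = 5  # noise columns; the bar is their max importance

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_leaf < 1 or self.cv_folds < 2:
            raise ValueError("forest settings out of range")
        if self.benchmark_probes < 1:
            raise ValueError("at least one benchmark probe is required")


@dataclass(frozen=True)
class TreeSettings:
    """Conditioning-tree limits: cell count and minimum per-cell support."""

    max_leaves: int = 4
    min_cell_per_arm: int = 20  # minimum observed outcomes per arm per cell

    def __post_init__(self) -> None:
        if self.max_leaves < 1 or self.min_cell_per_arm < 1:
            raise ValueError("tree settings out of range")


@dataclass(frozen=True)
class AnalysisConfig:
    """Shared analysis settings: significance levels, bootstrap, learner knobs."""

    alpha: float = 0.05
    ci_level: float = 0.95
    n_bootstrap: int = 500
    seed: int = 0
    rf_settings: ForestSettings = field(default_factory=ForestSettings)
    tree_settings: TreeSettings = field(default_factory=TreeSettings)
    covariate_missing_policy: str = "missing-indicator"
    trim_mode: str = "fractional"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.covariate_missing_policy not in ("missing-indicator", "drop-row"):
            raise ValueError(f"unknown covariate_missing_policy: {self.covariate_missing_policy}")
        if self.trim_mode not in ("fractional", "integer"):
            raise ValueError(f"unknown trim_mode: {self.trim_mode}")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Readers / writers

_MISSING_TOKENS = ("", "NA", "NaN", "nan")


def read_trial_table(
    path: str | Path,
    column_map: Mapping[str, object],
    dialect: str = "delimited",
) -> TrialDataset:
    """Read a trial table from delimited text or a Stata ``.dta`` file.

    ``column_map`` names the role columns: keys ``outcome``, ``treatment``
    (required), ``participant_id``, ``covariates`` (a list), and
    ``treatment_reference`` (required for string-coded treatments).  Empty
    fields and ``NA`` in the outcome column mark attrition.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "delimited":
        df = pd.read_csv(path, na_values=list(_MISSING_TOKENS), keep_default_na=True)
    elif dialect == "stata-table":
        # pandas' native Stata reader; value labels become categorical levels
        df = pd.read_stata(path, convert_categoricals=True)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    required = {"outcome", "treatment"}
    missing_roles = required - set(column_map)
    if missing_roles:
        raise TrialValidationError(f"column_map missing roles: {sorted(missing_roles)}")
    for role in ("outcome", "treatment", "participant_id"):
        col = column_map.get(role)
        if col is not None and col not in df.columns:
            raise TrialValidationError(f"mapped column {col!r} for role {role!r} not in file")
    for cov in column_map.get("covariates", ()):  # type: ignore[union-attr]
        if cov not in df.columns:
            raise TrialValidationError(f"mapped covariate column {cov!r} not in file")

    return TrialDataset.from_dataframe(
        df,
        outcome=column_map["outcome"],  # type: ignore[arg-type]
        treatment=column_map["treatment"],  # type: ignore[arg-type]
        covariates=tuple(column_map.get("covariates", ())),  # type: ignore[arg-type]
        participant_id=column_map.get("participant_id"),  # type: ignore[arg-type]
        treatment_reference=column_map.get("treatment_reference"),
    )


def write_trial_table(ds: TrialDataset, path: str | Path) -> None:
    """Write a dataset as UTF-8 CSV; missing outcomes become empty fields.

    Round-trips through :func:`read_trial_table` with the canonical column map.
    """
    df = ds.frame.drop(columns=["observed"]).copy()
    df.to_csv(path, index=False, na_rep="")


def canonical_column_map(ds: TrialDataset) -> dict:
    """The column map that re-reads a file written by :func:`write_trial_table`."""
    return {
        "participant_id": "participant_id",
        "outcome": "outcome",
        "treatment": "treatment",
        "covariates": list(ds.covariates),
    }


# ---------------------------------------------------------------------------
# Covariate missingness policy

_MISSING_LEVEL = "(missing)"


def apply_covariate_missing_policy(ds: TrialDataset, policy: str) -> TrialDataset:
    """Render the covariate matrix complete.

    ``missing-indicator``: each covariate with any missing value gains a
    companion 0/1 indicator column ``<name>__missing``; missing continuous
    entries are filled with the covariate's observed (arm-pooled) mean and
    missing categorical entries with a dedicated ``(missing)`` level.  Row
    count is unchanged.

    ``drop-row``: rows with any missing covariate are removed.
    """
    if policy not in ("missing-indicator", "drop-row"):
        raise ValueError(f"unsupported policy: {policy!r}")
    if not ds.covariates:
        return ds
    df = ds.frame.copy()
    covs = list(ds.covariates)
    miss = df[covs].isna()
    if not miss.any().any():
        return ds

    if policy == "drop-row":
        keep = ~miss.any(axis=1)
        out = df.loc[keep].reset_index(drop=True)
        return TrialDataset(out, ds.covariates)

    new_covs = []
    for cov in covs:
        new_covs.append(cov)
        col_missing = miss[cov]
        if not col_missing.any():
            continue
        if col_missing.all():
            raise ValueError(f"covariate {cov!r} is entirely missing; cannot fill")
        ind = f"{cov}__missing"
        df[ind] = col_missing.astype(int)
        if pd.api.types.is_numeric_dtype(df[cov]):
            df[cov] = df[cov].fillna(df.loc[~col_missing, cov].mean())
        else:
            if isinstance(df[cov].dtype, pd.CategoricalDtype):
                df[cov] = df[cov].cat.add_categories([_MISSING_LEVEL])
            df[cov] = df[cov].fillna(_MISSING_LEVEL)
        new_covs.append(ind)
    return TrialDataset(df, tuple(new_covs))
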