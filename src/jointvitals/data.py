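"""Cohort data containers, CSV readers/writers and per-visit summaries.

A cohort pairs a long-format table of repeated vital-sign measurements
(respiratory rate ``RR`` in breaths/min, pulse rate ``PR`` in beats/min and
oxygen saturation ``OX``, carried under the unit label mm Hg) with one
survival record per subject: the observed time in hours since admission and
an event indicator (1 = recovered/convalescent, 0 = censored).  Baseline
covariates live on the survival table; a :class:`CovariateSpec` declares their
types and reference levels so design matrices are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

#: canonical outcome order used everywhere (K = 3)
OUTCOMES = ("RR", "PR", "OX")

#: hours between scheduled visits; the longitudinal models use
#: ``visit_index = time_h / VISIT_SPACING_H`` as their time covariate, so a
#: per-visit slope is 6x the per-hour slope.
VISIT_SPACING_H = 6.0

LONG_COLUMNS = ["subject_id", "outcome", "time_h", "value"]
SURV_COLUMNS = ["subject_id", "observed_time_h", "event"]


class CohortValidationError(ValueError):
    """A cohort table violates one of the structural invariants."""


class CohortParseError(ValueError):
    """A cohort file could not be parsed."""


@dataclass(frozen=True)
class Covariate:
    """One baseline covariate: name, kind and (for categoricals) levels.

    kind is one of ``numeric``, ``binary`` or ``categorical``.  Binary
    covariates are stored as 0/1 with ``reference`` naming the 0 level (a
    documentation convenience only).  Categorical covariates are stored as
    string labels and one-hot expanded against ``reference``.
    """

    name: str
    kind: str = "numeric"
    levels: tuple[str, ...] = ()
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "binary", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.levels:
                raise ValueError(f"categorical covariate {self.name!r} needs levels")
            ref = self.reference if self.reference is not None else self.levels[0]
            if ref not in self.levels:
                raise ValueError(
                    f"reference {ref!r} not among levels of {self.name!r}"
                )
            object.__setattr__(self, "reference", ref)
            object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def design_columns(self) -> list[str]:
        """Names of the numeric design columns this covariate expands to."""
        if self.kind == "categorical":
            return [
                f"{self.name}[{lev}]" for lev in self.levels if lev != self.reference
            ]
        return [self.name]


@dataclass(frozen=True)
class CovariateSpec:
    """Ordered declaration of the baseline covariates."""

    covariates: tuple[Covariate, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate names in spec")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.covariates]

    @property
    def design_columns(self) -> list[str]:
        cols: list[str] = []
        for c in self.covariates:
            cols.extend(c.design_columns)
        return cols

    def __getitem__(self, name: str) -> Covariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    def expand(self, covariates: pd.DataFrame) -> pd.DataFrame:
        """One-hot expand a covariate table against the declared references.

        Numeric/binary columns pass through as float; each categorical level
        other than the reference becomes an indicator column ``name[level]``.
        """
        out = {}
        for c in self.covariates:
            if c.name not in covariates.columns:
                raise CohortValidationError(f"covariate {c.name!r} missing from table")
            col = covariates[c.name]
            if c.kind == "categorical":
                vals = col.astype(str)
                unknown = set(vals.unique()) - set(c.levels)
                if unknown:
                    raise CohortValidationError(
                        f"covariate {c.name!r} has undeclared levels {sorted(unknown)}"
                    )
                for lev in c.levels:
                    if lev == c.reference:
                        continue
                    out[f"{c.name}[{lev}]"] = (vals == lev).astype(float)
            else:
                out[c.name] = col.astype(float)
        return pd.DataFrame(out, index=covariates.index)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "covariates": [
                {
                    "name": c.name,
                    "kind": c.kind,
                    **(
                        {"levels": list(c.levels), "reference": c.reference}
                        if c.kind == "categorical"
                        else ({"reference": c.reference} if c.reference else {})
                    ),
                }
                for c in self.covariates
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateSpec":
        covs = [
            Covariate(
                name=e["name"],
                kind=e.get("kind", "numeric"),
                levels=tuple(e.get("levels", ())),
                reference=e.get("reference"),
            )
            for e in d.get("covariates", [])
        ]
        return cls(tuple(covs))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "CovariateSpec":
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class CohortDataset:
    """Validated pair of longitudinal measurements and survival records.

    ``longitudinal`` has columns subject_id, outcome, time_h, value;
    ``survival`` has subject_id, observed_time_h, event plus one column per
    declared covariate.  Construction validates all invariants.
    """

    longitudinal: pd.DataFrame
    survival: pd.DataFrame
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)

    def __post_init__(self) -> None:
        self.longitudinal = self.longitudinal.reset_index(drop=True)
        self.survival = self.survival.reset_index(drop=True)
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        long, surv = self.longitudinal, self.survival
        missing = [c for c in LONG_COLUMNS if c not in long.columns]
        if missing:
            raise CohortParseError(f"longitudinal table lacks columns {missing}")
        missing = [c for c in SURV_COLUMNS if c not in surv.columns]
        if missing:
            raise CohortParseError(f"survival table lacks columns {missing}")

        bad = set(long["outcome"].unique()) - set(OUTCOMES)
        if bad:
            raise CohortParseError(f"unknown outcome codes {sorted(bad)}")
        if (long["time_h"] < 0).any():
            raise CohortValidationError("negative measurement times")
        if long.duplicated(["subject_id", "outcome", "time_h"]).any():
            raise CohortValidationError(
                "duplicate (subject, outcome, time) measurement rows"
            )

        if surv["subject_id"].duplicated().any():
            raise CohortValidationError("survival table has duplicate subjects")
        if (surv["observed_time_h"] <= 0).any():
            raise CohortValidationError("observed_time_h must be positive")
        if not surv["event"].isin([0, 1]).all():
            raise CohortValidationError("event indicator must be 0/1")

        long_subj = set(long["subject_id"])
        surv_subj = set(surv["subject_id"])
        if long_subj - surv_subj or (surv_subj - long_subj and len(long) > 0):
            only_long = sorted(map(str, long_subj - surv_subj))
            only_surv = sorted(map(str, surv_subj - long_subj))
            raise CohortValidationError(
                "subject sets differ between tables: "
                f"only in longitudinal {only_long}, only in survival {only_surv}"
            )

        if len(long) > 0:
            tmax = surv.set_index("subject_id")["observed_time_h"]
            limit = long["subject_id"].map(tmax)
            late = long["time_h"] > limit + 1e-9
            if late.any():
                subj = sorted(map(str, long.loc[late, "subject_id"].unique()))
                raise CohortValidationError(
                    f"measurements after the observed time for subjects {subj}"
                )
            present = long["outcome"].unique()
            counts = long.groupby(["subject_id", "outcome"]).size().unstack(
                fill_value=0
            )
            for k in present:
                if (counts[k] == 0).any():
                    subj = sorted(map(str, counts.index[counts[k] == 0]))
                    raise CohortValidationError(
                        f"subjects {subj} lack outcome {k} measurements"
                    )

        # covariates declared in the spec must be present
        self.covariate_spec.expand(surv)

    # -- convenience ----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.survival)

    @property
    def subject_ids(self) -> list:
        return list(self.survival["subject_id"])

    def covariate_design(self) -> pd.DataFrame:
        """Expanded (one-hot) baseline covariates, indexed like survival."""
        return self.covariate_spec.expand(self.survival)

    def equals(self, other: "CohortDataset") -> bool:
        return (
            self.longitudinal.equals(other.longitudinal)
            and self.survival.equals(other.survival)
            and self.covariate_spec == other.covariate_spec
        )


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def load_cohort(
    long_path: str | Path,
    surv_path: str | Path,
    covariate_spec: CovariateSpec | str | Path | None = None,
) -> CohortDataset:
    """Read the two cohort CSVs and return a validated :class:`CohortDataset`.

    ``covariate_spec`` may be a :class:`CovariateSpec` or a path to its
    YAML/JSON serialization; if omitted, no covariates are declared.
    """
    if covariate_spec is None:
        spec = CovariateSpec()
    elif isinstance(covariate_spec, (str, Path)):
        spec = CovariateSpec.from_file(covariate_spec)
    else:
        spec = covariate_spec

    try:
        # round_trip parsing: the default fast parser can be 1 ulp off,
        # breaking the write -> load identity
        long = pd.read_csv(long_path, float_precision="round_trip")
        surv = pd.read_csv(surv_path, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise CohortParseError(str(e)) from e
    # categorical covariate columns stay as strings; everything else numeric
    for col in ("time_h", "value"):
        if col in long.columns:
            long[col] = pd.to_numeric(long[col])
    if "outcome" in long.columns:
        long["outcome"] = long["outcome"].astype(str)
    for col in surv.columns:
        if col in ("subject_id",):
            continue
        cov = next((c for c in spec.covariates if c.name == col), None)
        if cov is not None and cov.kind == "categorical":
            surv[col] = surv[col].astype(str)
        else:
            surv[col] = pd.to_numeric(surv[col])
    if "subject_id" in long.columns:
        long["subject_id"] = long["subject_id"].astype(str)
    if "subject_id" in surv.columns:
        surv["subject_id"] = surv["subject_id"].astype(str)
    if "event" in surv.columns:
        surv["event"] = surv["event"].astype(int)
    return CohortDataset(long, surv, spec)


def write_cohort(
    dataset: CohortDataset, long_path: str | Path, surv_path: str | Path
) -> None:
    """Write the two cohort CSVs so that :func:`load_cohort` inverts exactly.

    Floats are rendered with Python's shortest round-trip repr, so a
    write/load cycle reproduces every value bit for bit.
    """
    dataset.longitudinal.to_csv(long_path, index=False)
    dataset.survival.to_csv(surv_path, index=False)


# ----------------------------------------------------------------------
# Per-visit descriptive summaries
# ----------------------------------------------------------------------

def summarize_followup(
    dataset: CohortDataset, grid_h: Sequence[float] | None = None
) -> pd.DataFrame:
    """Per-visit mean/SD/n for each outcome, plus a pooled ``overall`` row.

    ``grid_h`` is the strictly increasing sequence of scheduled visit times
    (default 0, 6, ..., 96 h).  ``n`` counts subjects still under observation
    with a measurement at that time; the SD uses denominator n-1 and is
    reported missing when n < 2.
    """
    if grid_h is None:
        grid_h = np.arange(0.0, 96.0 + VISIT_SPACING_H, VISIT_SPACING_H)
    grid = np.asarray(list(grid_h), dtype=float)
    if len(grid) and not np.all(np.diff(grid) > 0):
        raise ValueError("grid_h must be strictly increasing")

    long = dataset.longitudinal
    rows = []
    for t in grid:
        for k in OUTCOMES:
            vals = long.loc[
                (long["outcome"] == k) & np.isclose(long["time_h"], t), "value"
            ].to_numpy()
            n = len(vals)
            rows.append(
                {
                    "time_h": t,
                    "outcome": k,
                    "mean": float(np.mean(vals)) if n else np.nan,
                    "sd": float(np.std(vals, ddof=1)) if n >= 2 else np.nan,
                    "n": n,
                }
            )
    for k in OUTCOMES:
        vals = long.loc[long["outcome"] == k, "value"].to_numpy()
        n = len(vals)
        rows.append(
            {
                "time_h": np.nan,
                "outcome": k,
                "mean": float(np.mean(vals)) if n else np.nan,
                "sd": float(np.std(vals, ddof=1)) if n >= 2 else np.nan,
                "n": n,
            }
        )
    out = pd.DataFrame(rows)
    out["visit"] = np.where(
        out["time_h"].notna(), out["time_h"] / VISIT_SPACING_H, np.nan
    )
    return out[["time_h", "visit", "outcome", "mean", "sd", "n"]]
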