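"""Domain types, validation and file I/O for multi-cohort subject-level data.

The package operates on individual-participant data (IPD): one row per
subject, with a cohort label, a binary diagnosis indicator (0 = control,
1 = patient), demographic covariates (age in years, sex coded 0/1,
intracranial volume in mm^3) and one or more continuous region-of-interest
(ROI) outcome columns — cortical thickness in mm or surface area in mm^2.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .evaluation import ComparisonReport

MEASURE_TYPES = ("thickness", "surface_area")

#: canonical subject-level column names, in fixed order
BASE_COLUMNS = ("cohort", "dx", "age", "sex", "icv")

#: the only missing-value markers recognised in CSV/TSV input
NA_VALUES = ("NA", "")


class SchemaError(ValueError):
    """A mandatory column is absent or the schema mapping is inconsistent."""


class ValidationError(ValueError):
    """Cell-level content violates the data contract (e.g. non-binary dx)."""


class NoEstimableCohortsError(RuntimeError):
    """No cohort is eligible for the requested analysis."""


@dataclass(frozen=True)
class CovariateSpec:
    """Covariate policy tied to the type of brain measure.

    Thickness models adjust for age and sex; surface-area models additionally
    adjust for intracranial volume (head size).  ``include_cohort_fixed``
    requests cohort dummy variables and is meaningful only for the pooled
    one-stage linear regression.  ``covariates_override`` replaces the
    measure-type policy with an explicit covariate list (e.g. ``()`` for an
    unadjusted two-group comparison).
    """

    measure_type: str
    include_cohort_fixed: bool = False
    covariates_override: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.measure_type not in MEASURE_TYPES:
            raise ValueError(f"unknown measure_type {self.measure_type!r}")

    @property
    def covariates(self) -> tuple[str, ...]:
        if self.covariates_override is not None:
            return tuple(self.covariates_override)
        if self.measure_type == "surface_area":
            return ("age", "sex", "icv")
        return ("age", "sex")

    @classmethod
    def for_measure(cls, measure_type: str, **kw) -> "CovariateSpec":
        return cls(measure_type=measure_type, **kw)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: cohort membership, diagnosis, covariates, ROI outcomes."""

    cohort_id: str
    diagnosis: int
    age: float
    sex: int
    icv: float | None
    outcomes: Mapping[str, float | None]

    def __post_init__(self) -> None:
        if self.diagnosis not in (0, 1):
            raise ValidationError(f"diagnosis must be 0/1, got {self.diagnosis!r}")
        if self.sex not in (0, 1):
            raise ValidationError(f"sex must be 0/1, got {self.sex!r}")
        if self.age < 0:
            raise ValidationError(f"age must be nonnegative, got {self.age!r}")


@dataclass
class IPDDataset:
    """Subject-level table plus the registry of ROI outcome columns.

    ``df`` holds the canonical columns ``cohort, dx, age, sex, icv`` followed
    by one column per registered ROI.  ``age_split`` partitions subjects into
    pediatric (age < split) and adult (age >= split) groups; the default of 18
    years reflects the usual inclusion cut-off of multi-site samples.
    """

    df: pd.DataFrame
    roi_registry: list[tuple[str, str]]
    age_split: float = 18.0

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def rois(self) -> list[str]:
        return [name for name, _ in self.roi_registry]

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.df["cohort"].unique())

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    def measure_type(self, roi: str) -> str:
        for name, mtype in self.roi_registry:
            if name == roi:
                return mtype
        raise KeyError(f"ROI {roi!r} not in registry")

    def validate(self) -> None:
        missing = [c for c in BASE_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing mandatory columns: {missing}")
        if self.df.empty:
            raise ValidationError("dataset has no rows")
        if (self.df["cohort"].astype(str).str.len() == 0).any():
            raise ValidationError("empty cohort labels present")
        bad_dx = set(self.df["dx"].unique()) - {0, 1}
        if bad_dx:
            raise ValidationError(f"non-binary diagnosis values: {sorted(bad_dx)}")
        bad_sex = set(self.df["sex"].dropna().unique()) - {0, 1}
        if bad_sex:
            raise ValidationError(f"non-binary sex values: {sorted(bad_sex)}")
        if (self.df["age"] < 0).any():
            raise ValidationError("negative ages present")
        seen = [n for n, _ in self.roi_registry]
        if len(seen) != len(set(seen)):
            raise ValidationError("duplicate ROI names in registry")
        for name, mtype in self.roi_registry:
            if name not in self.df.columns:
                raise SchemaError(f"registered ROI column {name!r} absent")
            if mtype not in MEASURE_TYPES:
                raise ValidationError(f"unknown measure type {mtype!r} for {name!r}")

    # -- age grouping ------------------------------------------------------
    def group_mask(self, group: str) -> pd.Series:
        if group == "all":
            return pd.Series(True, index=self.df.index)
        if group == "pediatric":
            return self.df["age"] < self.age_split
        if group == "adult":
            return self.df["age"] >= self.age_split
        raise ValueError(f"unknown group {group!r}")

    def subset(self, group: str) -> "IPDDataset":
        return IPDDataset(
            self.df.loc[self.group_mask(group)].copy(),
            list(self.roi_registry),
            self.age_split,
        )

    def records(self) -> Iterator[SubjectRecord]:
        rois = self.rois
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            icv = d["icv"]
            yield SubjectRecord(
                cohort_id=str(d["cohort"]),
                diagnosis=int(d["dx"]),
                age=float(d["age"]),
                sex=int(d["sex"]),
                icv=None if pd.isna(icv) else float(icv),
                outcomes={r: (None if pd.isna(d[r]) else float(d[r])) for r in rois},
            )

    def equals(self, other: "IPDDataset") -> bool:
        if self.roi_registry != other.roi_registry:
            return False
        if self.age_split != other.age_split:
            return False
        cols = list(BASE_COLUMNS) + self.rois
        a, b = self.df[cols], other.df[cols]
        if len(a) != len(b):
            return False
        for c in cols:
            x, y = a[c].to_numpy(), b[c].to_numpy()
            if c in ("cohort",):
                if not (x.astype(str) == y.astype(str)).all():
                    return False
            else:
                x = x.astype(float)
                y = y.astype(float)
                ok = (x == y) | (np.isnan(x) & np.isnan(y))
                if not ok.all():
                    return False
        return True


@dataclass
class FitResult:
    """Unified record of one fitted model's diagnosis effect.

    ``d`` is Cohen's d, signed so that negative values mean lower outcome in
    patients; ``beta_dx`` is the raw diagnosis coefficient in outcome units.
    ``loglik``/``bic`` are absent for the two-stage pooled estimate, whose
    fit criterion is not comparable with the subject-level models.
    """

    method: str
    d: float | None = None
    se_d: float | None = None
    ci95: tuple[float, float] | None = None
    beta_dx: float | None = None
    t: float | None = None
    df: float | None = None
    p: float | None = None
    loglik: float | None = None
    bic: float | None = None
    tau2: float | None = None
    converged: bool = True
    n_obs: int | None = None
    n1: int | None = None
    n2: int | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if self.se_d is not None and not self.se_d > 0:
                raise ValueError("se_d must be positive for a converged fit")
            if self.ci95 is not None and self.d is not None:
                lo, hi = self.ci95
                if not (lo <= self.d <= hi):
                    raise ValueError("d must lie inside its 95% CI")
        if self.tau2 is not None and self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

DEFAULT_SCHEMA: dict[str, str] = {c: c for c in BASE_COLUMNS}


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_ipd(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    roi_registry: Sequence[tuple[str, str]] | None = None,
    age_split: float = 18.0,
    sex_map: Mapping[str, int] | None = None,
) -> IPDDataset:
    """Read a subject-level CSV/TSV into a validated :class:`IPDDataset`.

    Parameters
    ----------
    schema
        Mapping from canonical names (``cohort, dx, age, sex, icv``) to the
        file's column names.  Canonical names are assumed where omitted.
    roi_registry
        ``(name, measure_type)`` pairs.  If omitted, every non-base column is
        registered as a thickness measure.
    sex_map
        Optional explicit recoding of sex labels to 0/1 (e.g. ``{"F": 0,
        "M": 1}``).  No inference beyond this dictionary is performed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    raw = pd.read_csv(
        path,
        sep=_sep_for(path),
        na_values=list(NA_VALUES),
        keep_default_na=False,
        float_precision="round_trip",
    )
    missing = [schema[c] for c in BASE_COLUMNS if schema[c] not in raw.columns]
    if missing:
        raise SchemaError(f"file {path} lacks mandatory column(s): {missing}")
    df = raw.rename(columns={schema[c]: c for c in BASE_COLUMNS})

    if sex_map:
        df["sex"] = df["sex"].map(lambda v: sex_map.get(v, v))

    # row-indexed rejection of unparseable cohort / diagnosis values
    bad_rows: list[tuple[int, str]] = []
    dx_num = pd.to_numeric(df["dx"], errors="coerce")
    for i in df.index:
        if pd.isna(df.at[i, "cohort"]) or str(df.at[i, "cohort"]) == "":
            bad_rows.append((int(i), f"unparseable cohort {df.at[i, 'cohort']!r}"))
        v = dx_num[i]
        if pd.isna(v) or v not in (0, 1):
            bad_rows.append((int(i), f"non-binary diagnosis value {df.at[i, 'dx']!r}"))
    if bad_rows:
        msgs = "; ".join(f"row {i}: {m}" for i, m in bad_rows)
        raise ValidationError(f"invalid rows in {path}: {msgs}")
    df["dx"] = dx_num.astype(int)
    for col in ("age", "sex", "icv"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    bad_sex = set(df["sex"].dropna().unique()) - {0, 1}
    if bad_sex:
        raise ValidationError(
            f"sex values {sorted(bad_sex)} not 0/1; supply sex_map to recode"
        )
    df["sex"] = df["sex"].astype(int)

    if roi_registry is None:
        roi_registry = [
            (c, "thickness") for c in df.columns if c not in BASE_COLUMNS
        ]
    roi_cols = [name for name, _ in roi_registry]
    for c in roi_cols:
        df[c] = pd.to_numeric(df[c], errors="raise")
    df = df[list(BASE_COLUMNS) + roi_cols]
    return IPDDataset(df, list(roi_registry), age_split=age_split)


def write_ipd(ds: IPDDataset, path: str | Path) -> None:
    """Write a dataset to CSV/TSV (missing cells as empty strings)."""
    path = Path(path)
    cols = list(BASE_COLUMNS) + ds.rois
    ds.df[cols].to_csv(path, sep=_sep_for(path), index=False, na_rep="")


# ---------------------------------------------------------------------------
# analysis-readiness
# ---------------------------------------------------------------------------


@dataclass
class AnalysisSubset:
    """Complete-case rows for one ROI plus eligibility bookkeeping.

    ``two_stage_eligible`` lists cohorts usable for per-cohort estimation
    (both groups present, residual df >= 1 after covariates, n >= floor);
    every cohort with at least one complete-case row stays in ``df`` and is
    usable by the pooled one-stage models.
    """

    df: pd.DataFrame
    roi: str
    spec: CovariateSpec
    cohort_counts: pd.DataFrame  # index cohort, columns n1 (patients), n2 (controls)
    two_stage_eligible: list[str]
    exclusion_log: list[dict]

    @property
    def n1(self) -> int:
        return int((self.df["dx"] == 1).sum())

    @property
    def n2(self) -> int:
        return int((self.df["dx"] == 0).sum())


def validate_for_analysis(
    ds: IPDDataset,
    roi: str,
    spec: CovariateSpec,
    min_cohort_n: int = 10,
) -> AnalysisSubset:
    """Complete-case subset for one ROI with a per-row exclusion log.

    Rows missing the ROI outcome or any required covariate are dropped and
    logged.  Cohort two-stage eligibility requires both diagnostic groups,
    at least one residual degree of freedom after the covariates, and a
    total complete-case n of at least ``min_cohort_n``.  One-stage analyses
    keep every cohort with >= 1 complete row.
    """
    if roi not in ds.rois:
        raise KeyError(f"ROI {roi!r} not in registry")
    needed = [roi, *spec.covariates]
    log: list[dict] = []
    keep = pd.Series(True, index=ds.df.index)
    for col in needed:
        miss = ds.df[col].isna() & keep
        for i in ds.df.index[miss]:
            log.append(
                {
                    "kind": "row",
                    "row": int(i),
                    "cohort": str(ds.df.at[i, "cohort"]),
                    "reason": f"missing {col}",
                }
            )
        keep &= ~miss
    sub = ds.df.loc[keep, [*BASE_COLUMNS, roi]].copy()
    if sub.empty:
        raise NoEstimableCohortsError(f"no complete-case rows for ROI {roi!r}")

    counts = (
        sub.assign(is_pat=sub["dx"] == 1)
        .groupby("cohort")["is_pat"]
        .agg(n1="sum", n=len)
        .astype(int)
    )
    counts["n2"] = counts["n"] - counts["n1"]
    counts = counts[["n1", "n2"]].sort_index()

    p = 2 + len(spec.covariates)  # intercept + dx + covariates
    eligible = []
    for cohort, row in counts.iterrows():
        n1, n2 = int(row["n1"]), int(row["n2"])
        n = n1 + n2
        reasons = []
        if n1 < 1 or n2 < 1:
            reasons.append("one diagnostic group absent")
        if n - p < 1:
            reasons.append("residual df < 1 after covariates")
        if n < min_cohort_n:
            reasons.append(f"n = {n} < min_cohort_n = {min_cohort_n}")
        if reasons:
            log.append(
                {
                    "kind": "cohort",
                    "cohort": str(cohort),
                    "reason": "two-stage ineligible: " + "; ".join(reasons),
                }
            )
        else:
            eligible.append(str(cohort))
    return AnalysisSubset(
        df=sub.reset_index(drop=True),
        roi=roi,
        spec=spec,
        cohort_counts=counts,
        two_stage_eligible=eligible,
        exclusion_log=log,
    )


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "outcome",
    "group",
    "method",
    "d",
    "se",
    "ci_low",
    "ci_high",
    "bic",
    "p",
    "converged",
    "significant",
)


def _report_frame(report: "ComparisonReport") -> pd.DataFrame:
    rows = []
    for row in report.rows:
        r = row.result
        rows.append(
            {
                "outcome": row.outcome,
                "group": row.group,
                "method": r.method,
                "d": r.d,
                "se": r.se_d,
                "ci_low": None if r.ci95 is None else r.ci95[0],
                "ci_high": None if r.ci95 is None else r.ci95[1],
                "bic": r.bic,
                "p": r.p,
                "converged": r.converged,
                "significant": row.significant,
            }
        )
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def write_report(report: "ComparisonReport", path: str | Path, format: str = "tsv") -> None:
    """Emit one row per (outcome, method); numbers at 4 decimals in TSV.

    The BIC cell of the two-stage pooled row is left empty: its restricted
    likelihood is a study-level quantity not comparable with subject-level
    model fits.
    """
    if not report.rows:
        raise ValueError("empty report")
    frame = _report_frame(report)
    path = Path(path)
    if format == "tsv":
        out = frame.copy()
        for c in ("d", "se", "ci_low", "ci_high", "bic", "p"):
            out[c] = out[c].map(lambda v: "" if v is None or pd.isna(v) else f"{v:.4f}")
        out["converged"] = out["converged"].astype(int)
        out["significant"] = out["significant"].map(
            lambda v: "" if v is None else int(v)
        )
        out.to_csv(path, sep="\t", index=False)
    elif format == "json":
        payload = {
            "alpha": report.alpha,
            "rows": json.loads(frame.to_json(orient="records")),
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_report(path: str | Path) -> "ComparisonReport":
    """Load a JSON report written by :func:`write_report`."""
    from .evaluation import ComparisonReport, ReportRow

    payload = json.loads(Path(path).read_text())
    rows = []
    for rec in payload["rows"]:
        ci = None
        if rec["ci_low"] is not None:
            ci = (rec["ci_low"], rec["ci_high"])
        rows.append(
            ReportRow(
                outcome=rec["outcome"],
                group=rec["group"],
                result=FitResult(
                    method=rec["method"],
                    d=rec["d"],
                    se_d=rec["se"],
                    ci95=ci,
                    bic=rec["bic"],
                    p=rec["p"],
                    converged=bool(rec["converged"]),
                ),
                significant=rec["significant"],
            )
        )
    return ComparisonReport(rows=rows, alpha=payload.get("alpha"))
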