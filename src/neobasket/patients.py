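"""Individual-patient data model, fixture I/O and endpoint derivation.

The packaged fixture (``data/patients.csv``) transcribes the published
individual-patient table of the two-cohort neoadjuvant trial: 14 patients
with T4 dMMR/MSI colon cancer and 8 with dMMR/MSI rectal cancer, each
carrying regimen, RAS/RAF status, surgery, pathological stage (ypTN), tumor
regression grade (TRG), and follow-up.  Pathological complete response
(pCR) is TRG 0, equivalently ypT0N0.

Analysis sets follow the trial's definitions: the full analysis set (FAS)
is everyone enrolled; the per-protocol set (PPS) is the operated,
protocol-compliant patients; the safety set (SS) is everyone who received
at least one dose of study drug (here: all).  Non-operated patients count
in FAS pCR denominators but can never contribute to a numerator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .design import CohortData
from .survival import SurvivalInput

__all__ = [
    "PatientRecord",
    "AnalysisSets",
    "EndpointCounts",
    "ValidationIssue",
    "PatientValidationError",
    "COHORTS",
    "fixture_path",
    "load_patients",
    "write_patients",
    "assign_analysis_sets",
    "derive_endpoints",
    "stage1_counts",
    "efs_input",
    "os_input",
    "dfs_input",
    "tts_values",
    "followup_values",
]

COHORTS = ("colon", "rectum")
_SEXES = frozenset({"male", "female"})
_TRI = frozenset({"wild", "mutant", "unknown"})
_LYNCH = frozenset({"yes", "no", "unknown"})
_CLINICAL_T = frozenset({"T1", "T2", "T3", "T4a", "T4b"})
_YP_T = frozenset({"ypT0", "ypT1", "ypT2", "ypT3", "ypT4a"})
_YP_N = frozenset({"ypN0", "ypN1", "ypN1a", "ypN1b", "ypN2"})
_REGIMEN_PARTS = frozenset({"TORI", "IRI", "BEV"})


@dataclass(frozen=True)
class PatientRecord:
    id: str
    cohort: str
    age: int
    sex: str
    ecog: int
    lynch: str
    clinical_t: str
    clinical_n_positive: bool
    site: str
    regimen: frozenset[str]
    kras: str
    nras: str
    braf: str
    surgery: bool
    cycles_preop: int
    cycles_postop: int
    tts_months: float | None
    yp_t: str | None
    yp_n: str | None
    trg: int | None
    r0: bool | None
    ccr: bool
    watch_and_wait: bool
    efs_months: float
    efs_event: bool
    dfs_months: float | None
    dfs_event: bool | None
    os_months: float
    os_event: bool
    followup_months: float

    @property
    def pcr(self) -> bool:
        """Pathological complete response: TRG 0 in the resected specimen."""
        return self.trg == 0

    def validation_issues(self) -> list["ValidationIssue"]:
        issues: list[ValidationIssue] = []

        def bad(field: str, message: str) -> None:
            issues.append(ValidationIssue(self.id, field, message))

        if self.cohort not in COHORTS:
            bad("cohort", f"unknown cohort {self.cohort!r}")
        if self.sex not in _SEXES:
            bad("sex", f"unknown sex {self.sex!r}")
        if not 0 <= self.ecog <= 1:
            bad("ecog", f"ECOG {self.ecog} outside 0-1")
        if self.lynch not in _LYNCH:
            bad("lynch", f"unknown Lynch status {self.lynch!r}")
        if self.clinical_t not in _CLINICAL_T:
            bad("clinical_t", f"unknown clinical T stage {self.clinical_t!r}")
        for field in ("kras", "nras", "braf"):
            if getattr(self, field) not in _TRI:
                bad(field, f"unknown mutation status {getattr(self, field)!r}")
        if not self.regimen or "TORI" not in self.regimen or not self.regimen <= _REGIMEN_PARTS:
            bad("regimen", f"regimen {sorted(self.regimen)} not a TORI-containing subset of TORI/IRI/BEV")
        if self.cycles_preop < 1:
            bad("cycles_preop", "at least one pre-operative cycle required")
        if self.cycles_postop < 0:
            bad("cycles_postop", "negative post-operative cycle count")

        if self.cohort == "colon" and self.clinical_t not in {"T4a", "T4b"}:
            bad("clinical_t", "colon cohort enrolled clinical T4 only")
        if self.cohort == "rectum" and self.clinical_t not in {"T1", "T2", "T3"}:
            bad("clinical_t", "rectum cohort enrolled clinical T1-T3 only")

        if self.surgery:
            if self.tts_months is None or self.tts_months <= 0:
                bad("tts_months", "operated patient needs a positive time to surgery")
            if self.trg is None or not 0 <= self.trg <= 3:
                bad("trg", "operated patient needs a TRG in 0-3")
            if self.yp_t not in _YP_T:
                bad("yp_t", f"unknown ypT stage {self.yp_t!r}")
            if self.yp_n not in _YP_N:
                bad("yp_n", f"unknown ypN stage {self.yp_n!r}")
            if self.trg is not None and self.yp_t and self.yp_n:
                complete = self.yp_t == "ypT0" and self.yp_n == "ypN0"
                if (self.trg == 0) != complete:
                    bad("trg", f"TRG {self.trg} inconsistent with {self.yp_t}{self.yp_n} (TRG 0 <=> ypT0N0)")
        else:
            for field in ("trg", "yp_t", "yp_n", "tts_months", "dfs_months"):
                if getattr(self, field) is not None:
                    bad(field, "must be absent without surgery")

        if self.watch_and_wait and not (self.ccr and not self.surgery):
            bad("watch_and_wait", "watch-and-wait requires clinical CR and no surgery")

        for field in ("efs_months", "os_months", "followup_months"):
            if getattr(self, field) <= 0:
                bad(field, "duration must be positive")
        if self.dfs_months is not None and self.dfs_months <= 0:
            bad("dfs_months", "duration must be positive")
        return issues


@dataclass(frozen=True)
class ValidationIssue:
    patient_id: str
    field: str
    message: str
    row: int | None = None

    def __str__(self) -> str:
        where = f"row {self.row}, " if self.row is not None else ""
        return f"{where}patient {self.patient_id!r}, field {self.field!r}: {self.message}"


class PatientValidationError(ValueError):
    """Raised when loading or validating patient records fails; carries all issues."""

    def __init__(self, issues: Sequence[ValidationIssue]):
        self.issues = list(issues)
        super().__init__("; ".join(str(i) for i in self.issues))


def fixture_path() -> Path:
    """Path of the packaged individual-patient-data fixture."""
    return Path(str(resources.files("neobasket").joinpath("data/patients.csv")))


_BOOL = {"true": True, "false": False}


def _parse_cell(name: str, raw: str, row: int, pid: str, issues: list[ValidationIssue]):
    raw = raw.strip()
    optional = name in {"tts_months", "yp_t", "yp_n", "trg", "r0", "dfs_months", "dfs_event"}
    if raw == "NA":
        if optional:
            return None
        issues.append(ValidationIssue(pid, name, "NA not allowed here", row))
        return None
    try:
        if name in {"age", "ecog", "cycles_preop", "cycles_postop", "trg"}:
            return int(raw)
        if name.endswith("_months"):
            return float(raw)
        if name in {"clinical_n_positive", "surgery", "r0", "ccr", "watch_and_wait",
                    "efs_event", "dfs_event", "os_event"}:
            return _BOOL[raw.lower()]
        if name == "regimen":
            return frozenset(raw.split("+"))
        return raw
    except (ValueError, KeyError):
        issues.append(ValidationIssue(pid, name, f"unparseable value {raw!r}", row))
        return None


_COLUMNS = [f.name for f in fields(PatientRecord)]


def load_patients(path: str | Path | None = None) -> list[PatientRecord]:
    """Load and validate patient records from a delimited-text file.

    ``path=None`` loads the packaged fixture.  All validation problems are
    collected and raised together as :class:`PatientValidationError`, each
    naming the offending row, patient id and field.
    """
    path = fixture_path() if path is None else Path(path)
    frame = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise PatientValidationError(
            [ValidationIssue("<header>", c, "missing column") for c in missing]
        )
    records: list[PatientRecord] = []
    issues: list[ValidationIssue] = []
    seen: set[str] = set()
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        data = dict(zip(frame.columns, row))
        pid = data["id"].strip()
        row_issues: list[ValidationIssue] = []
        parsed = {c: _parse_cell(c, data[c], idx, pid, row_issues) for c in _COLUMNS}
        if row_issues:
            issues.extend(row_issues)
            continue
        record = PatientRecord(**parsed)
        if pid in seen:
            issues.append(ValidationIssue(pid, "id", "duplicate patient id", idx))
        seen.add(pid)
        issues.extend(replace(i, row=idx) for i in record.validation_issues())
        records.append(record)
    if issues:
        raise PatientValidationError(issues)
    return records


def _format_cell(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, frozenset):
        return "+".join(p for p in ("TORI", "IRI", "BEV") if p in value)
    if isinstance(value, float):
        return repr(round(value, 6))
    return str(value)


def write_patients(records: Iterable[PatientRecord], path) -> None:
    """Write records in the fixture dialect (round-trips through load_patients).

    ``path`` may be a filesystem path or any writable text buffer.
    """
    rows = [{c: _format_cell(getattr(r, c)) for c in _COLUMNS} for r in records]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


@dataclass(frozen=True)
class AnalysisSets:
    """Per-cohort FAS / PPS / SS membership (patient-id sets)."""

    fas: Mapping[str, frozenset[str]]
    pps: Mapping[str, frozenset[str]]
    ss: Mapping[str, frozenset[str]]

    def members(self, cohort: str, analysis_set: str) -> frozenset[str]:
        try:
            per_cohort = getattr(self, analysis_set.lower())
        except AttributeError:
            raise ValueError(f"unknown analysis set {analysis_set!r}") from None
        if cohort not in per_cohort:
            raise ValueError(f"unknown cohort {cohort!r}")
        return per_cohort[cohort]


def assign_analysis_sets(patients: Sequence[PatientRecord]) -> AnalysisSets:
    """FAS = all enrolled; PPS = operated with perioperative treatment completed;
    SS = received at least one dose (all enrolled patients were treated)."""
    fas = {c: frozenset(p.id for p in patients if p.cohort == c) for c in COHORTS}
    pps = {c: frozenset(p.id for p in patients if p.cohort == c and p.surgery) for c in COHORTS}
    return AnalysisSets(fas=fas, pps=pps, ss=dict(fas))


@dataclass(frozen=True)
class EndpointCounts:
    cohort: str
    analysis_set: str
    pcr_x: int
    pcr_n: int
    trg_counts: Mapping[int, int]
    r0_x: int
    r0_n: int
    surgery_x: int
    kras_mutant_x: int
    kras_known_n: int


def _cohort_filter(patients: Sequence[PatientRecord], cohort: str) -> list[PatientRecord]:
    if cohort == "pooled":
        return list(patients)
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    return [p for p in patients if p.cohort == cohort]


def derive_endpoints(
    patients: Sequence[PatientRecord],
    sets: AnalysisSets,
    cohort: str,
    analysis_set: str = "fas",
) -> EndpointCounts:
    """Pathological/descriptive endpoint counts for one cohort and analysis set.

    ``cohort="pooled"`` pools both cohorts (used for the mutation-rate
    summary).  pCR denominators are the full set size, so non-operated
    watch-and-wait patients count against the rate.
    """
    pool = _cohort_filter(patients, cohort)
    if cohort == "pooled":
        ids = frozenset().union(*(sets.members(c, analysis_set) for c in COHORTS))
    else:
        ids = sets.members(cohort, analysis_set)
    members = [p for p in pool if p.id in ids]
    operated = [p for p in members if p.surgery]
    trg_counts = {g: sum(1 for p in operated if p.trg == g) for g in range(4)}
    return EndpointCounts(
        cohort=cohort,
        analysis_set=analysis_set,
        pcr_x=sum(1 for p in members if p.pcr),
        pcr_n=len(members),
        trg_counts=trg_counts,
        r0_x=sum(1 for p in operated if p.r0),
        r0_n=len(members),
        surgery_x=len(operated),
        kras_mutant_x=sum(1 for p in members if p.kras == "mutant"),
        kras_known_n=sum(1 for p in members if p.kras != "unknown"),
    )


def stage1_counts(
    patients: Sequence[PatientRecord], sets: AnalysisSets
) -> dict[str, CohortData]:
    """Observed (pCR responders, FAS size) per cohort, feeding the design layer."""
    out: dict[str, CohortData] = {}
    for cohort in COHORTS:
        counts = derive_endpoints(patients, sets, cohort, "fas")
        out[cohort] = CohortData(x=counts.pcr_x, n=counts.pcr_n)
    return out


def _survival_members(
    patients: Sequence[PatientRecord], cohort: str, analysis_set: str
) -> list[PatientRecord]:
    sets = assign_analysis_sets(patients)
    ids = sets.members(cohort, analysis_set)
    return [p for p in patients if p.id in ids]


def efs_input(
    patients: Sequence[PatientRecord],
    cohort: str,
    analysis_set: str = "fas",
    censor_floor: float | None = None,
) -> SurvivalInput:
    """Event-free survival input (time from study treatment to progression,
    recurrence or death).

    ``censor_floor`` reconstructs the published analysis cutoff: the trial's
    survival analysis was run at a later cutoff than the snapshot the
    per-patient table reflects (its stated median follow-up exceeds every
    per-patient value), so event-free patients are known to have been at
    risk at least that long.  When set, censoring times of event-free
    patients are floored at that many months; event times are untouched.
    """
    members = _survival_members(patients, cohort, analysis_set)
    times, events = [], []
    for p in members:
        t = p.efs_months
        if censor_floor is not None and not p.efs_event:
            t = max(t, censor_floor)
        times.append(t)
        events.append(p.efs_event)
    return SurvivalInput(times=times, events=events)


def os_input(
    patients: Sequence[PatientRecord], cohort: str, analysis_set: str = "fas"
) -> SurvivalInput:
    members = _survival_members(patients, cohort, analysis_set)
    return SurvivalInput(
        times=[p.os_months for p in members], events=[p.os_event for p in members]
    )


def dfs_input(
    patients: Sequence[PatientRecord], cohort: str, analysis_set: str = "pps"
) -> SurvivalInput:
    """Disease-free survival (from surgery) over operated patients."""
    members = [p for p in _survival_members(patients, cohort, analysis_set) if p.surgery]
    if any(p.dfs_months is None or p.dfs_event is None for p in members):
        raise PatientValidationError(
            [ValidationIssue(p.id, "dfs_months", "missing DFS for operated patient")
             for p in members if p.dfs_months is None or p.dfs_event is None]
        )
    return SurvivalInput(
        times=[float(p.dfs_months) for p in members],
        events=[bool(p.dfs_event) for p in members],
    )


def tts_values(patients: Sequence[PatientRecord], cohort: str) -> list[float]:
    """Times from first study treatment to surgery, operated patients only."""
    vals = [p.tts_months for p in _cohort_filter(patients, cohort) if p.surgery]
    assert all(v is not None and math.isfinite(v) for v in vals)
    return [float(v) for v in vals]  # type: ignore[arg-type]


def followup_values(patients: Sequence[PatientRecord], cohort: str = "pooled") -> list[float]:
    return [p.followup_months for p in _cohort_filter(patients, cohort)]
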