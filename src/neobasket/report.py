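"""Recomputed efficacy table and recompute-vs-printed discordance audit.

Every rate row (pCR, ORR, R0, TRG grades) is an exact Clopper-Pearson
cell; survival rows are Kaplan-Meier estimates with linear-scale Greenwood
intervals.  ORR numerators are *not* derivable from the patient table (the
per-patient radiological best response was never published), so they must
be supplied explicitly through the printed-counts configuration -- the
report never invents them.

Where the recomputed cell disagrees with the published string the cell is
flagged and both values are carried; nothing is silently overwritten.
Three published exact-interval cells (6/8, the 11/14 lower bound, the 6/6
lower bound) and the 5/6 interval do not match the exact method the
methods section states; the audit reports them as discordant.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .intervals import RateCI, clopper_pearson, round_half_up
from .patients import (
    PatientRecord,
    assign_analysis_sets,
    derive_endpoints,
    dfs_input,
    efs_input,
    os_input,
)
from .survival import km_fit, survival_at

__all__ = ["Table2Cell", "Table2Report", "build_table2", "render_report", "printed_config_path"]

# Published survival analysis ran at a later data cutoff than the patient
# table snapshot; event-free patients were at risk at least this long.
PUBLISHED_CUTOFF_MONTHS = 12.0


def printed_config_path() -> Path:
    return Path(str(resources.files("neobasket").joinpath("data/table2_printed.yaml")))


@dataclass(frozen=True)
class Table2Cell:
    endpoint: str
    cohort: str
    analysis_set: str
    kind: str  # "rate" | "survival"
    x: int | None
    n: int | None
    point: float
    lower: float | None
    upper: float | None
    formatted: str
    printed: str | None
    discordant: bool | None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Table2Report:
    cells: tuple[Table2Cell, ...]

    def cell(self, cohort: str, analysis_set: str, endpoint: str) -> Table2Cell:
        for c in self.cells:
            if (c.cohort, c.analysis_set, c.endpoint) == (cohort, analysis_set, endpoint):
                return c
        raise KeyError((cohort, analysis_set, endpoint))

    @property
    def discordant_cells(self) -> tuple[Table2Cell, ...]:
        return tuple(c for c in self.cells if c.discordant)


def _rate_cell(
    endpoint: str, cohort: str, aset: str, x: int, n: int, printed: str | None
) -> Table2Cell:
    ci = clopper_pearson(x, n)
    formatted = ci.as_percent_string()
    discordant = None
    if printed is not None:
        discordant = _normalize(printed) != _normalize(formatted)
    return Table2Cell(
        endpoint=endpoint, cohort=cohort, analysis_set=aset, kind="rate",
        x=x, n=n, point=ci.point, lower=ci.lower, upper=ci.upper,
        formatted=formatted, printed=printed, discordant=discordant,
    )


def _normalize(cell: str) -> str:
    return cell.replace("–", "-").replace(" ", "")


_SURV_RE = re.compile(r"^(\d+)%(?:\s*\((\d+)%-(\d+)%\))?$")


def _survival_cell(
    endpoint: str, cohort: str, aset: str, s: float, lo: float, hi: float,
    printed: str | None,
) -> Table2Cell:
    pct = round_half_up(100.0 * s)
    if s >= 1.0 - 1e-12:
        formatted = "100%"
    else:
        formatted = f"{pct:.0f}% ({round_half_up(100 * lo):.0f}%-{round_half_up(100 * hi):.0f}%)"
    discordant = None
    if printed is not None:
        m = _SURV_RE.match(_normalize(printed))
        if m:
            # the published rounding rule is unknown: allow 1 percentage point
            ok = abs(float(m.group(1)) - pct) <= 1.0
            if m.group(2) is not None:
                ok = ok and abs(float(m.group(2)) - round_half_up(100 * lo)) <= 1.0
                ok = ok and abs(float(m.group(3)) - round_half_up(100 * hi)) <= 1.0
            discordant = not ok
        else:
            discordant = True
    return Table2Cell(
        endpoint=endpoint, cohort=cohort, analysis_set=aset, kind="survival",
        x=None, n=None, point=s, lower=lo, upper=hi,
        formatted=formatted, printed=printed, discordant=discordant,
    )


def build_table2(
    patients: Sequence[PatientRecord],
    printed_config: Mapping | str | Path | None = None,
) -> Table2Report:
    """Recompute the efficacy table from patient records.

    ``printed_config`` supplies the ORR counts (mandatory for ORR rows) and
    optionally the published cell strings for the discordance audit; by
    default the packaged transcription is used.
    """
    if printed_config is None:
        printed_config = printed_config_path()
    if isinstance(printed_config, (str, Path)):
        printed_config = yaml.safe_load(Path(printed_config).read_text())
    orr_counts = printed_config.get("orr_counts", {})
    printed = printed_config.get("printed", {})
    sets = assign_analysis_sets(patients)
    cells: list[Table2Cell] = []
    for cohort in ("colon", "rectum"):
        for aset in ("fas", "pps"):
            said = printed.get(cohort, {}).get(aset, {})
            counts = derive_endpoints(patients, sets, cohort, aset)
            cells.append(_rate_cell("pcr", cohort, aset, counts.pcr_x, counts.pcr_n, said.get("pcr")))
            orr = orr_counts.get(cohort, {}).get(aset)
            if orr is None:
                raise ValueError(
                    f"printed ORR counts required for {cohort}/{aset}: per-patient "
                    "radiological response is not in the data"
                )
            cells.append(_rate_cell("orr", cohort, aset, orr["x"], orr["n"], said.get("orr")))
            cells.append(_rate_cell("r0", cohort, aset, counts.r0_x, counts.r0_n, said.get("r0")))
            for grade in range(4):
                cells.append(
                    _rate_cell(
                        f"trg{grade}", cohort, aset,
                        counts.trg_counts[grade], counts.pcr_n, said.get(f"trg{grade}"),
                    )
                )
            efs_curve = km_fit(
                efs_input(patients, cohort, aset, censor_floor=PUBLISHED_CUTOFF_MONTHS)
            )
            os_curve = km_fit(os_input(patients, cohort, aset))
            for years, label in ((1, "1yr"), (2, "2yr")):
                s, lo, hi = survival_at(efs_curve, 12.0 * years)
                cells.append(
                    _survival_cell(f"efs_{label}", cohort, aset, s, lo, hi, said.get(f"efs_{label}"))
                )
            if aset == "pps":
                dfs_curve = km_fit(dfs_input(patients, cohort, aset))
                for years, label in ((1, "1yr"), (2, "2yr")):
                    s, lo, hi = survival_at(dfs_curve, 12.0 * years)
                    cells.append(
                        _survival_cell(f"dfs_{label}", cohort, aset, s, lo, hi, said.get(f"dfs_{label}"))
                    )
            for years, label in ((1, "1yr"), (2, "2yr")):
                s, lo, hi = survival_at(os_curve, 12.0 * years)
                cells.append(
                    _survival_cell(f"os_{label}", cohort, aset, s, lo, hi, said.get(f"os_{label}"))
                )
    return Table2Report(cells=tuple(cells))


def render_report(report: Table2Report, format: str = "json") -> str:
    """Deterministic serialization of the recomputed table."""
    if format == "json":
        return json.dumps({"cells": [c.to_dict() for c in report.cells]}, indent=2, sort_keys=True)
    if format == "markdown":
        lines = [
            "| endpoint | cohort | set | recomputed | printed | discordant |",
            "|---|---|---|---|---|---|",
        ]
        for c in report.cells:
            flag = "" if c.discordant is None else ("yes" if c.discordant else "no")
            lines.append(
                f"| {c.endpoint} | {c.cohort} | {c.analysis_set.upper()} | "
                f"{c.formatted} | {c.printed or ''} | {flag} |"
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}")


def report_from_json(doc: str) -> Table2Report:
    """Inverse of ``render_report(..., "json")``."""
    data = json.loads(doc)
    return Table2Report(cells=tuple(Table2Cell(**c) for c in data["cells"]))
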