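"""Synthetic patient- and trial-level data generators.

The patient generator emulates the structure of the trial's
individual-patient table so every analysis stage is testable without any
external data: two cohorts of binomial pathological responders, a
triplet/monotherapy regimen mix, pre-operative cycle counts, log-normal
times to surgery, censored exponential event-free survival, and the
watch-and-wait pattern (clinical complete responders who decline surgery
and therefore carry no pathology).

The per-cohort ``pcr_rate`` parameter is the full-analysis-set pCR rate --
the design's decision endpoint: a patient drawn as a responder is operated
with TRG 0, so the derived count ``x/n`` is an unbiased binomial estimate
of the parameter and exact-interval coverage guarantees carry over to the
recovery harness.  Watch-and-wait behaviour is drawn among
*non*-responders, mirroring how such patients enter the published FAS
denominator without pathology.  Defaults are the design conditions under
the observed enrolment: rates (0.15, 0.35), sizes (14, 8).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.random import default_rng

from .design import CohortData, DesignSpec
from .intervals import RateCI, clopper_pearson
from .patients import COHORTS, PatientRecord, assign_analysis_sets, derive_endpoints

__all__ = ["SynthConfig", "gen_patients", "gen_trial_counts", "recover_rates"]

_SITES = {
    "colon": ["ascending colon", "transverse colon", "descending colon",
              "sigmoid colon", "hepatic flexure"],
    "rectum": ["lower rectum", "middle rectum"],
}
_CLINICAL_T = {"colon": ["T4a", "T4b"], "rectum": ["T3"]}
_TTS_LOGNORMAL = {"colon": (np.log(2.7), 0.40), "rectum": (np.log(6.0), 0.30)}


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults are the design conditions."""

    pcr_rate: Mapping[str, float] = field(
        default_factory=lambda: {"colon": 0.15, "rectum": 0.35}
    )
    n: Mapping[str, int] = field(default_factory=lambda: {"colon": 14, "rectum": 8})
    triplet_prob: float = 0.5
    watch_and_wait_prob: float = 0.18
    cycles_preop_range: tuple[int, int] = (3, 12)
    tts_lognormal: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_TTS_LOGNORMAL)
    )
    followup_range: tuple[float, float] = (8.0, 34.0)
    efs_hazard: float = 0.003  # events per month
    seed: int = 0

    def __post_init__(self) -> None:
        for c in COHORTS:
            if not 0.0 <= self.pcr_rate[c] <= 1.0:
                raise ValueError("pCR rates must lie in [0, 1]")
            if self.n[c] < 0:
                raise ValueError("cohort sizes must be nonnegative")
        if self.efs_hazard < 0:
            raise ValueError("hazard must be nonnegative")
        if not all(s > 0 for _, s in self.tts_lognormal.values()):
            raise ValueError("log-normal scales must be positive")


def _gen_one(pid: str, cohort: str, cfg: SynthConfig, rng) -> PatientRecord:
    pcr = rng.uniform() < cfg.pcr_rate[cohort]
    waw = (not pcr) and rng.uniform() < cfg.watch_and_wait_prob
    surgery = not waw
    triplet = rng.uniform() < cfg.triplet_prob
    regimen = frozenset({"TORI", "IRI", "BEV"}) if triplet else frozenset({"TORI"})
    kras = rng.choice(["mutant", "wild", "unknown"], p=[0.6, 0.15, 0.25])
    known = kras != "unknown"
    # durations kept to one decimal, like the transcribed table
    followup = float(np.round(rng.uniform(*cfg.followup_range), 1))
    tts = trg = yp_t = yp_n = r0 = dfs = dfs_event = None
    if surgery:
        mu_t, sd_t = cfg.tts_lognormal[cohort]
        tts = float(np.round(rng.lognormal(mu_t, sd_t), 1))
        followup = max(followup, round(tts + 0.5, 1))
        trg = 0 if pcr else int(rng.integers(1, 4))
        yp_t, yp_n = ("ypT0", "ypN0") if pcr else (f"ypT{int(rng.integers(1, 4))}", "ypN0")
        r0 = True
        dfs = round(followup - tts, 1)
        dfs_event = False
    if cfg.efs_hazard > 0:
        event_time = float(rng.exponential(1.0 / cfg.efs_hazard))
    else:
        event_time = np.inf
    efs_event = event_time < followup
    efs = max(round(event_time, 1), 0.1) if efs_event else followup
    return PatientRecord(
        id=pid,
        cohort=cohort,
        age=int(rng.integers(19, 75)),
        sex=str(rng.choice(["male", "female"])),
        ecog=int(rng.integers(0, 2)),
        lynch=str(rng.choice(["yes", "no", "unknown"])),
        clinical_t=str(rng.choice(_CLINICAL_T[cohort])),
        clinical_n_positive=bool(rng.uniform() < 0.8),
        site=str(rng.choice(_SITES[cohort])),
        regimen=regimen,
        kras=str(kras) if known else "unknown",
        nras="wild" if known else "unknown",
        braf="wild" if known else "unknown",
        surgery=surgery,
        cycles_preop=int(rng.integers(cfg.cycles_preop_range[0], cfg.cycles_preop_range[1] + 1)),
        cycles_postop=int(rng.integers(0, 10)) if surgery else 0,
        tts_months=tts,
        yp_t=yp_t,
        yp_n=yp_n,
        trg=trg,
        r0=r0,
        ccr=waw,
        watch_and_wait=waw,
        efs_months=float(efs),
        efs_event=bool(efs_event),
        dfs_months=dfs,
        dfs_event=dfs_event,
        os_months=followup,
        os_event=False,
        followup_months=followup,
    )


def gen_patients(config: SynthConfig | None = None) -> list[PatientRecord]:
    """Generate a fixture-compatible synthetic patient table.

    Every record satisfies the patient-data invariants (enforced by the
    loader's validator in the round-trip property test).
    """
    cfg = config or SynthConfig()
    rng = default_rng(cfg.seed)
    records: list[PatientRecord] = []
    for cohort, prefix in (("colon", "SC"), ("rectum", "SR")):
        for i in range(cfg.n[cohort]):
            records.append(_gen_one(f"{prefix}{i + 1}", cohort, cfg, rng))
    return records


def gen_trial_counts(
    true_p: Sequence[float],
    design: DesignSpec,
    n_trials: int,
    seed: int = 0,
) -> list[dict[str, CohortData]]:
    """Reproducible stage-1 binomial draws for the design simulator's tests."""
    rng = default_rng(seed)
    n1 = [c.n_stage1 for c in design.cohorts]
    xs = [rng.binomial(n1[j], true_p[j], size=n_trials) for j in range(2)]
    return [
        {name: CohortData(int(xs[j][t]), n1[j]) for j, name in enumerate(design.names)}
        for t in range(n_trials)
    ]


def recover_rates(records: Sequence[PatientRecord], level: float = 0.95) -> dict[str, RateCI]:
    """Exact interval estimate of each cohort's generated pCR rate.

    Used by the parameter-recovery harness: over replicated generation the
    interval covers the generating rate with at least the nominal
    frequency, because the derived count is exactly binomial.
    """
    sets = assign_analysis_sets(records)
    out: dict[str, RateCI] = {}
    for cohort in COHORTS:
        counts = derive_endpoints(records, sets, cohort, "fas")
        if counts.pcr_n == 0:
            raise ValueError(f"empty cohort {cohort!r}")
        out[cohort] = clopper_pearson(counts.pcr_x, counts.pcr_n, level)
    return out
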