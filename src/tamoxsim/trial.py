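"""Virtual clinical trial: the fifteen simulation protocols.

Three study groups over CYP2D6 phenotype populations (N = 1,000 each by
default, 15,000 virtual patients in total):

* **A** — standard dose: 20 mg tamoxifen q.d. for twelve months in EM,
  IM and PM populations (3 arms).  The EM arm provides the reference
  range (median and 5th/95th percentiles) for every other comparison.
* **B** — dose escalation: four months of 20 mg q.d. followed by four
  months of the escalated regimen (20 mg b.i.d. or 40 mg q.d. in IMs
  and PMs, plus 60 mg q.d. in PMs; 5 arms), evaluated at the pre-dose
  trough at the end of the second phase (day 240).
* **C** — fixed-dose combination: 20 mg tamoxifen q.d. plus concomitant
  once-daily oral endoxifen for twelve months (0.5/1.0/1.5 mg in IMs,
  1-4 mg in PMs; 7 arms).

Summaries report the 5/25/50/75/95th percentiles of the trough steady-
state concentration per analyte (linear interpolation between order
statistics); arms are classified against the EM reference band by their
median, and the dose-finding search returns the smallest endoxifen dose
whose median endoxifen trough lies within +/-10% of the EM reference
median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import CalibratedModel
from .kinetics import population_troughs
from .regimen import Regimen, combine, once_daily, twice_daily
from .population import population_spec, sample_population

PERCENTILES = (5, 25, 50, 75, 95)
DEFAULT_END_CANDIDATES = {"IM": (0.5, 1.0, 1.5), "PM": (1.0, 2.0, 3.0, 4.0)}
DOSE_FINDING_TOL = 0.10

PHASE1_DAYS = 120   # four months of 20 mg q.d. before escalation
PHASE2_END_DAY = 240
FULL_YEAR_DAY = 360


class TrialError(RuntimeError):
    pass


@dataclass(frozen=True)
class StudyArm:
    arm_id: str
    group: str
    phenotype: str
    regimen: Regimen
    n: int
    seed: int
    evaluation_day: int


@dataclass(frozen=True)
class TrialDesign:
    arms: tuple[StudyArm, ...]
    seed: int

    @property
    def total_subjects(self) -> int:
        return sum(a.n for a in self.arms)

    def filtered(self, group: str) -> "TrialDesign":
        if group in (None, "all"):
            return self
        if group not in {a.group for a in self.arms}:
            raise TrialError(f"unknown study group {group!r}")
        return TrialDesign(tuple(a for a in self.arms if a.group == group), self.seed)


def escalation_regimen(dose_mg: float, interval_h: float) -> Regimen:
    """Four months 20 mg q.d., then four months of the escalated regimen."""
    phase1 = once_daily("TAM", 20.0, PHASE1_DAYS)
    if interval_h == 24.0:
        phase2 = once_daily("TAM", dose_mg, PHASE2_END_DAY - PHASE1_DAYS,
                            start_day=PHASE1_DAYS)
    else:
        phase2 = twice_daily("TAM", dose_mg, PHASE2_END_DAY - PHASE1_DAYS,
                             start_day=PHASE1_DAYS)
    return combine(phase1, phase2)


def combination_regimen(end_dose_mg: float, days: int = FULL_YEAR_DAY) -> Regimen:
    """20 mg tamoxifen q.d. plus concomitant once-daily endoxifen."""
    return combine(once_daily("TAM", 20.0, days), once_daily("END", end_dose_mg, days))


def default_design(seed: int, n: int = 1000) -> TrialDesign:
    """The full fifteen-protocol design (3 + 5 + 7 arms).

    Each arm draws its population from ``seed + arm_index`` so runs are
    reproducible arm by arm."""
    specs: list[tuple[str, str, str, Regimen, int]] = []
    for phen in ("EM", "IM", "PM"):
        specs.append((f"A-{phen}-20qd", "A", phen,
                      once_daily("TAM", 20.0, FULL_YEAR_DAY), FULL_YEAR_DAY))
    for phen in ("IM", "PM"):
        specs.append((f"B-{phen}-20bid", "B", phen,
                      escalation_regimen(20.0, 12.0), PHASE2_END_DAY))
        specs.append((f"B-{phen}-40qd", "B", phen,
                      escalation_regimen(40.0, 24.0), PHASE2_END_DAY))
    specs.append(("B-PM-60qd", "B", "PM",
                  escalation_regimen(60.0, 24.0), PHASE2_END_DAY))
    for phen, candidates in DEFAULT_END_CANDIDATES.items():
        for dose in candidates:
            specs.append((f"C-{phen}-END{dose:g}", "C", phen,
                          combination_regimen(dose), FULL_YEAR_DAY))
    arms = tuple(
        StudyArm(arm_id, group, phen, regimen, n, seed + i, eval_day)
        for i, (arm_id, group, phen, regimen, eval_day) in enumerate(specs)
    )
    return TrialDesign(arms=arms, seed=seed)


# ---------------------------------------------------------------------------
# execution

def _require_calibrated(model) -> None:
    if not isinstance(model, CalibratedModel):
        raise TrialError("run_arm requires a calibrated model "
                         "(see tamoxsim.calibrate.calibrate)")


def run_arm(arm: StudyArm, model: CalibratedModel) -> pd.DataFrame:
    """Trough records for every subject and analyte at the evaluation day."""
    _require_calibrated(model)
    spec = population_spec(model, arm.phenotype, arm.n, arm.seed)
    subjects = sample_population(spec)
    records = population_troughs(
        model.network(arm.phenotype), model.phenotype(arm.phenotype),
        subjects, arm.regimen, arm.evaluation_day)
    records.insert(0, "arm_id", arm.arm_id)
    records.insert(1, "group", arm.group)
    records.insert(2, "phenotype", arm.phenotype)
    return records


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Percentile summary (5/25/50/75/95) of troughs per arm and analyte."""
    if records.empty:
        raise TrialError("cannot summarize an empty record set")
    keys = [k for k in ("arm_id", "group", "phenotype") if k in records.columns]
    rows = []
    for group_keys, sub in records.groupby(keys + ["analyte"], sort=False):
        if len(sub) < 20:
            warnings.warn("fewer than 20 records: extreme percentiles are "
                          "order-statistic noise", stacklevel=2)
        values = np.percentile(sub["trough_ugL"].to_numpy(), PERCENTILES)
        row = dict(zip(keys + ["analyte"], group_keys))
        row.update({f"p{p}": v for p, v in zip(PERCENTILES, values)})
        rows.append(row)
    return pd.DataFrame(rows)


def reference_range(em_records: pd.DataFrame) -> dict[str, dict[str, float]]:
    """EM reference band per analyte from the group A EM arm."""
    summary = summarize(em_records)
    return {
        r.analyte: {"p5": r.p5, "median": r.p50, "p95": r.p95}
        for r in summary.itertuples()
    }


def compare_to_reference(summary: pd.DataFrame,
                         ref: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Classify each arm median against the EM reference band.

    ``within`` iff the arm median lies in [EM p5, EM p95]; otherwise
    ``below``/``above`` by side.  The comparison basis (arm median vs
    reference band) is carried in the output."""
    out = summary.copy()

    def classify(row):
        band = ref[row["analyte"]]
        if row["p50"] < band["p5"]:
            return "below"
        if row["p50"] > band["p95"]:
            return "above"
        return "within"

    out["classification"] = out.apply(classify, axis=1)
    out["basis"] = "arm median vs EM p5-p95 band"
    return out


def run_trial(design: TrialDesign, model: CalibratedModel,
              em_reference: pd.DataFrame | None = None,
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every arm; returns (per-subject records, classified summary).

    The classification reference is the design's own group A EM arm; for
    a design filtered to group B or C, pass the reference arm's records
    via ``em_reference``."""
    _require_calibrated(model)
    records = pd.concat([run_arm(arm, model) for arm in design.arms],
                        ignore_index=True)
    em = records[(records.group == "A") & (records.phenotype == "EM")]
    if em.empty:
        em = em_reference
    if em is None or em.empty:
        raise TrialError("design lacks the group A EM reference arm; pass "
                         "em_reference records")
    ref = reference_range(em)
    summary = compare_to_reference(summarize(records), ref)
    return records, summary


# ---------------------------------------------------------------------------
# dose finding

def _em_reference_median(model: CalibratedModel, n: int | None, seed: int) -> float:
    regimen = once_daily("TAM", model.reference_dose_mg, model.reference_day)
    if n is None:
        return model.typical_troughs("EM", regimen, model.reference_day)["END"]
    arm = StudyArm("ref-EM", "A", "EM", regimen, n, seed, model.reference_day)
    records = run_arm(arm, model)
    return float(records[records.analyte == "END"]["trough_ugL"].median())


def find_minimal_dose(model: CalibratedModel, phenotype: str,
                      candidates=None, criterion_tol: float = DOSE_FINDING_TOL,
                      n: int | None = None, seed: int = 0,
                      ) -> tuple[float | None, pd.DataFrame]:
    """Smallest concomitant endoxifen dose matching the EM reference median.

    Simulates 20 mg TAM q.d. plus each candidate endoxifen dose
    (ascending) and returns the first whose median endoxifen trough lies
    within ``criterion_tol`` of the EM reference median, together with
    the per-candidate deviation table.  With ``n=None`` the search runs
    on the typical subject (deterministic); with ``n`` set it runs on
    seeded populations of that size.
    """
    _require_calibrated(model)
    if candidates is None:
        candidates = DEFAULT_END_CANDIDATES.get(phenotype, (0.0,))
    candidates = list(candidates)
    if not candidates:
        raise TrialError("candidate dose list is empty")
    if sorted(candidates) != candidates:
        raise TrialError("candidate doses must be ascending")
    ref = _em_reference_median(model, n, seed)
    rows, best = [], None
    for i, dose in enumerate(candidates):
        regimen = (combination_regimen(dose) if dose > 0
                   else once_daily("TAM", 20.0, FULL_YEAR_DAY))
        if n is None:
            median = model.typical_troughs(phenotype, regimen, FULL_YEAR_DAY)["END"]
        else:
            arm = StudyArm(f"find-{phenotype}-{dose:g}", "C", phenotype,
                           regimen, n, seed + 1 + i, FULL_YEAR_DAY)
            rec = run_arm(arm, model)
            median = float(rec[rec.analyte == "END"]["trough_ugL"].median())
        deviation = median / ref - 1.0
        passes = abs(deviation) <= criterion_tol
        rows.append({
            "end_dose_mg": dose, "median_end_ugL": median,
            "em_reference_ugL": ref, "rel_deviation": deviation, "passes": passes,
        })
        if passes and best is None:
            best = dose
    return best, pd.DataFrame(rows)
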