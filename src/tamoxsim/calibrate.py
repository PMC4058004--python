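"""Calibration of the cascade to the phenotype trough target table.

Because the system is linear, calibration is a short sequence of exact
one-dimensional scalings evaluated on the typical subject (all
variability multipliers = 1) at the 20 mg q.d. reference regimen:

1. scale the tamoxifen exposure (lumped bioavailability) to the TAM
   target — every downstream trough scales with it;
2. scale the TAM->NDM split to the NDM target, compensating in the
   lumped TAM elimination edge so the total TAM outflow (and hence the
   TAM profile) is unchanged;
3. likewise scale TAM->4OH to the 4OH target;
4. solve the NDM->END split from the affine dependence of the END
   trough on it (two simulations), compensating in the NDM elimination
   edge.

Holding each analyte's total outflow constant makes every step exact,
so a single pass reproduces all twelve targets to numerical precision
and re-calibration is a no-op.  Finally the endoxifen depot exposure is
scaled so that 1 mg/day of oral endoxifen alone yields the unit trough
k_END; the endoxifen subsystem is phenotype-independent, so direct
endoxifen exposure adds identically in every phenotype (superposition).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

from .kinetics import build_system, trough_css
from .network import (
    SINK,
    MetabolicNetwork,
    PhenotypeActivity,
    phenotype_activity,
)
from .regimen import once_daily
from .targets import endoxifen_unit_exposure_target, target_lookup, validate_targets

REFERENCE_TAM_DOSE_MG = 20.0
REFERENCE_DAY = 360
#: maximum relative error of any reproduced target after calibration
CALIBRATION_RTOL = 1e-6


class CalibrationError(RuntimeError):
    pass


@dataclass
class CalibratedModel:
    """Per-phenotype calibrated networks plus the endoxifen unit exposure.

    ``k_end_unit`` is the typical pre-dose trough (ug/L) contributed by
    each mg/day of directly administered oral endoxifen.  ``sigma_abs``
    and ``sigma_2d6`` are the population log-SDs used by the virtual
    population generator (``sigma_2d6`` is refined against the EM
    endoxifen percentile spread by :func:`tamoxsim.population.calibrate_variability`).
    """

    networks: dict[str, MetabolicNetwork]
    activities: dict[str, float]
    k_end_unit: float
    targets: pd.DataFrame
    sigma_abs: float = 0.28
    sigma_2d6: float | None = None
    reference_dose_mg: float = REFERENCE_TAM_DOSE_MG
    reference_day: int = REFERENCE_DAY

    def network(self, phenotype: str) -> MetabolicNetwork:
        return self.networks[phenotype]

    def phenotype(self, phenotype: str) -> PhenotypeActivity:
        return phenotype_activity(phenotype, self.activities[phenotype])

    def typical_troughs(self, phenotype: str, regimen, at_day: int) -> dict[str, float]:
        system = build_system(self.network(phenotype), self.phenotype(phenotype))
        return trough_css(system, regimen, at_day)

    # -- serialization ----------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "networks": {p: n.to_dict() for p, n in self.networks.items()},
                "activities": dict(self.activities),
                "k_end_unit_ugL_per_mg_day": self.k_end_unit,
                "sigma_abs": self.sigma_abs,
                "sigma_2d6": self.sigma_2d6,
                "reference_dose_mg": self.reference_dose_mg,
                "reference_day": self.reference_day,
                "targets": self.targets.to_dict(orient="records"),
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "CalibratedModel":
        d = yaml.safe_load(text)
        return cls(
            networks={p: MetabolicNetwork.from_dict(n) for p, n in d["networks"].items()},
            activities=dict(d["activities"]),
            k_end_unit=float(d["k_end_unit_ugL_per_mg_day"]),
            targets=pd.DataFrame(d["targets"]),
            sigma_abs=float(d["sigma_abs"]),
            sigma_2d6=None if d["sigma_2d6"] is None else float(d["sigma_2d6"]),
            reference_dose_mg=float(d["reference_dose_mg"]),
            reference_day=int(d["reference_day"]),
        )


def _typical_troughs(network: MetabolicNetwork, phen: PhenotypeActivity,
                     dose_mg: float, day: int) -> dict[str, float]:
    system = build_system(network, phen)
    return trough_css(system, once_daily("TAM", dose_mg, day), day)


def _scalar(edge, activity: float) -> float:
    """Constant factor mapping base to effective rate for the typical subject."""
    f = edge.cyp2d6_fraction
    return f * activity + (1.0 - f)


def _calibrate_phenotype(template: MetabolicNetwork, phenotype: str, activity: float,
                         targets: dict[tuple[str, str], float],
                         dose_mg: float, day: int) -> MetabolicNetwork:
    phen = phenotype_activity(phenotype, activity)
    net = template
    tgt = {a: targets[phenotype, a] for a in ("TAM", "NDM", "4OH", "END")}

    # effective outflow totals to be held fixed
    def eff(src, dst):
        e = net.edge(src, dst)
        return e.rate * _scalar(e, activity)

    k_tam_tot = sum(eff("TAM", d) for d in ("NDM", "4OH", SINK))
    k_ndm_tot = sum(eff("NDM", d) for d in ("END", SINK))

    t = _typical_troughs(net, phen, dose_mg, day)

    # 1. parent exposure: every trough scales with the lumped bioavailability
    f_scale = tgt["TAM"] / t["TAM"]
    net = net.with_bioavailability(
        "TAM", net.absorption["TAM"].bioavailability * f_scale)
    t = {a: v * f_scale for a, v in t.items()}

    # 2./3. formation splits, compensated in the lumped elimination edge
    net = net.with_edge_rate("TAM", "NDM",
                             net.edge("TAM", "NDM").rate * tgt["NDM"] / t["NDM"])
    net = net.with_edge_rate("TAM", "4OH",
                             net.edge("TAM", "4OH").rate * tgt["4OH"] / t["4OH"])
    k_tam_elim = k_tam_tot - eff("TAM", "NDM") - eff("TAM", "4OH")
    if k_tam_elim < 0:
        raise CalibrationError(
            f"{phenotype}: TAM->sink rate would be negative; the NDM/4OH targets "
            "demand more formation than the total TAM outflow allows")
    net = net.with_edge_rate("TAM", SINK, k_tam_elim)

    # 4. NDM->END split from the affine END response (exact for a linear system)
    k_ne = eff("NDM", "END")
    net = net.with_edge_rate("NDM", SINK, k_ndm_tot - k_ne)
    e1 = _typical_troughs(net, phen, dose_mg, day)["END"]
    net0 = net.with_edge_rate("NDM", "END", 0.0).with_edge_rate("NDM", SINK, k_ndm_tot)
    e0 = _typical_troughs(net0, phen, dose_mg, day)["END"]
    if e1 <= e0:
        raise CalibrationError(f"{phenotype}: NDM->END edge has no leverage on END")
    k_ne_req = (tgt["END"] - e0) * k_ne / (e1 - e0)
    if k_ne_req < 0 or k_ne_req > k_ndm_tot:
        raise CalibrationError(
            f"{phenotype}: NDM->END effective rate {k_ne_req:.3e}/h outside "
            f"[0, {k_ndm_tot:.3e}]; END target infeasible")
    scalar_ne = _scalar(net.edge("NDM", "END"), activity)
    if scalar_ne <= 0:
        raise CalibrationError(f"{phenotype}: NDM->END fully CYP2D6 with zero activity")
    net = net.with_edge_rate("NDM", "END", k_ne_req / scalar_ne)
    net = net.with_edge_rate("NDM", SINK, k_ndm_tot - k_ne_req)

    achieved = _typical_troughs(net, phen, dose_mg, day)
    worst = max(abs(achieved[a] / tgt[a] - 1.0) for a in tgt)
    if worst > CALIBRATION_RTOL:
        raise CalibrationError(
            f"{phenotype}: calibration residual {worst:.2e} exceeds tolerance")
    return net


def calibrate(targets: pd.DataFrame, template: MetabolicNetwork,
              activities: dict[str, float] | None = None,
              dose_mg: float = REFERENCE_TAM_DOSE_MG,
              day: int = REFERENCE_DAY) -> CalibratedModel:
    """Derive per-phenotype rate constants reproducing the target table."""
    validate_targets(targets)
    if activities is None:
        activities = {"EM": 1.0, "IM": 0.5, "PM": 0.0}
    lookup = target_lookup(targets)
    networks = {
        p: _calibrate_phenotype(template, p, a, lookup, dose_mg, day)
        for p, a in activities.items()
    }
    k_end = (lookup["EM", "END"] - lookup["PM", "END"]) / 3.0
    model = CalibratedModel(
        networks=networks, activities=dict(activities), k_end_unit=k_end,
        targets=targets.copy(), reference_dose_mg=dose_mg, reference_day=day,
    )
    _calibrate_endoxifen_depot(model)
    return model


def _calibrate_endoxifen_depot(model: CalibratedModel) -> None:
    """Scale the endoxifen depot exposure so 1 mg/day oral endoxifen alone
    yields a typical trough of exactly k_END; applied to every phenotype
    network (the endoxifen subsystem carries no CYP2D6 dependence)."""
    regimen = once_daily("END", 1.0, model.reference_day)
    em_net = model.networks["EM"]
    system = build_system(em_net, model.phenotype("EM"))
    trough = trough_css(system, regimen, model.reference_day)["END"]
    if trough <= 0:
        raise CalibrationError("oral endoxifen produced no exposure")
    scale = model.k_end_unit / trough
    for p, net in model.networks.items():
        model.networks[p] = net.with_bioavailability(
            "END", net.absorption["END"].bioavailability * scale)


def endoxifen_unit_exposure(model: CalibratedModel) -> float:
    """Simulated trough (ug/L) of 1 mg/day oral endoxifen alone for the
    typical subject — by construction equal to ``model.k_end_unit``."""
    regimen = once_daily("END", 1.0, model.reference_day)
    system = build_system(model.networks["EM"], model.phenotype("EM"))
    return trough_css(system, regimen, model.reference_day)["END"]


def calibration_report(model: CalibratedModel) -> pd.DataFrame:
    """Achieved typical troughs vs targets at the reference regimen."""
    regimen = once_daily("TAM", model.reference_dose_mg, model.reference_day)
    rows = []
    for phenotype in model.networks:
        achieved = model.typical_troughs(phenotype, regimen, model.reference_day)
        for _, r in model.targets[model.targets.phenotype == phenotype].iterrows():
            got = achieved[r.analyte]
            rows.append({
                "phenotype": phenotype, "analyte": r.analyte,
                "target_ugL": r.target_ugL, "achieved_ugL": got,
                "rel_error": got / r.target_ugL - 1.0,
            })
    return pd.DataFrame(rows)
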