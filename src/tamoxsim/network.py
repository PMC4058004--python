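"""Metabolic network of tamoxifen and its measured metabolites.

Tamoxifen (TAM) is mostly N-demethylated to N-desmethyltamoxifen (NDM),
which is 4-hydroxylated — almost exclusively by the polymorphic CYP2D6 —
to endoxifen (END).  A minor route 4-hydroxylates TAM to 4-hydroxy-
tamoxifen (4OH), which is then N-demethylated to END.  Conjugation and
all further clearance are lumped into one first-order elimination edge
per analyte.  Each compound that can be dosed orally (TAM, END) has a
first-order absorption depot.

The network stores *base* rate constants on the extensive-metabolizer
(EM) activity scale together with the fraction of each reaction carried
by CYP2D6; phenotype and inter-individual variability enter when a
linear system is built from the network (see :mod:`tamoxsim.kinetics`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

ANALYTES: tuple[str, ...] = ("TAM", "NDM", "4OH", "END")
DOSED_COMPOUNDS: tuple[str, ...] = ("TAM", "END")
SINK = "sink"

#: CYP2D6 activity multiplier per phenotype: EM normal, IM one functional
#: allele (gene-dose 0.5), PM abolished activity.
DEFAULT_ACTIVITIES: dict[str, float] = {"EM": 1.0, "IM": 0.5, "PM": 0.0}
PHENOTYPES: tuple[str, ...] = ("EM", "IM", "PM")


class NetworkError(ValueError):
    """Raised when a metabolic network violates its structural invariants."""


@dataclass(frozen=True)
class Edge:
    """A first-order formation or elimination step.

    ``rate`` is the base rate constant (1/h) at EM-typical CYP2D6
    activity; ``cyp2d6_fraction`` is the share of the reaction mediated
    by CYP2D6, in [0, 1].
    """

    source: str
    target: str
    rate: float
    cyp2d6_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise NetworkError(f"negative rate constant on {self.source}->{self.target}")
        if not 0.0 <= self.cyp2d6_fraction <= 1.0:
            raise NetworkError(
                f"cyp2d6_fraction outside [0, 1] on {self.source}->{self.target}"
            )


@dataclass(frozen=True)
class Absorption:
    """First-order oral absorption: rate constant ka (1/h) and a lumped
    bioavailability/exposure scale applied to each administered dose."""

    ka: float
    bioavailability: float

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.bioavailability < 0:
            raise NetworkError("absorption parameters must be positive")


@dataclass(frozen=True)
class PhenotypeActivity:
    """CYP2D6 phenotype and its dimensionless activity multiplier."""

    phenotype: str
    activity: float

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise NetworkError(f"unknown phenotype {self.phenotype!r}")
        if self.activity < 0:
            raise NetworkError("CYP2D6 activity must be >= 0")
        if self.phenotype == "EM" and self.activity != 1.0:
            raise NetworkError("EM activity is fixed at 1.0")
        if self.phenotype == "PM" and self.activity != 0.0:
            raise NetworkError("PM activity is fixed at 0.0 (abolished)")
        if self.phenotype == "IM" and not 0.0 < self.activity < 1.0:
            raise NetworkError("IM activity must lie strictly between 0 and 1")


def phenotype_activity(phenotype: str, activity: float | None = None) -> PhenotypeActivity:
    """Return the activity record for *phenotype*, defaulting to the
    gene-dose scale (EM 1.0, IM 0.5, PM 0.0)."""
    if activity is None:
        activity = DEFAULT_ACTIVITIES[phenotype]
    return PhenotypeActivity(phenotype, activity)


@dataclass(frozen=True)
class SubjectParameters:
    """Per-subject lognormal multipliers (median 1) on absorption and on
    CYP2D6 activity.  ``eta_2d6`` is inert for PM subjects (activity 0)."""

    subject_id: int
    eta_abs: float = 1.0
    eta_2d6: float = 1.0

    def __post_init__(self) -> None:
        if self.eta_abs <= 0 or self.eta_2d6 <= 0:
            raise NetworkError("subject multipliers must be > 0")


TYPICAL_SUBJECT = SubjectParameters(subject_id=0, eta_abs=1.0, eta_2d6=1.0)

# Edges that must exist, with constraints on their CYP2D6 share.
_REQUIRED_EDGES = {
    ("TAM", "NDM"): "zero",      # N-demethylation, CYP3A4-dominated
    ("TAM", "4OH"): "positive",  # 4-hydroxylation, partly CYP2D6
    ("NDM", "END"): "dominant",  # 4-hydroxylation, near-exclusively CYP2D6
    ("4OH", "END"): "zero",      # N-demethylation
}


@dataclass(frozen=True)
class MetabolicNetwork:
    """Directed formation/elimination graph over the four analytes.

    volumes: apparent volume of distribution per analyte (L).
    absorption: depot parameters per dosed compound (TAM, END).
    """

    edges: tuple[Edge, ...]
    volumes: dict[str, float] = field(default_factory=dict)
    absorption: dict[str, Absorption] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        seen = {}
        for e in self.edges:
            if e.source not in ANALYTES:
                raise NetworkError(f"unknown source analyte {e.source!r}")
            if e.target not in ANALYTES and e.target != SINK:
                raise NetworkError(f"unknown target {e.target!r}")
            if (e.source, e.target) in seen:
                raise NetworkError(f"duplicate edge {e.source}->{e.target}")
            seen[e.source, e.target] = e
        for (src, tgt), kind in _REQUIRED_EDGES.items():
            if (src, tgt) not in seen:
                raise NetworkError(f"required edge {src}->{tgt} missing")
            f = seen[src, tgt].cyp2d6_fraction
            if kind == "zero" and f != 0.0:
                raise NetworkError(f"{src}->{tgt} must have cyp2d6_fraction 0")
            if kind == "positive" and not f > 0.0:
                raise NetworkError(f"{src}->{tgt} must have cyp2d6_fraction > 0")
            if kind == "dominant" and not 0.0 < f < 1.0:
                raise NetworkError(
                    f"{src}->{tgt} cyp2d6_fraction must lie in (0, 1): a small "
                    "non-CYP2D6 residual keeps PM endoxifen non-zero"
                )
        for a in ANALYTES:
            if (a, SINK) not in seen:
                raise NetworkError(f"missing elimination edge for {a}")
            if a not in self.volumes or self.volumes[a] <= 0:
                raise NetworkError(f"missing or non-positive volume for {a}")
        for c in DOSED_COMPOUNDS:
            if c not in self.absorption:
                raise NetworkError(f"missing absorption parameters for {c}")

    # -- access -----------------------------------------------------------
    def edge(self, source: str, target: str) -> Edge:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        raise KeyError(f"{source}->{target}")

    def outflow(self, source: str) -> float:
        """Total base outflow rate constant of *source* (1/h)."""
        return sum(e.rate for e in self.edges if e.source == source)

    def with_edge_rate(self, source: str, target: str, rate: float) -> "MetabolicNetwork":
        edges = tuple(
            replace(e, rate=rate) if (e.source, e.target) == (source, target) else e
            for e in self.edges
        )
        return replace(self, edges=edges)

    def with_bioavailability(self, compound: str, value: float) -> "MetabolicNetwork":
        absorption = dict(self.absorption)
        absorption[compound] = replace(absorption[compound], bioavailability=value)
        return replace(self, absorption=absorption)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "rate_per_h": e.rate,
                    "cyp2d6_fraction": e.cyp2d6_fraction,
                }
                for e in self.edges
            ],
            "volumes_L": dict(self.volumes),
            "absorption": {
                c: {"ka_per_h": a.ka, "bioavailability": a.bioavailability}
                for c, a in self.absorption.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetabolicNetwork":
        return cls(
            edges=tuple(
                Edge(e["source"], e["target"], e["rate_per_h"], e.get("cyp2d6_fraction", 0.0))
                for e in d["edges"]
            ),
            volumes=dict(d["volumes_L"]),
            absorption={
                c: Absorption(a["ka_per_h"], a["bioavailability"])
                for c, a in d["absorption"].items()
            },
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "MetabolicNetwork":
        return cls.from_dict(yaml.safe_load(text))


def default_network() -> MetabolicNetwork:
    """Template network with literature-typical time constants.

    Effective elimination half-lives: TAM 7 d, NDM 20 d, 4OH 2 d,
    END 2.5 d; absorption half-life 3 h for both dosed compounds.  The
    half-lives shape only the transient approach to steady state — the
    calibration module rescales formation splits and exposure so that
    steady-state troughs hit the phenotype target table exactly.
    """
    k_tam = math.log(2) / (7 * 24)
    k_ndm = math.log(2) / (18 * 24)
    k_4oh = math.log(2) / (2 * 24)
    k_end = math.log(2) / (2.5 * 24)
    ka = math.log(2) / 3.0
    return MetabolicNetwork(
        edges=(
            Edge("TAM", "NDM", 0.80 * k_tam, 0.0),
            Edge("TAM", "4OH", 0.04 * k_tam, 0.5),
            Edge("TAM", SINK, 0.16 * k_tam, 0.0),
            Edge("NDM", "END", 0.10 * k_ndm, 0.95),
            Edge("NDM", SINK, 0.90 * k_ndm, 0.0),
            Edge("4OH", "END", 0.30 * k_4oh, 0.0),
            Edge("4OH", SINK, 0.70 * k_4oh, 0.0),
            Edge("END", SINK, k_end, 0.0),
        ),
        volumes={"TAM": 1000.0, "NDM": 1000.0, "4OH": 300.0, "END": 150.0},
        absorption={
            "TAM": Absorption(ka=ka, bioavailability=0.60),
            "END": Absorption(ka=ka, bioavailability=0.30),
        },
    )
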