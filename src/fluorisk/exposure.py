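"""Deterministic non-carcinogenic risk arithmetic for dietary fluoride.

The model is the standard EPA chronic oral exposure chain:

    ADD = C * IR * EF * ED / (BW * AT)        average daily dose, mg/kg/d
    HQ  = ADD / RfD                           hazard quotient
    HI  = sum over foods of HQ                hazard index

and its inversion, the maximum allowable intake of a contaminated food at a
chosen hazard level:

    IR_max = HQ_target * RfD * BW * AT / (C * EF * ED)

where C is the fluoride concentration in the food (mg/kg), IR the daily
intake (kg/d), EF the exposure frequency (d/a), ED the exposure duration
(a), BW body weight (kg), AT the averaging time (d) and RfD the oral
reference dose (mg/kg/d; 0.06 for fluoride).  With EF = 365 and
AT = ED * 365 the dose reduces exactly to C * IR / BW.

When a relative bioavailability fraction is supplied to the inversion, the
effective concentration becomes C * RBA (only the absorbed fluoride counts),
which raises the allowable intake by the factor 1/RBA.

Default population parameters ship with the package: two groups (children,
adults) with per-food median and (min, max) daily intakes from a household
consumption survey in a coal-burning fluorosis area of Southwest China.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "FOODS",
    "RFD_FLUORIDE",
    "DEFAULT_POPULATIONS",
    "FoodConcentrationRecord",
    "ExposureParameters",
    "RiskPointEstimate",
    "exposure_parameters",
    "intake_bounds",
    "average_daily_dose",
    "hazard_quotient",
    "hazard_index",
    "contribution_shares",
    "ir_max",
    "point_estimate",
]

FOODS = ("corn", "chili", "pork", "tofu")

#: Oral reference dose for fluoride, mg per kg body weight per day.
RFD_FLUORIDE = 0.06

#: Survey-based exposure defaults: per-food daily intake medians and ranges
#: (kg/d), body weight (kg), averaging time (d), exposure frequency (d/a)
#: and duration (a).  Children's intakes are the survey medians, not a
#: halving rule applied to adults.
DEFAULT_POPULATIONS: dict[str, dict] = {
    "children": {
        "ir": {
            "tofu": {"median": 0.012, "min": 0.0, "max": 0.05},
            "corn": {"median": 0.010, "min": 0.0, "max": 0.08},
            "pork": {"median": 0.033, "min": 0.004, "max": 0.10},
            "chili": {"median": 0.028, "min": 0.002, "max": 0.08},
        },
        "bw": 25.9,
        "at": 3285.0,
        "ef": 365.0,
        "ed": 9.0,
        "rfd": RFD_FLUORIDE,
    },
    "adults": {
        "ir": {
            "tofu": {"median": 0.023, "min": 0.0, "max": 0.10},
            "corn": {"median": 0.021, "min": 0.0, "max": 0.17},
            "pork": {"median": 0.067, "min": 0.008, "max": 0.20},
            "chili": {"median": 0.056, "min": 0.004, "max": 0.17},
        },
        "bw": 56.8,
        "at": 25550.0,
        "ef": 365.0,
        "ed": 70.0,
        "rfd": RFD_FLUORIDE,
    },
}


@dataclass(frozen=True)
class FoodConcentrationRecord:
    """One replicate measurement of total fluoride in one food, mg/kg."""

    food: str
    roast_day: int
    replicate: int
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(
                f"concentration must be >= 0, got {self.concentration!r}"
            )


@dataclass(frozen=True)
class ExposureParameters:
    """Population exposure constants for one group and one food's intake.

    ``at`` defaults to ``ed * 365`` and ``ef`` to 365, under which the dose
    equation cancels to C * IR / BW.
    """

    group: str
    ir: float
    bw: float
    ed: float
    ef: float = 365.0
    at: Optional[float] = None
    rfd: float = RFD_FLUORIDE

    def __post_init__(self) -> None:
        if self.at is None:
            object.__setattr__(self, "at", self.ed * 365.0)
        if self.ir < 0:
            raise ValueError(f"ir must be >= 0, got {self.ir!r}")
        for name in ("bw", "ed", "ef", "at", "rfd"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value!r}")

    def with_intake(self, ir: float) -> "ExposureParameters":
        return replace(self, ir=ir)


def exposure_parameters(
    group: str,
    food: str,
    *,
    statistic: str = "median",
    populations: Mapping[str, dict] = DEFAULT_POPULATIONS,
) -> ExposureParameters:
    """Build :class:`ExposureParameters` from a population config block.

    ``statistic`` selects which intake value to use ("median", "min", "max").
    """
    try:
        block = populations[group]
    except KeyError:
        raise KeyError(
            f"unknown population group {group!r}; have {sorted(populations)}"
        ) from None
    try:
        ir = block["ir"][food][statistic]
    except KeyError:
        raise KeyError(f"no intake {statistic!r} for food {food!r} in {group!r}") from None
    return ExposureParameters(
        group=group,
        ir=ir,
        bw=block["bw"],
        ed=block["ed"],
        ef=block.get("ef", 365.0),
        at=block.get("at"),
        rfd=block.get("rfd", RFD_FLUORIDE),
    )


def intake_bounds(
    group: str,
    food: str,
    populations: Mapping[str, dict] = DEFAULT_POPULATIONS,
) -> tuple[float, float]:
    """(min, max) daily intake for clamping sampled intakes, kg/d."""
    spec = populations[group]["ir"][food]
    return spec["min"], spec["max"]


@dataclass(frozen=True)
class RiskPointEstimate:
    """Deterministic HQ for one food x roasting stage x population group."""

    food: str
    roast_day: int
    group: str
    add: float
    hq: float
    bioavailability_adjusted: bool = False

    @property
    def at_risk(self) -> bool:
        return self.hq >= 1.0


def average_daily_dose(c: float, p: ExposureParameters) -> float:
    """Chronic average daily dose, mg fluoride per kg body weight per day."""
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c!r}")
    return c * p.ir * p.ef * p.ed / (p.bw * p.at)


def hazard_quotient(add: float, rfd: float = RFD_FLUORIDE) -> float:
    """HQ = ADD / RfD; values >= 1 flag potential non-carcinogenic risk."""
    if not rfd > 0:
        raise ValueError(f"rfd must be > 0, got {rfd!r}")
    return add / rfd


def hazard_index(hqs: Sequence[RiskPointEstimate]) -> float:
    """Sum of hazard quotients over co-consumed foods at one stage.

    All estimates must share the same group and roasting day; mixing
    scenarios would add incommensurable quotients.
    """
    estimates = list(hqs)
    if not estimates:
        raise ValueError("hazard_index requires at least one HQ")
    groups = {e.group for e in estimates}
    days = {e.roast_day for e in estimates}
    if len(groups) > 1 or len(days) > 1:
        raise ValueError(
            f"hazard_index requires one group and one roast_day, "
            f"got groups={sorted(groups)} days={sorted(days)}"
        )
    return sum(e.hq for e in estimates)


def contribution_shares(hqs: Mapping[str, float]) -> dict[str, float]:
    """Per-food fraction of the hazard index: share_i = HQ_i / sum(HQ).

    Accepts any per-food weights with the same additive structure — raw
    HQs (total-concentration weighting) or absorbed-dose-weighted HQs
    (bioavailability weighting).  Shares sum to 1.
    """
    total = sum(hqs.values())
    if not total > 0:
        raise ValueError("contribution shares undefined: hazard index is 0")
    if any(v < 0 for v in hqs.values()):
        raise ValueError("negative HQ in contribution_shares input")
    return {food: hq / total for food, hq in hqs.items()}


def ir_max(
    c: float,
    p: ExposureParameters,
    hq_target: float = 1.0,
    rba: Optional[float] = None,
) -> float:
    """Maximum allowable daily intake (kg/d) of a food at a hazard target.

    Inverts the dose chain at HQ = ``hq_target``.  When ``rba`` is given the
    total concentration is replaced by the bioavailable concentration
    ``c * rba``, raising the limit by 1/rba.
    """
    if not c > 0:
        raise ValueError(f"concentration must be > 0 to invert, got {c!r}")
    if not hq_target > 0:
        raise ValueError(f"hq_target must be > 0, got {hq_target!r}")
    c_eff = c
    if rba is not None:
        if not 0 < rba <= 1:
            raise ValueError(f"rba must be in (0, 1], got {rba!r}")
        c_eff = c * rba
    return hq_target * p.rfd * p.bw * p.at / (c_eff * p.ef * p.ed)


def point_estimate(
    food: str,
    roast_day: int,
    c: float,
    p: ExposureParameters,
    *,
    bioavailability_adjusted: bool = False,
) -> RiskPointEstimate:
    """Convenience: ADD and HQ for one concentration and parameter set."""
    add = average_daily_dose(c, p)
    return RiskPointEstimate(
        food=food,
        roast_day=roast_day,
        group=p.group,
        add=add,
        hq=hazard_quotient(add, p.rfd),
        bioavailability_adjusted=bioavailability_adjusted,
    )
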