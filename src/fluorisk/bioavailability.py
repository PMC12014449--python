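"""Relative bioavailability (RBA) from Caco-2 transwell transport assays.

A transport assay applies a food's intestinal digestive fluid (diluted with
HBSS) to the apical chamber of a Caco-2 monolayer and measures how much
fluoride disappears from the apical side over the incubation.  The relative
bioavailability is the absorbed amount expressed as a fraction of the total
fluoride contained in the digested food sample:

    RBA = (C_IV - C_AV) * V_IV / (T_S * M_S)

where C_IV and C_AV are the apical fluoride concentrations before and after
incubation (mg/L), V_IV the applied volume (L), T_S the total fluoride
concentration of the food (mg/kg) and M_S the digested sample mass (kg).
RBA is held as a fraction in [0, 1] throughout the package; percent appears
only at I/O boundaries.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from statistics import fmean
from typing import Iterable

from .exposure import FoodConcentrationRecord

__all__ = [
    "TransportAssay",
    "BioavailabilityResult",
    "relative_bioavailability",
    "absorbed_concentration",
    "summarize_bioavailability",
]


@dataclass(frozen=True)
class TransportAssay:
    """One transwell experiment on one food at one roasting stage.

    Concentrations are mg/L, volumes L, masses kg, total food fluoride
    mg/kg.  ``c_av > c_iv`` is tolerated (measurement noise near zero
    absorption); non-positive ``v_iv``, ``t_s`` or ``m_s`` is not.
    ``teer_ok`` records whether the monolayer passed the transepithelial
    electrical resistance QC; it is data, not a computed value.
    """

    assay_id: str
    food: str
    roast_day: int
    c_iv: float
    c_av: float
    v_iv: float
    t_s: float
    m_s: float
    dilution_ratio: str = "1:4"
    teer_ok: bool = True

    def __post_init__(self) -> None:
        for name in ("v_iv", "t_s", "m_s"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(
                    f"TransportAssay field {name!r} must be > 0, got {value!r}"
                )
        for name in ("c_iv", "c_av"):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(
                    f"TransportAssay field {name!r} must be >= 0, got {value!r}"
                )


@dataclass(frozen=True)
class BioavailabilityResult:
    """Per (food, roasting day) aggregate: mean RBA and absorbed dose."""

    food: str
    roast_day: int
    rba: float
    absorbed_mg_per_kg: float
    n_assays: int


def relative_bioavailability(assay: TransportAssay, *, clamp: bool = True) -> float:
    """Fraction of the sample's fluoride transported across the monolayer.

    Computed from apical-side depletion.  A negative raw value (apical
    concentration increased, possible near zero absorption) is clamped to 0
    with a warning rather than raised: the raw value is measurement noise,
    not an invalid input.

    Parameters
    ----------
    assay
        Validated transport assay record.
    clamp
        When true (default), negative raw RBA is returned as 0.0.

    Returns
    -------
    float
        RBA as a fraction (multiply by 100 for the conventional percent).
    """
    raw = (assay.c_iv - assay.c_av) * assay.v_iv / (assay.t_s * assay.m_s)
    if raw < 0 and clamp:
        warnings.warn(
            f"assay {assay.assay_id!r}: c_av ({assay.c_av}) exceeds c_iv "
            f"({assay.c_iv}); raw RBA {raw:.4g} clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return raw


def absorbed_concentration(c_food: float, rba: float) -> float:
    """Bioavailable ("absorbed") fluoride, mg/kg: total concentration x RBA."""
    if c_food < 0:
        raise ValueError(f"c_food must be >= 0, got {c_food!r}")
    if not 0.0 <= rba <= 1.0:
        raise ValueError(f"rba must be a fraction in [0, 1], got {rba!r}")
    return c_food * rba


def summarize_bioavailability(
    assays: Iterable[TransportAssay],
    concentrations: Iterable[FoodConcentrationRecord],
    *,
    include_failed_teer: bool = False,
) -> list[BioavailabilityResult]:
    """Aggregate assays into per-(food, roast_day) bioavailability results.

    The group RBA is the arithmetic mean of per-assay RBA fractions; the
    absorbed concentration is the mean total concentration at that stage
    times the mean RBA.  Assays failing the TEER QC flag are excluded
    unless ``include_failed_teer`` is set.

    Raises
    ------
    KeyError
        If any (food, roast_day) present in the assays has no matching
        concentration record; the message lists all offending keys.
    """
    groups: dict[tuple[str, int], list[float]] = defaultdict(list)
    for assay in assays:
        if not assay.teer_ok and not include_failed_teer:
            continue
        groups[(assay.food, assay.roast_day)].append(relative_bioavailability(assay))

    conc_groups: dict[tuple[str, int], list[float]] = defaultdict(list)
    for rec in concentrations:
        conc_groups[(rec.food, rec.roast_day)].append(rec.concentration)

    missing = sorted(k for k in groups if k not in conc_groups)
    if missing:
        raise KeyError(
            f"no concentration records for assay groups: {missing}"
        )

    results = []
    for (food, day), rbas in sorted(groups.items()):
        mean_rba = fmean(rbas)
        mean_conc = fmean(conc_groups[(food, day)])
        results.append(
            BioavailabilityResult(
                food=food,
                roast_day=day,
                rba=mean_rba,
                absorbed_mg_per_kg=absorbed_concentration(mean_conc, mean_rba),
                n_assays=len(rbas),
            )
        )
    return results
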