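"""Synthetic study bundles with known ground truth.

The generator emulates the structure of a coal-roasting fluoride study:

* four foods (corn, chili, pork, tofu) measured at roasting days
  0, 5, 10, 15, 20, 25, 30 with three replicates each (84 records);
* concentration means follow a saturating accumulation curve
  ``C(t) = c0 + (c_peak - c0) * (1 - exp(-rate * t))`` with an optional
  compact mid-roast dip (the chili-like transient), calibrated so the
  day-30 mean hits the observed end-of-roast concentration;
* transwell transport assays constructed by inverting the RBA equation,
  so a noise-free assay returns its target RBA exactly;
* intake surveys drawn from a named family (gumbel_max / logistic /
  weibull / normal / lognormal) with stored true parameters, optionally
  clamped to survey (min, max) bounds.

Everything is seeded; two bundles with the same seed are byte-identical.
The ground-truth manifest (curve parameters, per-day RBA targets, intake
families and parameters) makes the bundle usable for end-to-end recovery
tests: the pipeline's estimates can be compared against what generated the
data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .bioavailability import TransportAssay
from .exposure import DEFAULT_POPULATIONS, FOODS, FoodConcentrationRecord
from .fitting import FittedDistribution, family_frozen

__all__ = [
    "FoodProfile",
    "StudyDesign",
    "IntakeGroundTruth",
    "accumulation_curve",
    "generate_concentration_table",
    "generate_intake_survey",
    "generate_transport_assays",
    "study_bundle",
    "paper_shaped_design",
    "default_intake_truth",
]

#: Digestion constants: 0.1 g sample, 0.5 mL digestive-fluid/HBSS mixture.
DEFAULT_M_S = 0.0001  # kg
DEFAULT_V_IV = 0.0005  # L

DEFAULT_DAYS = (0, 5, 10, 15, 20, 25, 30)


@dataclass(frozen=True)
class FoodProfile:
    """Accumulation and bioavailability ground truth for one food.

    ``c_end`` is the observed mean concentration at the last roasting day;
    the curve's asymptote is back-solved so the deterministic mean hits
    ``c_end`` exactly at ``end_day``.  ``dip`` is (start_day, depth): a
    compact multiplicative dip of the given fractional depth over a
    half-sine window of ``dip_span`` days, emulating the mid-roast
    transient some foods show; it never touches day 0 or the end day.
    ``rba_range`` is the (fresh, end-of-roast) bioavailability fraction
    pair; per-day targets interpolate linearly between them.
    """

    food: str
    c0: float
    c_end: float
    rate: float = 0.12
    end_day: float = 30.0
    dip: Optional[tuple[float, float]] = None
    dip_span: float = 7.5
    rba_range: tuple[float, float] = (0.03, 0.10)

    def __post_init__(self) -> None:
        if not self.c_end >= self.c0 >= 0:
            raise ValueError(f"need c_end >= c0 >= 0, got {self.c0}, {self.c_end}")
        if not self.rate > 0:
            raise ValueError(f"rate must be > 0, got {self.rate!r}")
        low, high = self.rba_range
        if not 0 < low <= high <= 1:
            raise ValueError(f"rba_range must satisfy 0 < low <= high <= 1: {self.rba_range}")
        if self.dip is not None and not 0 <= self.dip[1] < 1:
            raise ValueError(f"dip depth must be in [0, 1): {self.dip}")

    @property
    def c_asymptote(self) -> float:
        """Saturation level implied by hitting c_end at end_day."""
        sat = 1.0 - math.exp(-self.rate * self.end_day)
        return self.c0 + (self.c_end - self.c0) / sat

    def rba_target(self, day: float) -> float:
        """Linear ground-truth RBA trajectory from fresh to end-of-roast."""
        low, high = self.rba_range
        return low + (high - low) * min(day, self.end_day) / self.end_day


def accumulation_curve(profile: FoodProfile, day: float) -> float:
    """Deterministic mean fluoride concentration (mg/kg) at a roasting day.

    ``C(0) = c0`` exactly; without a dip the curve is strictly increasing
    and saturates toward the profile's asymptote.
    """
    if day < 0:
        raise ValueError(f"day must be >= 0, got {day!r}")
    c = profile.c0 + (profile.c_asymptote - profile.c0) * (
        1.0 - math.exp(-profile.rate * day)
    )
    if profile.dip is not None:
        start, depth = profile.dip
        end = start + profile.dip_span
        if start < day < end:
            bump = math.sin(math.pi * (day - start) / (end - start)) ** 2
            c *= 1.0 - depth * bump
    return c


@dataclass(frozen=True)
class IntakeGroundTruth:
    """True intake distribution for one (group, food): family + parameters."""

    group: str
    food: str
    family: str
    params: dict[str, float]
    clamp: Optional[tuple[float, float]] = None


@dataclass(frozen=True)
class StudyDesign:
    """Full synthetic study: food profiles, sampling grid, noise, surveys."""

    foods: tuple[FoodProfile, ...]
    days: tuple[int, ...] = DEFAULT_DAYS
    replicates: int = 3
    noise_cv: float = 0.05
    survey_n: int = 500
    intake_truth: tuple[IntakeGroundTruth, ...] = ()
    assay_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if list(self.days) != sorted(self.days) or self.days[0] != 0:
            raise ValueError("days must be ascending and start at 0")


def default_intake_truth(survey_clamp: bool = True) -> tuple[IntakeGroundTruth, ...]:
    """Ground-truth intake families mirroring the study's best-fit choices:
    Gumbel (max) for chili and tofu, logistic for corn, Weibull for pork;
    distribution centres sit near the survey median intakes."""
    truths = []
    family_by_food = {
        "chili": "gumbel_max",
        "tofu": "gumbel_max",
        "corn": "logistic",
        "pork": "weibull",
    }
    for group, block in DEFAULT_POPULATIONS.items():
        for food in FOODS:
            median = block["ir"][food]["median"]
            lo, hi = block["ir"][food]["min"], block["ir"][food]["max"]
            family = family_by_food[food]
            if family == "gumbel_max":
                scale = median / 5.0
                params = {"loc": median - 0.5772156649015329 * scale, "scale": scale}
            elif family == "logistic":
                params = {"loc": median, "scale": median / 5.0}
            else:  # weibull
                shape = 1.5
                params = {"shape": shape, "scale": median / math.gamma(1 + 1 / shape)}
            truths.append(
                IntakeGroundTruth(
                    group=group,
                    food=food,
                    family=family,
                    params=params,
                    clamp=(lo, hi) if survey_clamp else None,
                )
            )
    return tuple(truths)


def paper_shaped_design(
    *,
    noise_cv: float = 0.05,
    survey_n: int = 500,
    assay_noise_sd: float = 0.0,
    survey_clamp: bool = False,
) -> StudyDesign:
    """The default study: 4 foods x 7 days x 3 replicates, fresh and
    end-of-roast concentrations and bioavailability ranges matching the
    observed magnitudes for corn, chili, pork and tofu."""
    profiles = (
        FoodProfile("corn", c0=1.72, c_end=308.24, rate=0.14,
                    rba_range=(0.0392, 0.1242)),
        FoodProfile("chili", c0=8.56, c_end=869.82, rate=0.10,
                    dip=(12.5, 0.30), rba_range=(0.0218, 0.1200)),
        FoodProfile("pork", c0=6.47, c_end=141.59, rate=0.16,
                    rba_range=(0.0379, 0.0976)),
        FoodProfile("tofu", c0=6.19, c_end=265.70, rate=0.15,
                    rba_range=(0.0220, 0.1163)),
    )
    return StudyDesign(
        foods=profiles,
        noise_cv=noise_cv,
        survey_n=survey_n,
        intake_truth=default_intake_truth(survey_clamp=survey_clamp),
        assay_noise_sd=assay_noise_sd,
    )


def generate_concentration_table(
    design: StudyDesign, seed: int
) -> list[FoodConcentrationRecord]:
    """Replicate concentrations: normal(mean=curve, sd=cv*mean), clamped at 0."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0C]))
    records = []
    for profile in design.foods:
        for day in design.days:
            mean = accumulation_curve(profile, day)
            sd = design.noise_cv * mean
            draws = rng.normal(mean, sd, size=design.replicates) if sd > 0 else np.full(
                design.replicates, mean
            )
            draws = np.maximum(draws, 0.0)
            for rep, value in enumerate(draws, start=1):
                records.append(
                    FoodConcentrationRecord(
                        food=profile.food,
                        roast_day=int(day),
                        replicate=rep,
                        concentration=float(value),
                    )
                )
    return records


def generate_intake_survey(
    truth: IntakeGroundTruth, n: int, seed: int
) -> list[dict]:
    """n seeded intake draws (kg/d) for one (group, food), optionally clamped
    to the survey's (min, max).  Returns tidy records."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    frozen = family_frozen(truth.family, truth.params)  # validates family/params
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [int(seed), 0x15, _stable_key(truth.group, truth.food)]
        )
    )
    draws = np.asarray(frozen.ppf(rng.uniform(size=n)), dtype=float)
    if truth.clamp is not None:
        lo, hi = truth.clamp
        draws = np.clip(draws, lo, hi)
    return [
        {
            "person_id": f"{truth.group[:2]}-{truth.food}-{i + 1:04d}",
            "group": truth.group,
            "food": truth.food,
            "intake_kg_per_day": float(v),
        }
        for i, v in enumerate(draws)
    ]


def _stable_key(*parts) -> int:
    import hashlib

    digest = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return int.from_bytes(digest[:8], "little")


def generate_transport_assays(
    profile: FoodProfile,
    concentrations: Sequence[FoodConcentrationRecord],
    target_rba_by_day: dict[int, float],
    seed: int,
    *,
    noise_sd: float = 0.0,
    v_iv: float = DEFAULT_V_IV,
    m_s: float = DEFAULT_M_S,
) -> list[TransportAssay]:
    """Construct transwell assays that reproduce target RBA values.

    The RBA equation is inverted: the applied digestive-fluid concentration
    is set to the fully released level ``c_iv = t_s * m_s / v_iv`` (so any
    target fraction <= 1 leaves a non-negative apical concentration), and
    ``c_av = c_iv - target * t_s * m_s / v_iv``.  Optional additive normal
    noise (sd in RBA-fraction units) perturbs the target per assay.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), 0xA5, _stable_key(profile.food)])
    )
    assays = []
    by_day: dict[int, list[FoodConcentrationRecord]] = {}
    for rec in concentrations:
        if rec.food == profile.food:
            by_day.setdefault(rec.roast_day, []).append(rec)
    for day, target in sorted(target_rba_by_day.items()):
        if not 0 <= target <= 1:
            raise ValueError(f"target RBA {target!r} outside [0, 1]")
        for rec in by_day.get(day, []):
            t_s = rec.concentration
            if t_s <= 0:
                continue
            eff_target = target
            if noise_sd > 0:
                eff_target = max(0.0, target + rng.normal(0.0, noise_sd))
            c_iv = t_s * m_s / v_iv
            c_av = c_iv - eff_target * t_s * m_s / v_iv
            if c_av < 0:
                raise ValueError(
                    f"target RBA {eff_target:.4g} needs c_iv >= "
                    f"{eff_target * t_s * m_s / v_iv:.4g} mg/L; raise c_iv"
                )
            assays.append(
                TransportAssay(
                    assay_id=f"{profile.food}-d{day}-r{rec.replicate}",
                    food=profile.food,
                    roast_day=day,
                    c_iv=c_iv,
                    c_av=c_av,
                    v_iv=v_iv,
                    t_s=t_s,
                    m_s=m_s,
                )
            )
    return assays


def study_bundle(seed: int, out_dir: str | Path, design: StudyDesign | None = None) -> dict:
    """Write a complete synthetic study to ``out_dir``.

    Files: ``foods.csv``, ``assays.csv``, ``intake_survey.csv``,
    ``populations.yaml`` (exposure constants) and ``ground_truth.json``
    (curve parameters, RBA targets, intake families/parameters).  Returns
    the manifest dict.  Byte-identical across calls with the same seed.
    """
    import pandas as pd

    if design is None:
        design = paper_shaped_design()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = generate_concentration_table(design, seed)
    foods_df = pd.DataFrame(
        [
            {
                "food": r.food,
                "roast_day": r.roast_day,
                "replicate": r.replicate,
                "concentration_mg_per_kg": r.concentration,
            }
            for r in records
        ]
    )

    assays: list[TransportAssay] = []
    rba_targets: dict[str, dict[int, float]] = {}
    for profile in design.foods:
        targets = {int(d): profile.rba_target(d) for d in design.days}
        rba_targets[profile.food] = targets
        assays.extend(
            generate_transport_assays(
                profile, records, targets, seed, noise_sd=design.assay_noise_sd
            )
        )
    assays_df = pd.DataFrame(
        [
            {
                "assay_id": a.assay_id,
                "food": a.food,
                "roast_day": a.roast_day,
                "c_iv_mg_per_L": a.c_iv,
                "c_av_mg_per_L": a.c_av,
                "v_iv_L": a.v_iv,
                "t_s_mg_per_kg": a.t_s,
                "m_s_kg": a.m_s,
                "dilution_ratio": a.dilution_ratio,
                "teer_ok": a.teer_ok,
            }
            for a in assays
        ]
    )

    survey_rows: list[dict] = []
    for truth in design.intake_truth:
        survey_rows.extend(generate_intake_survey(truth, design.survey_n, seed))
    survey_df = pd.DataFrame(survey_rows)

    foods_df.to_csv(out / "foods.csv", index=False)
    assays_df.to_csv(out / "assays.csv", index=False)
    survey_df.to_csv(out / "intake_survey.csv", index=False)
    with open(out / "populations.yaml", "w") as fh:
        yaml.safe_dump(DEFAULT_POPULATIONS, fh, sort_keys=True)

    manifest = {
        "seed": int(seed),
        "design": {
            "days": list(design.days),
            "replicates": design.replicates,
            "noise_cv": design.noise_cv,
            "survey_n": design.survey_n,
            "assay_noise_sd": design.assay_noise_sd,
            "note": "replicate noise sd is noise_cv x curve mean; a stand-in, "
            "not an observed per-stage dispersion",
        },
        "curves": {
            p.food: {
                "c0": p.c0,
                "c_end": p.c_end,
                "rate": p.rate,
                "c_asymptote": p.c_asymptote,
                "dip": list(p.dip) if p.dip else None,
                "rba_range": list(p.rba_range),
            }
            for p in design.foods
        },
        "rba_targets": rba_targets,
        "intake_truth": [asdict(t) for t in design.intake_truth],
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
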