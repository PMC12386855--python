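"""Synthetic cage-trial generator.

Emulates the statistical structure the downstream analysis assumes: hatch
suppression consistent with the competitiveness index (the generator is the
algebraic inverse of the estimator, so parameter recovery is self-consistent),
a two-stage daily competing-risk chain for immature development observed
only at examination days, logit-scale between-cage overdispersion, and
zero-augmented, outlier-contaminated water concentrations with a
log-logistic emergence-inhibition dose response anchored at EI50 and EI95.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trial_model import (
    TREATMENTS,
    TREATMENT_ORDER,
    CageSpec,
    CohortCounts,
    ConcentrationSample,
    IntervalRecord,
    TrialDesign,
)

__all__ = [
    "GeneratorParams",
    "hatch_under_treatment",
    "emergence_inhibition",
    "simulate_cohort",
    "simulate_trial",
    "canonical_design",
]

_LOGIT95 = math.log(0.95 / 0.05)


@dataclass
class GeneratorParams:
    """Tunable parameters of the synthetic trial generator."""

    ph_control: float = 0.936
    cp_by_treatment: dict[str, float] = field(default_factory=lambda: {
        "SIT1": 0.229, "SIT5": 0.562, "bSIT1": 0.211, "bSIT5": 0.125,
    })
    sigma_cage: float = 0.3
    daily_molt_hazard_larva: float = 0.18
    daily_death_hazard_larva: float = 0.02
    daily_molt_hazard_pupa: float = 0.45
    daily_death_hazard_pupa: float = 0.02
    ei50_ppb: float = 0.20
    ei95_ppb: float = 0.67
    conc_zero_prob: float = 0.25
    conc_gamma_shape: float = 1.5
    conc_mean_by_condition: dict[float, float] = field(default_factory=lambda: {
        1.0: 0.3, 5.0: 1.2,
    })
    outlier_prob: float = 0.05
    outlier_mean: float = 8.0
    eggs_per_cage_mean: float = 220.0
    eggs_dispersion: float = 25.0
    traps_per_cage: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.ph_control <= 1.0):
            raise ValueError("ph_control must be in (0, 1]")
        if self.ei95_ppb <= self.ei50_ppb or self.ei50_ppb <= 0:
            raise ValueError("require ei95_ppb > ei50_ppb > 0")
        for name in ("sigma_cage", "conc_gamma_shape", "outlier_mean",
                     "eggs_per_cage_mean", "eggs_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("daily_molt_hazard_larva", "daily_death_hazard_larva",
                     "daily_molt_hazard_pupa", "daily_death_hazard_pupa",
                     "conc_zero_prob", "outlier_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.daily_molt_hazard_larva + self.daily_death_hazard_larva > 1:
            raise ValueError("larval daily hazards sum above 1")
        if self.daily_molt_hazard_pupa + self.daily_death_hazard_pupa > 1:
            raise ValueError("pupal daily hazards sum above 1")


def hatch_under_treatment(ph_control: float, cp: float, s2f: float) -> float:
    """Hatch probability under sterile-male pressure.

    Inverts the competitiveness estimator: the returned value p satisfies
    (ph_control - p) / p / s2f == cp, i.e. p = ph_control / (1 + cp * s2f).
    """
    if not (0.0 < ph_control <= 1.0):
        raise ValueError("ph_control must be in (0, 1]")
    if cp < 0 or s2f < 0:
        raise ValueError("cp and s2f must be non-negative")
    return ph_control / (1.0 + cp * s2f)


def emergence_inhibition(conc_ppb: float, ei50: float = 0.20, ei95: float = 0.67) -> float:
    """Two-parameter log-logistic adult-emergence inhibition.

    The curve is fully determined by its two anchors: EI(ei50) = 0.50 and
    EI(ei95) = 0.95 exactly, with EI(0) = 0 and EI strictly increasing.
    """
    if ei50 <= 0 or ei95 <= ei50:
        raise ValueError("require ei95 > ei50 > 0")
    if conc_ppb < 0:
        raise ValueError("concentration must be non-negative")
    if conc_ppb == 0:
        return 0.0
    slope = math.log(ei95 / ei50) / _LOGIT95
    z = (math.log(conc_ppb) - math.log(ei50)) / slope
    return 1.0 / (1.0 + math.exp(-z))


def simulate_cohort(n_larvae: int,
                    params: GeneratorParams,
                    conc_ppb: float,
                    rng: np.random.Generator,
                    *,
                    cage_id: str = "C1",
                    replicate_id: str = "R1",
                    treatment: str = "control",
                    eggs_total: int | None = None,
                    observation_interval_days: int = 2,
                    horizon_days: int = 15,
                    return_blocked: bool = False):
    """Run the daily two-stage competing-risk chain for one cage-cohort.

    Each day every larva independently dies, molts to pupa, or stays; every
    pupa dies, attempts emergence, or stays.  Pyriproxyfen multiplies the
    emergence success probability by ``1 - EI(conc)``; blocked pupae are
    removed from risk and tallied as pupal deaths at the horizon.  Events are
    recorded only at examination days, so the returned records are
    interval-censored aggregates.  Survivors at the horizon are censored.
    """
    if n_larvae < 0:
        raise ValueError("n_larvae must be non-negative")
    ei = emergence_inhibition(conc_ppb, params.ei50_ppb, params.ei95_ppb)
    dl, ml = params.daily_death_hazard_larva, params.daily_molt_hazard_larva
    dp, mp = params.daily_death_hazard_pupa, params.daily_molt_hazard_pupa

    exam_days = list(range(observation_interval_days, horizon_days + 1,
                           observation_interval_days))
    if not exam_days or exam_days[-1] != horizon_days:
        exam_days.append(horizon_days)

    larvae, pupae = n_larvae, 0
    l_death = n_death = n_meta = blocked = 0
    acc = {"larva_deaths": 0, "larva_molts": 0, "pupa_deaths": 0, "pupa_molts": 0}
    records: list[IntervalRecord] = []

    def flush(day: int) -> None:
        for stage in ("larva", "pupa"):
            deaths, molts = acc[f"{stage}_deaths"], acc[f"{stage}_molts"]
            if deaths or molts:
                records.append(IntervalRecord(cage_id=cage_id, day=day, stage=stage,
                                              deaths=deaths, molts=molts))
            acc[f"{stage}_deaths"] = acc[f"{stage}_molts"] = 0

    for day in range(1, horizon_days + 1):
        if larvae > 0:
            died, molted, _ = rng.multinomial(larvae, [dl, ml, 1.0 - dl - ml])
            larvae -= died + molted
            l_death += died
            acc["larva_deaths"] += died
            acc["larva_molts"] += molted
        else:
            molted = 0
        if pupae > 0:
            died, attempted, _ = rng.multinomial(pupae, [dp, mp, 1.0 - dp - mp])
            emerged = rng.binomial(attempted, 1.0 - ei) if attempted else 0
            pupae -= died + attempted
            n_death += died
            n_meta += emerged
            blocked += attempted - emerged
            acc["pupa_deaths"] += died
            acc["pupa_molts"] += emerged
        pupae += molted  # new pupae enter risk the following day
        if day in exam_days:
            if day == horizon_days and blocked:
                acc["pupa_deaths"] += blocked  # blocked emergences surface at horizon
            flush(day)
    censored = larvae + pupae

    counts = CohortCounts(
        cage_id=cage_id, replicate_id=replicate_id, treatment=treatment,
        eggs_total=n_larvae if eggs_total is None else eggs_total,
        eggs_hatched=n_larvae, e_meta=n_larvae,
        l_death=l_death, n_death=n_death + blocked, n_meta=n_meta,
        censored=censored,
    )
    if return_blocked:
        return counts, records, blocked
    return counts, records


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _cage_rng(seed: int, index: int) -> np.random.Generator:
    # indexed substreams: adding cages never reshuffles existing ones
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def simulate_trial(design: TrialDesign, params: GeneratorParams) -> tuple[
        list[CohortCounts], list[IntervalRecord], list[ConcentrationSample]]:
    """Generate a complete synthetic trial dataset for ``design``.

    Per cage: overdispersed egg totals, binomial hatch at the competitiveness-
    consistent probability jittered by a logit-scale cage effect, ovitrap
    concentrations from a zero-augmented gamma with outlier contamination
    (boosted cages only), and the immature cohort chain of
    :func:`simulate_cohort`.  Fully reproducible from ``params.seed``.
    """
    cohorts: list[CohortCounts] = []
    intervals: list[IntervalRecord] = []
    water: list[ConcentrationSample] = []

    for idx, cage in enumerate(design.cages):
        rng = _cage_rng(params.seed, idx)
        t = cage.treatment
        cp = params.cp_by_treatment.get(t.label, 0.0) if t.s2f > 0 else 0.0
        p_hatch = hatch_under_treatment(params.ph_control, cp, t.s2f)
        if params.sigma_cage > 0:
            p_hatch = _expit(_logit(p_hatch) + params.sigma_cage * rng.standard_normal())

        if params.eggs_dispersion > 0:
            k = params.eggs_dispersion
            eggs_total = int(rng.negative_binomial(k, k / (k + params.eggs_per_cage_mean)))
        else:
            eggs_total = int(rng.poisson(params.eggs_per_cage_mean))
        eggs_hatched = int(rng.binomial(eggs_total, p_hatch)) if eggs_total else 0

        concs = []
        for _ in range(params.traps_per_cage):
            if not t.boosted:
                c = 0.0
            elif rng.random() < params.conc_zero_prob:
                c = 0.0
            else:
                mean = params.conc_mean_by_condition.get(float(t.s2f), 1.0)
                if rng.random() < params.outlier_prob:
                    mean = params.outlier_mean
                shape = params.conc_gamma_shape
                c = float(rng.gamma(shape, mean / shape))
            concs.append(c)
            water.append(ConcentrationSample(
                cage_id=cage.cage_id, replicate_id=cage.replicate_id,
                concentration=c, females_present=cage.n_females > 0,
                fertile_males_present=cage.n_fertile_males > 0,
                s2f=t.s2f, boosted_dose_mg_per_200=2.0 if t.boosted else 0.0,
            ))
        cage_conc = float(np.mean(concs)) if concs else 0.0

        counts, records = simulate_cohort(
            eggs_hatched, params, cage_conc if t.boosted else 0.0, rng,
            cage_id=cage.cage_id, replicate_id=cage.replicate_id,
            treatment=t.label, eggs_total=eggs_total,
            observation_interval_days=design.observation_interval_days,
            horizon_days=design.horizon_days,
        )
        cohorts.append(counts)
        intervals.extend(records)
    return cohorts, intervals, water


def canonical_design(replicates: int = 4,
                     n_females: int = 40,
                     n_fertile_males: int = 40) -> TrialDesign:
    """The 5-treatment x ``replicates`` layout used throughout the trial."""
    cages = []
    for r in range(1, replicates + 1):
        for label in TREATMENT_ORDER:
            t = TREATMENTS[label]
            cages.append(CageSpec(
                cage_id=f"{label}-R{r}", replicate_id=f"R{r}", treatment=t,
                n_females=n_females, n_fertile_males=n_fertile_males,
                n_sterile_males=int(round(t.s2f * n_fertile_males)),
            ))
    return TrialDesign(replicates=replicates, cages=cages)
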