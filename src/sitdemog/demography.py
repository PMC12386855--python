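"""Aggregation of interval-censored stage events and the corrected
emergence probability.

The emergence probability of adults from larvae is estimated from the count
of emerged adults over an exposure denominator corrected for the competing
molting and death processes: half of the larval and pupal deaths are removed
from the initial number of larvae,

    Pa = n_meta / (e_meta - (l_death + n_death) / 2).
"""

from __future__ import annotations

from dataclasses import dataclass

from .trial_model import CohortCounts, IntervalRecord, SchemaError, TrialDesign

__all__ = [
    "CorrectedTrials",
    "UndefinedEstimateError",
    "aggregate_intervals",
    "corrected_emergence",
    "corrected_trials",
]


class UndefinedEstimateError(ValueError):
    """The corrected exposure denominator is non-positive."""


@dataclass(frozen=True)
class CorrectedTrials:
    """Corrected binomial numerator/denominator for one cage-cohort.

    ``denominator_raw`` is the exact corrected exposure; ``denominator_int``
    is its round-half-to-even integer form usable in a binomial likelihood.
    ``inconsistent`` marks cohorts where the numerator exceeds the rounded
    denominator (possible under heavy censoring) — reported, never clipped.
    """

    cage_id: str
    numerator: int
    denominator_raw: float
    denominator_int: int
    inconsistent: bool = False


def aggregate_intervals(records: list[IntervalRecord],
                        design: TrialDesign,
                        e_meta: dict[str, int],
                        *,
                        cohort_meta: dict[str, tuple[str, str]] | None = None,
                        eggs: dict[str, tuple[int, int]] | None = None,
                        ) -> list[CohortCounts]:
    """Tally per-cage stage events; censored counts follow by conservation.

    ``e_meta`` maps cage_id to the number of hatched larvae entering
    monitoring.  ``cohort_meta`` optionally supplies (replicate_id, treatment)
    per cage and ``eggs`` supplies (eggs_total, eggs_hatched); both default
    to values derived from the design / e_meta.
    """
    by_cage: dict[str, dict[str, int]] = {
        cid: {"l_death": 0, "n_death": 0, "n_meta": 0, "larva_molts": 0}
        for cid in e_meta
    }
    for rec in records:
        if rec.cage_id not in by_cage:
            raise SchemaError(f"interval record for unknown cage {rec.cage_id!r}")
        if rec.day > design.horizon_days:
            raise SchemaError(
                f"cage {rec.cage_id!r}: examination day {rec.day} beyond horizon")
        tally = by_cage[rec.cage_id]
        if rec.stage == "larva":
            tally["l_death"] += rec.deaths
            tally["larva_molts"] += rec.molts
        else:
            tally["n_death"] += rec.deaths
            tally["n_meta"] += rec.molts

    cage_specs = design.cage_index()
    out: list[CohortCounts] = []
    for cid, n0 in e_meta.items():
        t = by_cage[cid]
        if t["l_death"] + t["larva_molts"] > n0:
            raise SchemaError(
                f"cage {cid!r}: larval events {t['l_death'] + t['larva_molts']} "
                f"exceed e_meta {n0}")
        if t["n_death"] + t["n_meta"] > t["larva_molts"]:
            raise SchemaError(
                f"cage {cid!r}: pupal events {t['n_death'] + t['n_meta']} "
                f"exceed pupations {t['larva_molts']}")
        censored = n0 - t["l_death"] - t["n_death"] - t["n_meta"]
        if cohort_meta and cid in cohort_meta:
            replicate_id, treatment = cohort_meta[cid]
        elif cid in cage_specs:
            spec = cage_specs[cid]
            replicate_id, treatment = spec.replicate_id, spec.treatment.label
        else:
            replicate_id, treatment = "", ""
        eggs_total, eggs_hatched = (eggs or {}).get(cid, (n0, n0))
        out.append(CohortCounts(
            cage_id=cid, replicate_id=replicate_id, treatment=treatment,
            eggs_total=eggs_total, eggs_hatched=eggs_hatched, e_meta=n0,
            l_death=t["l_death"], n_death=t["n_death"], n_meta=t["n_meta"],
            censored=censored,
        ))
    return out


def corrected_emergence(counts: CohortCounts) -> float:
    """Plug-in corrected emergence probability for one cage-cohort.

    Raises :class:`UndefinedEstimateError` when the corrected denominator is
    non-positive.  A ratio above 1 (possible under heavy censoring) is
    returned as-is; callers should check :func:`corrected_trials` for the
    inconsistency flag rather than rely on silent clipping.
    """
    denom = counts.e_meta - (counts.l_death + counts.n_death) / 2.0
    if denom <= 0:
        raise UndefinedEstimateError(
            f"cage {counts.cage_id!r}: corrected denominator {denom} <= 0")
    return counts.n_meta / denom


def corrected_trials(counts: CohortCounts) -> CorrectedTrials:
    """Corrected numerator/denominator with a banker's-rounded integer form."""
    denom = counts.e_meta - (counts.l_death + counts.n_death) / 2.0
    if denom <= 0:
        raise UndefinedEstimateError(
            f"cage {counts.cage_id!r}: corrected denominator {denom} <= 0")
    denom_int = round(denom)  # Python round = round-half-to-even
    return CorrectedTrials(
        cage_id=counts.cage_id,
        numerator=counts.n_meta,
        denominator_raw=denom,
        denominator_int=denom_int,
        inconsistent=counts.n_meta > denom_int,
    )
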