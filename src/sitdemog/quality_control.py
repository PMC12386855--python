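"""Rearing-quality indicators: hatch and flight-test escape probabilities.

Batches of eggs (hatch) or males (flight-test escape) are modelled with the
same mixed binomial machinery as the trial analysis, with the batch as the
observation level.  A category passes quality control when its estimated
probability exceeds the 0.70 threshold; the pass flag uses the posterior
point estimate, and the one-sided posterior probability Pr(P > 0.70) is
reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes_binomial import (
    ProbabilitySummary,
    RankWarning,
    aggregate_by_treatment,
    fit_binomial_mixed,
    summarize,
)
from .efficacy import RelativeRiskSummary

__all__ = ["QualityBatch", "QualitySummary", "QUALITY_THRESHOLD",
           "quality_estimate", "quality_rr", "read_quality"]

QUALITY_THRESHOLD = 0.70

_CATEGORIES = ("fertile", "sterile", "boosted_sterile", "control")


@dataclass(frozen=True)
class QualityBatch:
    batch_id: str
    category: str
    n_total: int
    n_event: int

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not (0 <= self.n_event <= self.n_total):
            raise ValueError(
                f"batch {self.batch_id!r}: require 0 <= n_event <= n_total")


@dataclass(frozen=True)
class QualitySummary:
    summary: ProbabilitySummary
    passes: bool                    # point estimate above the 0.70 threshold
    prob_above_threshold: float     # Pr(P > 0.70 | data)


def read_quality(path) -> list[QualityBatch]:
    df = pd.read_csv(path)
    required = ["batch_id", "category", "n_total", "n_event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [QualityBatch(str(r.batch_id), str(r.category),
                         int(r.n_total), int(r.n_event))
            for r in df.itertuples()]


def quality_estimate(batches: list[QualityBatch],
                     n_draws: int = 4_000,
                     seed: int = 0,
                     threshold: float = QUALITY_THRESHOLD,
                     **fit_kwargs) -> dict[str, QualitySummary]:
    """Posterior summaries per category with pass/fail against the threshold."""
    if not batches:
        raise ValueError("no quality batches supplied")
    successes = [b.n_event for b in batches]
    trials = [b.n_total for b in batches]
    categories = [b.category for b in batches]
    labels = [(b.batch_id, "", b.category) for b in batches]
    with warnings.catch_warnings():
        # a single-category quality table is a legitimate use, not a design flaw
        warnings.simplefilter("ignore", RankWarning)
        fit = fit_binomial_mixed(successes, trials, categories, n_draws=n_draws,
                                 seed=seed, row_labels=labels, **fit_kwargs)
    per_cat = aggregate_by_treatment(fit)
    out = {}
    for s in summarize(per_cat):
        draws = per_cat.row(s.treatment)
        out[s.treatment] = QualitySummary(
            summary=s,
            passes=s.mean > threshold,
            prob_above_threshold=float(np.mean(draws > threshold)),
        )
    return out


def quality_rr(p_draws: np.ndarray, ref_draws: np.ndarray,
               *, treatment: str = "", reference: str = "ref",
               alpha: float = 0.05) -> RelativeRiskSummary:
    """Draw-wise relative risk of one category against a reference.

    Shares the zero-exclusion contract of the trial relative-risk machinery:
    zero reference draws are dropped, never clamped.
    """
    p_draws = np.asarray(p_draws, dtype=float)
    ref_draws = np.asarray(ref_draws, dtype=float)
    if p_draws.shape != ref_draws.shape:
        raise ValueError("draw vectors must be aligned")
    ok = ref_draws > 0
    if not ok.any():
        raise ZeroDivisionError("all reference draws are zero")
    rr = p_draws[ok] / ref_draws[ok]
    ll, ul = np.quantile(rr, [alpha / 2.0, 1.0 - alpha / 2.0])
    return RelativeRiskSummary(
        treatment=treatment, rr_mean=float(rr.mean()), ll=float(ll), ul=float(ul),
        reference_label=reference, excluded_draws=int((~ok).sum()))
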