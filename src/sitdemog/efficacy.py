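"""Headline efficacy statistics: competitiveness, emergence products,
relative risks, and the posterior simulation test for efficacy loss.

All draw-wise statistics are posterior means of per-draw ratios or
differences (never ratios of means); plug-in values computed from point
probabilities are reported alongside, since published summary tables permit
exact desk checks of those.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bayes_binomial import PosteriorMatrix, TreatmentPosterior

__all__ = [
    "CompetitivenessSummary",
    "RelativeRiskSummary",
    "DeltaTestResult",
    "competitiveness_plugin",
    "competitiveness_posterior",
    "emergence_product",
    "relative_risk",
    "delta_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompetitivenessSummary:
    treatment: str
    cp_mean: float
    ll: float
    ul: float
    cp_plugin: float
    excluded_draws: int = 0


@dataclass(frozen=True)
class RelativeRiskSummary:
    treatment: str
    rr_mean: float
    ll: float
    ul: float
    reference_label: str
    rr_plugin: float | None = None
    excluded_draws: int = 0


@dataclass(frozen=True)
class DeltaTestResult:
    group_a: str
    group_b: str
    delta_mean: float
    p_value: float
    B: int
    direction: str  # "less" | "greater"


def competitiveness_plugin(ph_control: float, ph_i: float, s2f: float) -> float:
    """Sterile-male competitiveness from point hatch probabilities:
    (ph_control - ph_i) / ph_i / s2f."""
    if s2f <= 0:
        raise ValueError("s2f must be positive (undefined for control)")
    if ph_i <= 0:
        raise ZeroDivisionError(
            "treatment hatch probability is 0 — competitiveness undefined "
            "(separation-linked: check detect_separation output)")
    return (ph_control - ph_i) / ph_i / s2f


def competitiveness_posterior(hatch: TreatmentPosterior,
                              treatment: str,
                              s2f: float,
                              *,
                              control_label: str = "control",
                              alpha: float = 0.05) -> CompetitivenessSummary:
    """Draw-wise competitiveness with posterior mean and credible limits.

    Zero treatment draws are excluded with a logged count rather than
    clamped: a zero is impossible under the logistic model, so any
    occurrence signals an upstream bug worth surfacing.
    """
    if treatment == control_label:
        raise ValueError("competitiveness is undefined for the control group")
    control = hatch.row(control_label)
    treat = hatch.row(treatment)
    ok = treat > 0
    excluded = int((~ok).sum())
    if excluded:
        logger.warning("competitiveness_posterior(%s): excluded %d zero draws",
                       treatment, excluded)
    if not ok.any():
        raise ZeroDivisionError(f"all draws for {treatment!r} are zero")
    cp = (control[ok] - treat[ok]) / treat[ok] / s2f
    ll, ul = np.quantile(cp, [alpha / 2.0, 1.0 - alpha / 2.0])
    return CompetitivenessSummary(
        treatment=treatment, cp_mean=float(cp.mean()), ll=float(ll), ul=float(ul),
        cp_plugin=competitiveness_plugin(float(control.mean()), float(treat.mean()), s2f),
        excluded_draws=excluded)


def emergence_product(hatch: PosteriorMatrix, emergence: PosteriorMatrix) -> PosteriorMatrix:
    """Element-wise product matrix: per-row, per-draw probability of an adult
    emerging from an egg.  Rows and draws must already be aligned."""
    if hatch.row_labels != emergence.row_labels:
        raise ValueError("row labels differ between hatch and emergence matrices; "
                         "refusing to reindex silently")
    if hatch.draws.shape != emergence.draws.shape:
        raise ValueError("draw counts differ between hatch and emergence matrices")
    return PosteriorMatrix(
        row_labels=list(hatch.row_labels),
        draws=hatch.draws * emergence.draws,
        treatment_levels=list(hatch.treatment_levels),
    )


def relative_risk(posterior: TreatmentPosterior,
                  reference: str = "control",
                  *,
                  alpha: float = 0.05) -> list[RelativeRiskSummary]:
    """Per-treatment draw-wise risk ratio against ``reference``.

    Returns the posterior mean of the per-draw ratio plus equal-tailed
    credible limits; the plug-in ratio of posterior means is attached for
    desk checks.  Reference draws equal to zero are excluded with a logged
    count (shared contract with competitiveness).
    """
    ref = posterior.row(reference)
    ok = ref > 0
    excluded = int((~ok).sum())
    if excluded:
        logger.warning("relative_risk: excluded %d zero reference draws", excluded)
    if not ok.any():
        raise ZeroDivisionError("all reference draws are zero")
    out = []
    for label, draws in zip(posterior.treatment_labels, posterior.draws):
        rr = draws[ok] / ref[ok]
        ll, ul = np.quantile(rr, [alpha / 2.0, 1.0 - alpha / 2.0])
        ref_mean = float(ref.mean())
        out.append(RelativeRiskSummary(
            treatment=label, rr_mean=float(rr.mean()), ll=float(ll), ul=float(ul),
            reference_label=reference,
            rr_plugin=float(draws.mean()) / ref_mean if ref_mean > 0 else None,
            excluded_draws=excluded))
    return out


def delta_test(posterior: TreatmentPosterior,
               group_a: str,
               group_b: str,
               B: int = 10_000,
               *,
               direction: str = "less") -> DeltaTestResult:
    """Posterior simulation test on delta = P(group_a) - P(group_b).

    Uses the first ``B`` aligned draw pairs.  The reported p-value is the
    posterior probability of the stated alternative, ties counted as
    consistent: for ``direction="less"`` (alternative delta < 0) it is
    Pr(delta <= 0).  Identical groups therefore give p = 1, and a group_a
    everywhere above group_b gives p = 0 under "less".  The direction is
    recorded in the result so the convention is always explicit.
    """
    if direction not in ("less", "greater"):
        raise ValueError("direction must be 'less' or 'greater'")
    a = posterior.row(group_a)
    b = posterior.row(group_b)
    if B > a.shape[0]:
        raise ValueError(f"B={B} exceeds available draws {a.shape[0]}")
    delta = a[:B] - b[:B]
    if direction == "less":
        p = float(np.mean(delta <= 0.0))
    else:
        p = float(np.mean(delta >= 0.0))
    return DeltaTestResult(group_a=group_a, group_b=group_b,
                           delta_mean=float(delta.mean()), p_value=p,
                           B=B, direction=direction)
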