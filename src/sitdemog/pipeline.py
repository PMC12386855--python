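"""End-to-end orchestration: simulate -> aggregate -> fit -> efficacy -> report.

A single configuration seed drives every random stage through named
substreams (one fixed stream index per stage), so changing the draw count of
one stage never perturbs another, and two runs with the same configuration
produce byte-identical JSON reports.

The machine-readable report stores floats at full precision; the
human-readable table rounds to 3 decimals and orders treatments from the
most to the least effective (ascending relative risk).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes_binomial import (
    PosteriorMatrix,
    aggregate_by_treatment,
    detect_separation,
    fit_binomial_mixed,
    summarize,
)
from .demography import corrected_trials
from .efficacy import (
    competitiveness_posterior,
    delta_test,
    emergence_product,
    relative_risk,
)
from .pyriproxyfen_glm import design_from_frame, fit_zag, flag_outliers, lrt
from .synthetic_data import GeneratorParams, canonical_design, simulate_trial
from .trial_model import (
    TREATMENTS,
    CohortCounts,
    TrialDesign,
    read_trial,
    validate_design,
    write_trial,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

# fixed substream indices per stage (see module docstring)
_STAGE_STREAMS = {"simulate": 0, "fit_hatch": 1, "fit_emergence": 2, "qc": 3}


class ConfigError(ValueError):
    """The pipeline configuration is malformed."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([seed, _STAGE_STREAMS[stage]])
               .generate_state(1)[0])


def load_config(path: str | Path) -> dict:
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from None
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return raw


# ---------------------------------------------------------------------------
# posterior container (de)serialization

def save_posterior(path: str | Path, matrix: PosteriorMatrix) -> None:
    np.savez(path,
             draws=matrix.draws,
             row_labels=np.array(["\t".join(lab) for lab in matrix.row_labels]),
             treatment_levels=np.array(matrix.treatment_levels),
             beta_draws=(matrix.beta_draws if matrix.beta_draws is not None
                         else np.empty((0, 0))),
             sigma_draws=(matrix.sigma_draws if matrix.sigma_draws is not None
                          else np.empty(0)))


def load_posterior(path: str | Path) -> PosteriorMatrix:
    with np.load(path, allow_pickle=False) as data:
        beta = data["beta_draws"]
        sigma = data["sigma_draws"]
        return PosteriorMatrix(
            row_labels=[tuple(s.split("\t")) for s in data["row_labels"]],
            draws=data["draws"],
            treatment_levels=list(data["treatment_levels"]),
            beta_draws=beta if beta.size else None,
            sigma_draws=sigma if sigma.size else None)


# ---------------------------------------------------------------------------
# stages

def fit_stage(cohorts: list[CohortCounts], response: str, n_draws: int,
              seed: int, **fit_kwargs) -> tuple[PosteriorMatrix, list]:
    """Fit the mixed binomial model for one response; returns the posterior
    matrix plus separation flags."""
    labels = [(c.cage_id, c.replicate_id, c.treatment) for c in cohorts]
    if response == "hatch":
        successes = [c.eggs_hatched for c in cohorts]
        trials = [c.eggs_total for c in cohorts]
    elif response == "emergence":
        corrected = [corrected_trials(c) for c in cohorts]
        successes = [ct.numerator for ct in corrected]
        trials = [ct.denominator_int for ct in corrected]
        bad = [ct.cage_id for ct in corrected if ct.inconsistent]
        if bad:
            raise StageError("fit_emergence",
                             f"numerator exceeds corrected denominator in cages {bad}")
    else:
        raise ValueError("response must be 'hatch' or 'emergence'")
    treatments = [c.treatment for c in cohorts]
    matrix = fit_binomial_mixed(successes, trials, treatments, n_draws=n_draws,
                                seed=seed, row_labels=labels, **fit_kwargs)
    flags = detect_separation(successes, trials, treatments, fit=matrix)
    return matrix, flags


def efficacy_stage(hatch: PosteriorMatrix, emergence: PosteriorMatrix,
                   B: int | None = None) -> dict:
    th = aggregate_by_treatment(hatch)
    ta = aggregate_by_treatment(emergence)
    me = emergence_product(hatch, emergence)
    te = aggregate_by_treatment(me)

    result: dict[str, Any] = {
        "hatch_probability": [dataclasses.asdict(s) for s in summarize(th)],
        "emergence_probability": [dataclasses.asdict(s) for s in summarize(ta)],
        "egg_to_adult_probability": [dataclasses.asdict(s) for s in summarize(te)],
    }
    cps = []
    for label in th.treatment_labels:
        if label == "control":
            continue
        s2f = TREATMENTS[label].s2f if label in TREATMENTS else 1.0
        cps.append(dataclasses.asdict(
            competitiveness_posterior(th, label, s2f)))
    result["competitiveness"] = cps
    rrs = [dataclasses.asdict(r)
           for r in relative_risk(te, "control")] if "control" in te.treatment_labels else []
    result["relative_risk"] = sorted(rrs, key=lambda r: r["rr_mean"])
    B = B or th.draws.shape[1]
    deltas = []
    for a, b in (("bSIT1", "SIT1"), ("bSIT5", "SIT5")):
        if a in th.treatment_labels and b in th.treatment_labels:
            deltas.append(dataclasses.asdict(
                delta_test(th, a, b, B=min(B, th.draws.shape[1]), direction="less")))
    result["efficacy_loss"] = deltas
    return result


def water_stage(water_rows, terms: list[str]) -> dict:
    frame = pd.DataFrame([{
        "concentration_ppb": w.concentration, "s2f": w.s2f,
        "females_present": w.females_present,
        "fertile_males_present": w.fertile_males_present,
    } for w in water_rows])
    boosted = frame[frame["s2f"] > 0].reset_index(drop=True)
    if len(boosted) < len(terms) + 3 or (boosted["concentration_ppb"] > 0).sum() < 2:
        raise StageError("water", "too few boosted-cage measurements to fit")
    y = boosted["concentration_ppb"].to_numpy()
    x_full, labels = design_from_frame(boosted, terms)
    null_fit = fit_zag(y, design_labels=[])
    full_fit = fit_zag(y, x_full, design_labels=labels)
    test = lrt(null_fit, full_fit)
    return {
        "n_obs": int(full_fit.n_obs),
        "terms": labels,
        "zero_coefs": [float(v) for v in full_fit.zero_coefs],
        "positive_coefs": [float(v) for v in full_fit.pos_coefs],
        "shape": float(full_fit.shape),
        "log_likelihood": float(full_fit.log_likelihood),
        "lrt_vs_intercept": dataclasses.asdict(test),
        "outlier_flags": int(flag_outliers(y).sum()),
    }


# ---------------------------------------------------------------------------
# the pipeline

def run_pipeline(config: dict, seed: int, out_dir: str | Path,
                 draws: int | None = None) -> dict:
    """Run every configured stage in order and write ``report.json`` plus a
    human-readable ``report.txt`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    draws = int(draws or config.get("draws", 4000))
    log: list[dict] = []

    def note(stage: str, message: str) -> None:
        logger.info("[%s] %s", stage, message)
        log.append({"stage": stage, "message": message})

    # -- data ---------------------------------------------------------------
    if "simulate" in config:
        sim_cfg = dict(config["simulate"] or {})
        replicates = int(sim_cfg.pop("replicates", 4))
        try:
            params = GeneratorParams(seed=stage_seed(seed, "simulate"), **sim_cfg)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad simulate parameters: {exc}") from None
        design = canonical_design(replicates=replicates)
        cohorts, intervals, water = simulate_trial(design, params)
        data_dir = out_dir / "data"
        write_trial(data_dir, design, cohorts, intervals, water)
        note("simulate", f"wrote synthetic trial ({len(cohorts)} cohorts)")
        design, intervals, cohorts, water = read_trial(data_dir)
    elif "data_dir" in config:
        design, intervals, cohorts, water = read_trial(config["data_dir"])
        note("read", f"read trial tables from {config['data_dir']}")
    else:
        raise ConfigError("config needs either a 'simulate' section or 'data_dir'")

    for message in validate_design(design):
        note("validate", message)

    # -- fits ---------------------------------------------------------------
    hatch, hatch_flags = fit_stage(cohorts, "hatch", draws,
                                   stage_seed(seed, "fit_hatch"))
    for f in hatch_flags:
        note("fit_hatch", f"separation: {f.kind} {f.target} — {f.detail}")
    note("fit_hatch", f"converged={hatch.diagnostics['converged']} "
                      f"max_rhat={hatch.diagnostics['max_rhat']:.4f}")
    emergence, em_flags = fit_stage(cohorts, "emergence", draws,
                                    stage_seed(seed, "fit_emergence"))
    for f in em_flags:
        note("fit_emergence", f"separation: {f.kind} {f.target} — {f.detail}")
    note("fit_emergence", f"converged={emergence.diagnostics['converged']} "
                          f"max_rhat={emergence.diagnostics['max_rhat']:.4f}")

    # -- efficacy -----------------------------------------------------------
    efficacy = efficacy_stage(hatch, emergence)

    # -- water --------------------------------------------------------------
    water_result = None
    if water:
        try:
            water_result = water_stage(water, list(config.get("water_terms", ["s2f"])))
        except StageError as exc:
            note("water", f"skipped: {exc}")
    else:
        note("water", "skipped: no water table")

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": seed,
        "draws": draws,
        "efficacy": efficacy,
        "water": water_result,
        "diagnostics": {
            "hatch": _diag(hatch), "emergence": _diag(emergence),
        },
        "log": log,
    }
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, allow_nan=True) + "\n")
    (out_dir / "report.txt").write_text(render_report(report))
    return report


def _diag(matrix: PosteriorMatrix) -> dict:
    d = matrix.diagnostics
    return {"converged": d["converged"], "max_rhat": float(d["max_rhat"]),
            "min_ess": float(d["min_ess"])}


def render_report(report: dict) -> str:
    """Human-readable summary, treatments ordered most-to-least effective."""
    lines = [f"sitdemog report (schema v{report['schema_version']}, "
             f"seed {report['seed']}, {report['draws']} draws)", ""]
    lines.append("Relative risk of adult emergence vs control "
                 "(most effective first):")
    for rr in report["efficacy"]["relative_risk"]:
        if rr["treatment"] == rr["reference_label"]:
            continue
        lines.append(f"  {rr['treatment']:>6}  RR = {rr['rr_mean']:.3f} "
                     f"[{rr['ll']:.3f}; {rr['ul']:.3f}]")
    lines.append("")
    lines.append("Hatch probability:")
    for s in report["efficacy"]["hatch_probability"]:
        lines.append(f"  {s['treatment']:>6}  {s['mean']:.3f} "
                     f"[{s['ll']:.3f}; {s['ul']:.3f}]")
    lines.append("")
    lines.append("Competitiveness:")
    for c in report["efficacy"]["competitiveness"]:
        lines.append(f"  {c['treatment']:>6}  Cp = {c['cp_mean']:.3f} "
                     f"[{c['ll']:.3f}; {c['ul']:.3f}]")
    lines.append("")
    for d in report["efficacy"]["efficacy_loss"]:
        lines.append(f"Efficacy loss {d['group_a']} vs {d['group_b']}: "
                     f"delta = {d['delta_mean']:.3f}, "
                     f"p({d['direction']}) = {d['p_value']:.4f}, B = {d['B']}")
    if report.get("water"):
        w = report["water"]
        t = w["lrt_vs_intercept"]
        lines.append("")
        lines.append(f"Water model ({', '.join(w['terms']) or 'intercept'}): "
                     f"LRT chi2 = {t['statistic']:.2f}, df = {t['df']}, "
                     f"p = {t['p_value']:.3f}")
    lines.append("")
    return "\n".join(lines)
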