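"""End-to-end analysis pipeline.

Orchestrates the three analysis stages over a collection of vial series:

1. primary stage — aggregate replicates per concentration, normalize, fit
   the selected sigmoid models, and tabulate (s_dvp, t_mid, lag,
   diagnostics) per model x concentration;
2. secondary stage — regress each parameter against concentration with
   linear and bilinear reaction norms, compare by SSE-based AIC, and
   attach residual-bootstrap confidence intervals;
3. sampling-frequency stage — repeat 1–2 on daily-schedule-thinned copies
   of the data to quantify how reduced observation frequency degrades the
   secondary fit.

Outputs are plain DataFrames / JSON-able dicts; floating-point output is
formatted at 6 significant digits so identical configs and seeds produce
byte-identical files. Every secondary result embeds a hash of its input
parameter table and the bootstrap seed for traceability.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from importlib import resources

import numpy as np
import pandas as pd

from ._exceptions import DegenerateCurveError, DevKineticsError, EmptyCurveError
from .data_io import VialSeries, aggregate_replicates, normalize_curve
from .primary import fit_dose_response, fit_gompertz, fit_logit_linear
from .secondary import compare_linear_bilinear, residual_bootstrap_bilinear
from .synthetic import downsample_schedule
from .viability import viability_stats

logger = logging.getLogger("devkinetics")

__all__ = [
    "PRIMARY_FITTERS",
    "run_primary_table",
    "run_secondary_table",
    "sampling_frequency_experiment",
    "run_viability",
    "load_fixture_table",
    "reproduce_reference_tables",
    "format_table",
]

PRIMARY_FITTERS = {
    "gompertz": fit_gompertz,
    "dose_response": fit_dose_response,
    "logit": fit_logit_linear,
}

PARAM_TABLE_COLUMNS = [
    "model",
    "concentration_M",
    "s_dvp",
    "t_mid",
    "lambda",
    "sse",
    "r2",
    "nrmse",
    "n_points",
    "status",
]


def run_primary_table(
    vials: list[VialSeries],
    models=("gompertz", "dose_response", "logit"),
    response: str = "pupae",
) -> pd.DataFrame:
    """Fit the selected primary models at every concentration.

    Returns one row per (model x concentration). Concentrations whose
    curves cannot be fitted (no survivors, or no interior points) appear
    as rows with NaN parameters and the failure reason in ``status``.
    """
    unknown = set(models) - set(PRIMARY_FITTERS)
    if unknown:
        raise ValueError(f"unknown primary model(s): {sorted(unknown)}")
    concs = sorted({v.concentration for v in vials if v.response == response})
    if not concs:
        raise ValueError("no vials with the requested response type")
    rows = []
    n_ok = 0
    for E in concs:
        curve = None
        reason = None
        try:
            curve = normalize_curve(aggregate_replicates(vials, E, response=response))
        except (EmptyCurveError, DevKineticsError) as exc:
            reason = str(exc)
        for model in models:
            row = {"model": model, "concentration_M": E, "status": "ok"}
            if curve is None:
                row.update(status=f"skipped: {reason}")
            else:
                try:
                    fit = PRIMARY_FITTERS[model](curve)
                    row.update(
                        s_dvp=fit.s_dvp,
                        t_mid=fit.t_mid,
                        sse=fit.sse,
                        r2=fit.r2,
                        nrmse=fit.nrmse,
                        n_points=fit.n_points,
                    )
                    row["lambda"] = fit.lam
                    n_ok += 1
                except DevKineticsError as exc:
                    row.update(status=f"failed: {exc}")
                    logger.warning("%s at %g M: %s", model, E, exc)
            rows.append(row)
    if n_ok == 0:
        raise DegenerateCurveError("every concentration was degenerate; nothing fitted")
    df = pd.DataFrame(rows)
    for col in PARAM_TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[PARAM_TABLE_COLUMNS]


def _table_hash(df: pd.DataFrame) -> str:
    payload = df.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_secondary_table(
    param_table: pd.DataFrame,
    parameters=("s_dvp", "t_mid"),
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Secondary reaction-norm modeling for every (model x parameter).

    ``param_table`` is the output of :func:`run_primary_table` (or a
    fixture table with at least model/concentration_M plus the parameter
    columns). Returns a JSON-able dict keyed ``"<model>:<parameter>"``.
    """
    results = {"input_hash": _table_hash(param_table), "seed": seed, "fits": {}}
    for model, grp in param_table.groupby("model", sort=True):
        for param in parameters:
            if param not in grp.columns:
                continue
            sub = grp.dropna(subset=[param]).sort_values("concentration_M")
            x = sub["concentration_M"].to_numpy(dtype=float)
            y = sub[param].to_numpy(dtype=float)
            if x.size < 5:
                logger.warning(
                    "%s/%s: only %d usable concentrations; skipping secondary fit",
                    model, param, x.size,
                )
                results["fits"][f"{model}:{param}"] = {
                    "status": f"skipped: {x.size} points"
                }
                continue
            lin, bil, delta = compare_linear_bilinear(x, y, parameter_name=param)
            cis = residual_bootstrap_bilinear(x, y, n_boot=n_boot, seed=seed)
            results["fits"][f"{model}:{param}"] = {
                "status": "ok",
                "model": model,
                "parameter": param,
                "n_points": int(x.size),
                "linear": {"a": lin.coef["a"], "b": lin.coef["b"],
                           "sse": lin.sse, "aic": lin.aic,
                           "r2": lin.r2, "nrmse": lin.nrmse},
                "bilinear": {**bil.coef, "sse": bil.sse, "aic": bil.aic,
                             "r2": bil.r2, "nrmse": bil.nrmse,
                             "fallback": bil.fallback},
                "delta_aic": delta,
                "bootstrap": {
                    name: {"point": ci.point, "lower": ci.lower, "upper": ci.upper,
                           "n_failed": ci.n_failed, "n_fallback": ci.n_fallback}
                    for name, ci in cis.items()
                } | {"n_boot": n_boot, "seed": seed, "level": 0.95},
            }
    return results


def sampling_frequency_experiment(
    vials: list[VialSeries],
    schedules=(3, 2, 1),
    parameters=("s_dvp", "t_mid"),
    response: str = "pupae",
) -> pd.DataFrame:
    """Compare the Gompertz + bilinear pipeline across observation schedules.

    For each schedule (observations per day), the 8 h data are thinned with
    :func:`~devkinetics.synthetic.downsample_schedule`, the Gompertz primary
    table rebuilt, and the bilinear secondary fit summarized per parameter
    (breakpoint, nRMSE, R²). Fit failures surface in ``n_failed`` rather
    than silently vanishing.
    """
    rows = []
    for per_day in schedules:
        thinned = [downsample_schedule(v, per_day) for v in vials
                   if v.response == response]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = run_primary_table(thinned, models=("gompertz",), response=response)
        n_failed = int((table["status"] != "ok").sum())
        if n_failed:
            logger.warning("schedule %d/day: %d concentration(s) failed to fit",
                           per_day, n_failed)
        for param in parameters:
            sub = table.dropna(subset=[param]).sort_values("concentration_M")
            x = sub["concentration_M"].to_numpy(dtype=float)
            y = sub[param].to_numpy(dtype=float)
            row = {"per_day": per_day, "parameter": param,
                   "n_concentrations": int(x.size), "n_failed": n_failed}
            if x.size >= 5:
                _, bil, delta = compare_linear_bilinear(x, y, parameter_name=param)
                row.update(x_c=bil.coef["x_c"], nrmse=bil.nrmse, r2=bil.r2,
                           delta_aic=delta, fallback=bil.fallback)
            else:
                row.update(x_c=np.nan, nrmse=np.nan, r2=np.nan,
                           delta_aic=np.nan, fallback=True)
            rows.append(row)
    return pd.DataFrame(rows)


def run_viability(vials: list[VialSeries], alpha: float = 0.05, response="pupae"):
    """Per-vial viabilities grouped by concentration -> full viability stats."""
    groups, labels = [], []
    for E in sorted({v.concentration for v in vials if v.response == response}):
        sel = [v.final_count / v.n_embryos for v in vials
               if v.response == response and np.isclose(v.concentration, E)]
        if len(sel) >= 2:
            groups.append(sel)
            labels.append(f"{E:g}M")
    return viability_stats(groups, labels=labels, alpha=alpha)


def load_fixture_table(name: str) -> pd.DataFrame:
    """Load a packaged reference parameter table.

    ``name`` is ``"t_mid"`` or ``"s_dvp"``; the tables transcribe the
    published per-concentration parameter estimates for all three primary
    models (11 concentrations each).
    """
    fname = {"t_mid": "table1_tmid.csv", "s_dvp": "table2_sdvp.csv"}[name]
    with resources.files("devkinetics.fixtures").joinpath(fname).open() as fh:
        return pd.read_csv(fh)


def reproduce_reference_tables(n_boot: int = 1000, seed: int = 0) -> dict:
    """Secondary modeling on the packaged reference parameter tables.

    Merges the two fixture tables into one primary-parameter table and runs
    the full secondary stage (linear vs bilinear AIC comparison plus
    bootstrap CIs) for every model x parameter combination.
    """
    tmid = load_fixture_table("t_mid")
    sdvp = load_fixture_table("s_dvp")
    merged = tmid.merge(sdvp, on=["model", "concentration_M"])
    return run_secondary_table(merged, n_boot=n_boot, seed=seed)


def format_table(df: pd.DataFrame) -> str:
    """CSV text with floats at 6 significant digits (stable across runs)."""
    return df.to_csv(index=False, float_format="%.6g")
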