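"""End-to-end orchestration: screen -> response surface -> surrogate + GA ->
verification arithmetic -> kinetics -> assays, with a machine-readable report.

Mandatory stages are the screening and response-surface fits (they need the
design CSVs); the surrogate/GA stage runs whenever the response-surface stage
does.  Kinetics and assay stages are optional: a missing input marks the
section "skipped" instead of aborting.  All randomness derives from the
config seed, so a rerun with the same config yields a byte-identical report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ann import TrainConfig, degree_of_approximation, select_hidden_nodes, \
    split_data, train_network
from .assays import ScavengingRecord, scavenging_rate
from .datasets import load_table1_pbd, load_table2_bbd, read_design_csv
from .designs import bbd_factors
from .ga import GaConfig, optimize_extraction
from .kinetics import TimeCourse, compare_techniques, fit_linearized, fit_nls
from .rsm import anova_decompose, fit_quadratic, polynomial_optimum, \
    studentized_diagnostics
from .screening import fit_first_order, pareto_effects

__all__ = ["PipelineConfig", "run_pipeline", "relative_error"]


def relative_error(observed: float, reference: float) -> float:
    """|observed - reference| / reference * 100 (percent)."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return abs(observed - reference) / abs(reference) * 100.0


@dataclass
class PipelineConfig:
    # None -> the bundled published tables
    pbd_csv: str | Path | None = None
    bbd_csv: str | Path | None = None
    kinetics_uae_csv: str | Path | None = None
    kinetics_tse_csv: str | Path | None = None
    assay_csv: str | Path | None = None
    alpha: float = 0.05
    ann_hidden: int = 10
    ann_seeds: int = 10
    select_width: bool = False
    ga: GaConfig = field(default_factory=GaConfig)
    verification_yield: float | None = None   # measured mean at the optimum
    seed: int = 0
    out_dir: str | Path | None = None


def _read_timecourse(path, label):
    df = pd.read_csv(path)
    return TimeCourse(df["t_min"].to_numpy(float),
                      df["conc_mg_per_g"].to_numpy(float), label=label)


def run_pipeline(config: PipelineConfig) -> dict:
    report: dict = {"software": {"extractopt": __version__},
                    "seed": config.seed}

    # --- screening -------------------------------------------------------
    if config.pbd_csv is None:
        pbd, y_pbd = load_table1_pbd()
    else:
        pbd, y_pbd = read_design_csv(config.pbd_csv, design_kind="pbd")
        if y_pbd is None:
            raise ValueError("screening stage: design CSV has no Y column")
    sfit = fit_first_order(pbd, y_pbd, alpha=config.alpha)
    report["screening"] = {
        "intercept": sfit.intercept,
        "coefficients": sfit.coefficients,
        "standardized_effects": sfit.standardized_effects,
        "threshold": sfit.threshold,
        "r_squared": sfit.r_squared,
        "ranking": [
            {"factor": f, "standardized_effect": e, "significant": s}
            for f, e, s in pareto_effects(sfit)
        ],
    }

    # --- response surface ------------------------------------------------
    if config.bbd_csv is None:
        bbd, y_bbd = load_table2_bbd()
    else:
        bbd, y_bbd = read_design_csv(config.bbd_csv, factors=bbd_factors(),
                                     design_kind="bbd")
        if y_bbd is None:
            raise ValueError("rsm stage: design CSV has no Y column")
    qfit = fit_quadratic(bbd, y_bbd)
    anova = anova_decompose(qfit, bbd, y_bbd)
    diag = studentized_diagnostics(qfit, bbd, y_bbd)
    opt_poly = polynomial_optimum(qfit)
    report["rsm"] = {
        "coefficients": qfit.coefficients.tolist(),
        "r_squared": qfit.r_squared,
        "anova": anova.replace({np.nan: None}).to_dict(orient="records"),
        "n_outliers": int(diag.outlier_flags.sum()),
        "polynomial_optimum": {"coded": opt_poly[0].tolist(),
                               "predicted_yield": opt_poly[1]},
    }

    # --- surrogate + GA --------------------------------------------------
    rng = np.random.default_rng(config.seed)
    seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=config.ann_seeds)]
    hidden = config.ann_hidden
    da_trace = None
    if config.select_width:
        hidden, da_trace = select_hidden_nodes(bbd, y_bbd, seeds=seeds)
    preds_max, corrs, decoded_best = [], [], None
    best_da = -np.inf
    for s in seeds:
        split = split_data(bbd.n_runs, seed=s)
        model = train_network(split, bbd, y_bbd, hidden, TrainConfig(seed=s))
        da = degree_of_approximation(model, bbd, y_bbd)
        ga_cfg = GaConfig(**{**config.ga.__dict__, "seed": s})
        opt = optimize_extraction(model, bbd, ga_cfg)
        preds_max.append(opt.predicted_yield)
        corrs.append(float(np.corrcoef(model.predict(bbd.runs),
                                       y_bbd.values)[0, 1]))
        if da.da > best_da:
            best_da = da.da
            decoded_best = {"coded": opt.coded.tolist(),
                            "decoded": opt.decoded.tolist(),
                            "predicted_yield": opt.predicted_yield,
                            "seed": s}
    report["ann_ga"] = {
        "hidden_nodes": hidden,
        "da_trace": da_trace,
        "median_predicted_max_yield": float(np.median(preds_max)),
        "median_overall_correlation": float(np.median(corrs)),
        "best_run": decoded_best,
        "n_seeds": len(seeds),
    }

    # --- verification ----------------------------------------------------
    predicted = report["ann_ga"]["median_predicted_max_yield"]
    verification = {"predicted_yield": predicted}
    if config.verification_yield is not None:
        verification["measured_yield"] = config.verification_yield
        verification["relative_error_percent"] = relative_error(
            config.verification_yield, predicted)
    report["verification"] = verification

    # --- kinetics (optional) --------------------------------------------
    if config.kinetics_uae_csv is None:
        report["kinetics"] = {"status": "skipped"}
    else:
        fits = {}
        tc_a = _read_timecourse(config.kinetics_uae_csv, "UAE")
        fits["UAE"] = {m.method: m for m in
                       (fit_linearized(tc_a), fit_nls(tc_a))}
        if config.kinetics_tse_csv is not None:
            tc_b = _read_timecourse(config.kinetics_tse_csv, "TSE")
            fits["TSE"] = {m.method: m for m in
                           (fit_linearized(tc_b), fit_nls(tc_b))}
        sec = {
            lab: {meth: {"cs": f.cs, "k": f.k, "r_squared": f.r_squared,
                         "initial_rate": f.initial_rate}
                  for meth, f in d.items()}
            for lab, d in fits.items()
        }
        if "TSE" in fits:
            sec["comparison"] = compare_techniques(
                fits["UAE"]["linearized"], fits["TSE"]["linearized"])
        sec["cs_vs_predicted_relative_error_percent"] = relative_error(
            predicted, fits["UAE"]["linearized"].cs)
        report["kinetics"] = sec

    # --- assays (optional) ----------------------------------------------
    if config.assay_csv is None:
        report["assays"] = {"status": "skipped"}
    else:
        df = pd.read_csv(config.assay_csv)
        out = []
        for _, row in df.iterrows():
            bg = row.get("a_background", 0.0)
            conc = row.get("concentration_mg_per_ml")
            rec = ScavengingRecord(row["a_sample"], row["a_control"],
                                   0.0 if pd.isna(bg) else float(bg),
                                   assay=row["assay"],
                                   concentration=None if pd.isna(conc)
                                   else float(conc))
            out.append({"assay": rec.assay,
                        "concentration_mg_per_ml": rec.concentration,
                        "scavenging_percent": scavenging_rate(rec)})
        report["assays"] = {"records": out}

    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        (out_dir / "report.md").write_text(_render_markdown(report))
    return report


def _render_markdown(report: dict) -> str:
    lines = ["# Extraction optimization report", ""]
    scr = report["screening"]
    top = scr["ranking"][0]
    lines += [
        "## Screening",
        f"R^2 = {scr['r_squared']:.4f}; strongest factor {top['factor']} "
        f"(|t| = {top['standardized_effect']:.2f}, "
        f"threshold {scr['threshold']:.2f})", "",
        "## Response surface",
        f"R^2 = {report['rsm']['r_squared']:.4f}; polynomial optimum "
        f"{np.round(report['rsm']['polynomial_optimum']['coded'], 3).tolist()} "
        f"-> {report['rsm']['polynomial_optimum']['predicted_yield']:.4f} mg/g", "",
        "## Surrogate + GA",
        f"hidden nodes {report['ann_ga']['hidden_nodes']}; median predicted "
        f"maximum {report['ann_ga']['median_predicted_max_yield']:.4f} mg/g; "
        f"median overall R {report['ann_ga']['median_overall_correlation']:.4f}",
        "",
    ]
    ver = report["verification"]
    if "relative_error_percent" in ver:
        lines += ["## Verification",
                  f"measured {ver['measured_yield']} vs predicted "
                  f"{ver['predicted_yield']:.4f} mg/g: relative error "
                  f"{ver['relative_error_percent']:.3f}%", ""]
    for key in ("kinetics", "assays"):
        sec = report[key]
        lines.append(f"## {key.capitalize()}")
        lines.append("skipped" if sec.get("status") == "skipped"
                     else json.dumps(sec, indent=2, default=str))
        lines.append("")
    return "\n".join(lines)
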