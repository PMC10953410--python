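"""End-to-end orchestration: simulate → clean → score → latent → analyze.

A run is fully described by a config mapping (seed, sample sizes, window,
planted truth, FDR level, toggles); :func:`run_all` executes every stage,
writes CSV/JSON outputs plus a provenance manifest into a run directory,
and :func:`make_report` renders a Markdown summary with per-family
forest-style tables and — when a truth record is present — a
planted-vs-estimated recovery table.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import achburden
from achburden import achb, association, latent, prescriptions, synthetic

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "n_participants": 20_000,
    "n_drugs": 60,
    "n_combinations": 5,
    "n_scales": 15,
    "coverage_range": [0.05, 0.40],
    "window": [2000, 2015],
    "fdr_level": 0.05,
    "adjust_polypharmacy": True,
    "imaging": True,
    "n_regions": 14,
    "n_tracts": 25,
    "truth": {},
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = {k: (list(v) if isinstance(v, list) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            cfg.update(yaml.safe_load(fh) or {})
    if overrides:
        cfg.update(overrides)
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def simulate_inputs(cfg: dict, out_dir: Path | None = None) -> dict:
    """Generate all synthetic inputs (optionally writing them as CSVs)."""
    seeds = synthetic.spawn_seeds(cfg["seed"], 8)
    truth = synthetic.SimulationTruth(seed=cfg["seed"], **cfg.get("truth", {}))
    catalogue = synthetic.make_catalogue(cfg["n_drugs"], cfg["n_combinations"], seeds[0])
    scales = synthetic.make_scales(catalogue, cfg["n_scales"], tuple(cfg["coverage_range"]), seeds[1])
    scales = [achb.apply_improbable_rule(s) if s.improbable_set else s for s in scales]
    participants = synthetic.simulate_participants(cfg["n_participants"], seeds[2])
    records, violation_audit = synthetic.simulate_prescriptions(
        participants, catalogue, truth, tuple(cfg["window"]), seeds[3]
    )
    bundle = {
        "truth": truth,
        "catalogue": catalogue,
        "scales": scales,
        "participants": participants,
        "records": records,
        "violation_audit": violation_audit,
        "seeds": seeds,
    }
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        rec_out = records.copy()
        rec_out["date"] = pd.to_datetime(rec_out["issue_date"]).dt.strftime("%Y-%m-%d")
        rec_out.rename(columns={"drug_raw": "drug"})[["participant_id", "date", "drug", "route", "supplier"]].to_csv(
            out_dir / "prescriptions.csv", index=False
        )
        participants.to_csv(out_dir / "participants.csv", index=False)
        catalogue.atc_map.to_csv(out_dir / "atc_map.csv", index=False)
        pd.DataFrame(
            [(b, g) for b, g in catalogue.brand_map.items()], columns=["brand", "generic"]
        ).to_csv(out_dir / "brand_map.csv", index=False)
        pd.DataFrame(
            [(p, ";".join(c)) for p, c in catalogue.combination_products.items()], columns=["product", "components"]
        ).to_csv(out_dir / "combos.csv", index=False)
        scales_dir = out_dir / "scales"
        scales_dir.mkdir(exist_ok=True)
        for s in scales:
            pd.DataFrame(
                {
                    "drug": list(s.potencies),
                    "potency": list(s.potencies.values()),
                    "improbable_flag": [d in s.improbable_set for d in s.potencies],
                }
            ).to_csv(scales_dir / f"{s.name}.csv", index=False)
        (out_dir / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2))
    return bundle


def run_all(config: dict | str | Path | None = None, out: str | Path = "runs/demo") -> Path:
    """Execute the full pipeline; returns the run directory.

    Stages: simulate inputs → normalize + clean cascade → burden scoring →
    latent factors (CFA g, gFA/gMD) → association batteries with FDR.  A
    provenance manifest (config hash, seed, versions, per-stage row counts)
    is written alongside the result tables.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)

    bundle = simulate_inputs(cfg, out_dir / "inputs")
    truth, catalogue, scales = bundle["truth"], bundle["catalogue"], bundle["scales"]
    participants, records = bundle["participants"], bundle["records"]
    seeds = bundle["seeds"]

    # clean
    normalized = prescriptions.normalize_names(records, catalogue.brand_map, catalogue.formulary)
    clean = prescriptions.clean_cascade(
        normalized,
        participants,
        window=tuple(cfg["window"]),
        combos=catalogue.combination_products,
    )
    clean.audit.to_json(out_dir / "cleaning_audit.json")

    # score
    burden = achb.build_burden_table(clean.records, scales, catalogue.atc_map, participants=participants)
    burden.to_csv(out_dir / "burden.csv", index=False)

    # latent traits
    exposure_for_g = burden[f"achb_{scales[-1].name}"]  # largest-coverage scale as the exposure proxy
    cognition, g_true = synthetic.simulate_cognition(
        participants, exposure_for_g, truth, seed=seeds[4], polypharmacy=burden[f"nonac_{scales[-1].name}"]
    )
    cog_long = cognition.melt(id_vars=["participant_id"], var_name="test", value_name="score").dropna()
    cog_long["visit"] = np.where(cog_long["test"].isin(synthetic.VISIT2_ONLY_TESTS), 2, 1)
    cog_long[["participant_id", "visit", "test", "score"]].to_csv(out_dir / "inputs" / "cognition.csv", index=False)
    spec = latent.CFASpec(
        indicators=tuple(truth.loadings),
        residual_pairs=tuple((a, b) for a, b, _ in truth.residual_correlations),
        reference_indicator=list(truth.loadings)[0],
    )
    fit = latent.fit_cfa(cognition, spec)
    g = latent.score_g(fit, cognition)

    master = participants.merge(burden, on="participant_id")
    master["g"] = g.to_numpy()
    master["n_years"] = master["n_years"].astype(float)

    imaging = None
    if cfg.get("imaging", True):
        imaging = synthetic.simulate_imaging(
            participants, exposure_for_g, truth, cfg["n_regions"], cfg["n_tracts"], seeds[5]
        )
        fa = latent.fit_general_pc(imaging, measure="tract_fa")
        md = latent.fit_general_pc(imaging, measure="tract_md")
        imaging["gFA"] = fa.scores.to_numpy()
        imaging["gMD"] = md.scores.to_numpy()
        imaging["total_brain_volume_corrected"] = imaging["total_brain_volume"] * imaging["head_scaling"]
        imaging.to_csv(out_dir / "inputs" / "imaging.csv", index=False)
        master = master.merge(imaging, on="participant_id")
        pd.DataFrame({"measure": ["gFA", "gMD"], "variance_share": [fa.variance_share, md.variance_share]}).to_csv(
            out_dir / "general_pc.csv", index=False
        )

    # analysis battery
    scale_names = [s.name for s in scales]
    imaging_outcomes = None
    brain_outcome = None
    if imaging is not None:
        brain_outcome = "total_brain_volume_corrected"
        imaging_outcomes = {
            "regions": [c for c in imaging.columns if c.startswith("region_vol_")],
            "tracts_fa": [c for c in imaging.columns if c.startswith("tract_fa_")],
            "tracts_md": [c for c in imaging.columns if c.startswith("tract_md_")],
            "gfa_gmd": ["gFA", "gMD"],
        }
    battery = association.run_battery(
        master,
        scale_names,
        level=cfg["fdr_level"],
        adjust_polypharmacy=cfg["adjust_polypharmacy"],
        imaging_outcomes=imaging_outcomes,
        brain_outcome=brain_outcome,
    )
    results_dir = out_dir / "results"
    results_dir.mkdir(exist_ok=True)
    for fam, df in battery.families.items():
        df.to_csv(results_dir / f"{fam}.csv", index=False)

    sizes = {s.name: s.n_drugs for s in scales}
    size_family = battery.families.get("scales_g_unadjusted", battery.families["scales_g"])
    r_size, p_size = association.scale_size_correlation(size_family, sizes)

    manifest = {
        "package_version": achburden.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg["seed"],
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "best_scale": battery.best_scale,
        "scale_size_correlation": {"r": r_size, "p": p_size},
        "cfa": {"proportional_variance": fit.proportional_variance, **fit.fit_stats},
        "row_counts": {
            "participants": len(participants),
            "raw_records": len(records),
            "clean_records": len(clean.records),
            "participant_years": len(clean.participant_years),
        },
        "violation_audit": bundle["violation_audit"],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out_dir


def make_report(run_dir: str | Path) -> str:
    """Render a Markdown summary of a completed run (written to report.md)."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {run_dir}; is this a completed run?")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        "# achburden run report",
        "",
        f"- seed: {manifest['seed']} (config hash {manifest['config_hash']})",
        f"- best scale (strongest AChB→g association): **{manifest['best_scale']}**",
        f"- scale size vs |beta| correlation: r = {manifest['scale_size_correlation']['r']:.3f}, "
        f"p = {manifest['scale_size_correlation']['p']:.2g}",
        f"- CFA proportional variance: {manifest['cfa']['proportional_variance']:.3f}",
        "",
    ]
    results_dir = run_dir / "results"
    for path in sorted(results_dir.glob("*.csv")):
        df = pd.read_csv(path)
        if df.empty:
            lines += [f"## {path.stem}", "", "(empty family — skipped)", ""]
            continue
        lines.append(f"## {path.stem}")
        lines.append("")
        cols = [c for c in ("predictor", "outcome", "beta", "se", "p_fdr", "ci_low", "ci_high", "n") if c in df]
        sub = df[cols].copy()
        for c in ("beta", "se", "ci_low", "ci_high"):
            if c in sub:
                sub[c] = sub[c].map(lambda v: f"{v:+.3f}")
        if "p_fdr" in sub:
            sub["p_fdr"] = sub["p_fdr"].map(lambda v: f"{v:.3g}")
        lines.append(sub.to_markdown(index=False))
        lines.append("")
    truth_path = run_dir / "inputs" / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        scales_g = pd.read_csv(results_dir / "scales_g.csv")
        best = scales_g.loc[scales_g["beta"].abs().idxmax()]
        lines += [
            "## Recovery vs planted truth",
            "",
            "| quantity | planted | estimated |",
            "|---|---|---|",
            f"| AChB → g (strongest scale) | {truth['beta_achb_g']:+.3f} | {best['beta']:+.3f} |",
            f"| AChB → imaging outcomes | {truth['beta_achb_brain']:+.3f} | (see imaging families) |",
            "",
        ]
    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text)
    return text
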