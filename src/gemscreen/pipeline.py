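"""Configuration-driven stage orchestration and reporting.

Each stage is a pure function from validated inputs to files in an output
directory, accompanied by a manifest (input hashes, parameters, package
version) so that deterministic stages reproduce byte-identical outputs
when re-run with the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotate, breakdown, doseresponse, fluctuation, screen, spheroid
from . import synthetic

__all__ = ["run_stage", "write_report", "STAGES"]

FLOAT_FMT = "%.12g"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if math.isfinite(f) else ("inf" if f > 0 else "-inf")
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(_jsonify(payload), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Stage implementations


def _stage_screen(cfg: dict, outdir: Path) -> list[Path]:
    counts = pd.read_csv(cfg["counts"], index_col=0)
    meta = pd.read_csv(cfg["meta"], index_col=0)["condition"]
    table = screen.CountTable(counts, meta)
    table = screen.filter_low_counts(table, int(cfg.get("min_count", 10)))
    stats_df = screen.wald_enrichment(table)
    hits = screen.call_hits(stats_df, float(cfg.get("fc", 16.0)),
                            float(cfg.get("q", 0.05)))
    out_stats = outdir / "stats.csv"
    stats_df.to_csv(out_stats, float_format=FLOAT_FMT)
    out_hits = outdir / "hits.json"
    _write_json(out_hits, {"resistant": list(hits.resistant),
                           "sensitive": list(hits.sensitive),
                           "fc_cutoff": hits.fc_cutoff, "q_cutoff": hits.q_cutoff})
    return [out_stats, out_hits]


def _stage_ic50(cfg: dict, outdir: Path) -> list[Path]:
    readings = pd.read_csv(cfg["plate"])
    layout = pd.read_csv(cfg["layout"])
    series = doseresponse.PlateSeries(readings, layout)
    resp = doseresponse.relative_growth(series, float(cfg.get("t_eval", 720)))
    fit = doseresponse.fit_4pl(resp.index.to_numpy(), resp.to_numpy())
    out = outdir / "fit.json"
    _write_json(out, {"bottom": fit.bottom, "top": fit.top, "x50": fit.x50,
                      "hill": fit.hill, "rss": fit.rss, "ic50": fit.ic50,
                      "converged": fit.converged, "max_dose": fit.max_dose})
    return [out]


def _stage_breakdown(cfg: dict, outdir: Path) -> list[Path]:
    aucs = pd.read_csv(cfg["aucs"])
    calls = breakdown.classify_degraders(aucs, float(cfg.get("q", 0.1)),
                                         wt_label=cfg.get("wt_label", "WT"))
    out = outdir / "calls.csv"
    pd.DataFrame([vars(c) for c in calls]).to_csv(out, index=False,
                                                  float_format=FLOAT_FMT)
    return [out]


def _stage_spheroid(cfg: dict, outdir: Path) -> list[Path]:
    end = pd.read_csv(cfg["areas"], index_col=0).to_numpy()
    t0 = pd.read_csv(cfg["t0"], index_col=0).to_numpy()
    grid = spheroid.SpheroidGrid(end, t0)
    fit = spheroid.fit_poly44(grid)
    front = fit.ec50_front(float(cfg.get("level", 0.5)))
    out = outdir / "fit.json"
    _write_json(out, {"coefficients": fit.coefficients, "rss": fit.rss,
                      "level": front.level,
                      "crossings": front.crossings, "rows": front.y_rows})
    return [out]


def _stage_fluctuation(cfg: dict, outdir: Path) -> list[Path]:
    counts = pd.read_csv(cfg["counts"])["count"].to_numpy()
    design = fluctuation.FluctuationDesign(
        N0=float(cfg.get("n0", 730)), Nt=float(cfg["nt"]),
        epsilon=float(cfg.get("epsilon", 1.0)),
        gene_length=int(cfg.get("gene_length", 1000)), n_cultures=len(counts))
    res = fluctuation.FluctuationModel(counts, design.epsilon, design).fit()
    mu, mu_kb = res.mutation_rate(divisor=cfg.get("divisor", "divisions"))
    out = outdir / "fit.json"
    _write_json(out, {"m": res.m, "ci": res.ci, "loglik": res.loglik,
                      "mu": mu, "mu_per_kb": mu_kb, "epsilon": design.epsilon})
    return [out]


def _stage_annotate(cfg: dict, outdir: Path) -> list[Path]:
    from Bio import SeqIO
    ref = str(next(SeqIO.parse(cfg["ref"], "fasta")).seq)
    calls = {rec.id: annotate.align_and_classify(str(rec.seq), ref)
             for rec in SeqIO.parse(cfg["queries"], "fasta")}
    out_calls = outdir / "calls.csv"
    pd.DataFrame([{"query": k, **vars(v)} for k, v in calls.items()]).to_csv(
        out_calls, index=False)
    out_spec = outdir / "spectrum.json"
    _write_json(out_spec, annotate.spectrum(calls.values()))
    outputs = [out_calls, out_spec]
    if "profile" in cfg:
        prof = pd.read_csv(cfg["profile"])
        positions = [c.protein_position for c in calls.values()
                     if c.type == "missense" and c.protein_position]
        W, p = annotate.conservation_bias_test(prof["score"].to_numpy(), positions)
        out_test = outdir / "conservation_test.json"
        _write_json(out_test, {"W": W, "p": p, "n_missense": len(positions)})
        outputs.append(out_test)
    return outputs


def _stage_simulate(cfg: dict, outdir: Path) -> list[Path]:
    """Write a synthetic demo input set for every downstream stage."""
    seed = int(cfg["seed"])
    outputs = []

    table = synthetic.simulate_screen_counts(synthetic.ScreenSimConfig(
        n_strains=int(cfg.get("n_strains", 500)), depth=float(cfg.get("depth", 2e5)),
        planted_resistors=[("s0001", 5.0)], planted_sensitives=[("s0002", -5.0)],
        seed=seed))
    p = outdir / "screen_counts.csv"
    table.counts.to_csv(p)
    outputs.append(p)
    p = outdir / "screen_meta.csv"
    table.condition.rename("condition").to_frame().to_csv(p)
    outputs.append(p)

    gcfg = synthetic.GrowthSimConfig(ic50_true=10.0, seed=seed)
    series = synthetic.simulate_growth_curves(
        gcfg, synthetic.serial_dilution_doses(100.0))
    p = outdir / "plate.csv"
    series.readings.to_csv(p, index=False, float_format=FLOAT_FMT)
    outputs.append(p)
    p = outdir / "layout.csv"
    series.layout.to_csv(p, index=False)
    outputs.append(p)

    aucs = synthetic.simulate_breakdown_cohort(seed=seed)
    p = outdir / "aucs.csv"
    aucs.to_csv(p, index=False, float_format=FLOAT_FMT)
    outputs.append(p)

    grid = synthetic.simulate_spheroid_plate(synthetic.SpheroidSimConfig(
        degradation_coefficient=1.0, noise_sd=0.03, seed=seed))
    for name, arr in (("spheroid_end.csv", grid.area_end),
                      ("spheroid_t0.csv", grid.area_t0)):
        p = outdir / name
        pd.DataFrame(arr).to_csv(p, float_format=FLOAT_FMT)
        outputs.append(p)

    counts = synthetic.simulate_fluctuation(synthetic.FluctuationSimConfig(seed=seed))
    p = outdir / "fluctuation_counts.csv"
    pd.DataFrame({"culture_id": np.arange(len(counts)), "count": counts}).to_csv(
        p, index=False)
    outputs.append(p)

    rng = np.random.default_rng(seed)
    ref = synthetic.random_cds(400, seed=seed)
    lines = [">ref\n" + ref + "\n"]
    qlines = []
    for i in range(12):
        spec = synthetic.random_mutation_spec(ref, rng)
        qlines.append(f">q{i}\n" + synthetic.mutate_sequence(ref, spec) + "\n")
    p = outdir / "ref_cds.fasta"
    p.write_text("".join(lines))
    outputs.append(p)
    p = outdir / "queries.fasta"
    p.write_text("".join(qlines))
    outputs.append(p)

    scores, pos = synthetic.simulate_conservation(400, bias=8.0, n_mut=50, seed=seed)
    p = outdir / "conservation.csv"
    pd.DataFrame({"position": np.arange(1, 401), "score": scores}).to_csv(p, index=False)
    outputs.append(p)
    return outputs


STAGES = {
    "simulate": (_stage_simulate, ["seed"]),
    "screen": (_stage_screen, ["counts", "meta"]),
    "ic50": (_stage_ic50, ["plate", "layout"]),
    "breakdown": (_stage_breakdown, ["aucs"]),
    "spheroid": (_stage_spheroid, ["areas", "t0"]),
    "fluctuation": (_stage_fluctuation, ["counts", "nt"]),
    "annotate": (_stage_annotate, ["queries", "ref"]),
}

_PATH_KEYS = {"counts", "meta", "plate", "layout", "aucs", "areas", "t0",
              "queries", "ref", "profile"}


def run_stage(config: dict) -> dict:
    """Validate ``config``, run the stage, and write a manifest.

    Required keys: ``stage``, ``outdir``, plus the stage's own inputs.
    Raises before any computation on schema violations or missing files.
    Returns the manifest (also written to ``<outdir>/manifest.json``).
    """
    if "stage" not in config or "outdir" not in config:
        raise ValueError("config must have 'stage' and 'outdir'")
    name = config["stage"]
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; known: {sorted(STAGES)}")
    func, required = STAGES[name]
    missing = [k for k in required if k not in config]
    if missing:
        raise ValueError(f"stage {name!r} missing required keys: {missing}")
    inputs = {k: Path(config[k]) for k in config if k in _PATH_KEYS}
    for k, pth in inputs.items():
        if not pth.exists():
            raise ValueError(f"input {k}={pth} does not exist")

    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = func(config, outdir)
    manifest = {
        "stage": name,
        "version": __version__,
        "parameters": {k: v for k, v in config.items()
                       if k not in _PATH_KEYS | {"stage", "outdir"}},
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)}
                   for k, p in inputs.items()},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    _write_json(outdir / "manifest.json", manifest)
    return manifest


_REPORT_ORDER = ["simulate", "screen", "ic50", "breakdown", "spheroid",
                 "fluctuation", "annotate"]


def write_report(manifests: list[dict]) -> str:
    """Human-readable summary of executed stages, in fixed stage order."""
    if not manifests:
        raise ValueError("need at least one manifest")
    by_stage = {m["stage"]: m for m in manifests}
    lines = ["# gemscreen run report", ""]
    for name in _REPORT_ORDER:
        if name not in by_stage:
            continue
        m = by_stage[name]
        lines.append(f"## stage: {name}")
        lines.append(f"- package version: {m['version']}")
        if m["parameters"]:
            pars = ", ".join(f"{k}={v}" for k, v in sorted(m["parameters"].items()))
            lines.append(f"- parameters: {pars}")
        for fname, digest in sorted(m["outputs"].items()):
            lines.append(f"- output {fname}: sha256 {digest[:12]}")
        lines.append("")
    return "\n".join(lines)
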