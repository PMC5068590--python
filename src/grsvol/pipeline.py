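"""End-to-end pipeline: ingest -> harmonize -> MAF filter -> clump -> score
-> associate -> permute -> report, driven by a declarative YAML config.

Outputs a Table-style TSV report (one row per training set x threshold, one
column group per ROI), a machine-readable JSON twin, per-stage variant counts,
and a provenance record (config hash, seed, version).  Identical config and
seed produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .assoc import CovariatePolicy, results_frame, run_table
from .clump import ClumpParams, clump
from .exceptions import GrsvolError
from .io import harmonize, maf_filter, read_genotypes, read_phenotypes, read_sumstats
from .prs import ScoreProfile, ThresholdSet, score, standardize_scores

logger = logging.getLogger("grsvol")

__all__ = ["load_config", "run"]

_DEFAULTS: dict[str, Any] = {
    "genotype_format": "tsv",
    "maf_threshold": 0.01,
    "clump": {"r2_threshold": 0.25, "window_kb": 500.0, "p1": 1.0},
    "thresholds": [1e-5, 1e-4, 0.01, 0.1, 0.3, 0.5],
    "score_mode": "sum",
    "standardize": True,
    "drop_ambiguous": True,
    "covariates": {"always": ["sex", "icv"], "age_rois": ["lateral_ventricles"]},
    "n_perm": 10000,
    "perm_policy": "significant",
    "perm_method": "permute-score",
    "perm_estimator": "plain",
    "alpha": 0.05,
    "seed": 0,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(_DEFAULTS))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    for req in ("sumstats", "genotypes", "phenotypes", "rois", "out_dir"):
        if req not in cfg:
            raise GrsvolError(f"config missing required key {req!r}")
    return cfg


def _config_hash(cfg: dict) -> str:
    # machine-local path prefixes are excluded so identical analyses hash
    # identically regardless of where the working copy lives
    hashed = {k: v for k, v in cfg.items() if k not in ("base_dir", "out_dir")}
    return hashlib.sha256(json.dumps(hashed, sort_keys=True).encode()).hexdigest()[:16]


def run(cfg: dict) -> Path:
    """Execute every stage; returns the output directory."""
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    base = Path(cfg.get("base_dir", "."))

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    gm = read_genotypes(_resolve(cfg["genotypes"]), format=cfg["genotype_format"])
    log(f"genotypes: {gm.n_samples} samples x {gm.n_variants} variants")
    pheno = read_phenotypes(_resolve(cfg["phenotypes"]), rois=cfg["rois"])
    log(f"phenotypes: {len(pheno.table)} samples, ROIs: {', '.join(pheno.rois)}")

    params = ClumpParams(**cfg["clump"])
    thresholds = ThresholdSet(tuple(cfg["thresholds"]))
    scores: dict[str, ScoreProfile] = {}
    for ts_name, path in cfg["sumstats"].items():
        ss = read_sumstats(_resolve(path))
        log(f"[{ts_name}] sumstats: {len(ss)} variants read, {len(ss.rejected)} rejected")
        ss = harmonize(ss, gm, drop_ambiguous=cfg["drop_ambiguous"])
        log(f"[{ts_name}] harmonized: {len(ss)} variants")
        ss = maf_filter(ss, gm, threshold=cfg["maf_threshold"])
        log(f"[{ts_name}] after MAF>={cfg['maf_threshold']}: {len(ss)} variants")
        cres = clump(ss, gm, params)
        ss = ss.restrict(cres.index_variants)
        log(f"[{ts_name}] clumped: {len(cres.index_variants)} index variants")
        sp = score(gm, ss, thresholds, mode=cfg["score_mode"])
        if cfg["standardize"]:
            sp = standardize_scores(sp)
        scores[ts_name] = sp
        counts = ", ".join(f"{t}:{sp.n_variants[t]}" for t in sp.thresholds)
        log(f"[{ts_name}] variants per threshold: {counts}")

    policy = CovariatePolicy(
        always=tuple(cfg["covariates"]["always"]),
        age_rois=tuple(cfg["covariates"]["age_rois"]),
    )
    results = run_table(
        pheno,
        scores,
        policy=policy,
        rois=cfg["rois"],
        n_perm=cfg["n_perm"],
        perm_policy=cfg["perm_policy"],
        alpha=cfg["alpha"],
        seed=cfg["seed"],
        perm_method=cfg["perm_method"],
        perm_estimator=cfg["perm_estimator"],
    )
    long = results_frame(results)
    long.to_csv(out_dir / "associations.tsv", sep="\t", index=False, float_format="%.6g")
    (out_dir / "associations.json").write_text(
        json.dumps([r.as_dict() for r in results], indent=1) + "\n"
    )
    _write_wide_report(long, cfg["rois"], out_dir / "report.tsv", cfg["alpha"])
    (out_dir / "stages.log").write_text("\n".join(log_lines) + "\n")
    provenance = {
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "grsvol_version": __version__,
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1) + "\n")
    return out_dir


def _write_wide_report(long: pd.DataFrame, rois: list[str], path: Path, alpha: float) -> None:
    """Table-style layout: rows (training set, P_T), per-ROI beta/p/dR2 columns."""
    rows = []
    for (ts, p_t), grp in long.groupby(["training_set", "p_t"], sort=False):
        row: dict[str, Any] = {"training_set": ts, "p_t": p_t}
        for roi in rois:
            cell = grp[grp["roi"] == roi].iloc[0]
            row[f"{roi}:beta"] = round(cell["beta"], 4)
            row[f"{roi}:p"] = round(cell["p_nominal"], 4)
            row[f"{roi}:delta_r2"] = round(cell["delta_r2"], 4)
            pp = cell["p_perm"]
            row[f"{roi}:p_perm"] = "" if pd.isna(pp) else round(pp, 4)
            row[f"{roi}:sig"] = (
                "*" if (not pd.isna(pp) and pp < alpha and cell["p_nominal"] < alpha) else ""
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def make_demo(out_dir: str | Path, seed: int = 0, n: int = 274, m: int = 2000) -> Path:
    """Write a self-contained synthetic demo (inputs + config) to ``out_dir``."""
    from .io import write_genotypes_tsv, write_phenotypes, write_sumstats
    from .simulate import ArchitectureSpec, PhenoSpec, sim_genotypes, sim_phenotypes, sim_sumstats

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arch = ArchitectureSpec(
        m=m, block_size=20, rho=0.8, n_causal_shared=25, n_causal_a=25, n_causal_b=25,
        effect_sd=0.12, n_train_eff=50000, seed=seed,
    )
    gm = sim_genotypes(n, arch)
    sumstats = sim_sumstats(arch)
    specs = {
        "globus_pallidus": PhenoSpec(
            roi="globus_pallidus", coupling="shared", target_delta_r2=0.022, seed=seed
        ),
        "amygdala": PhenoSpec(
            roi="amygdala", coupling="b-specific", target_delta_r2=0.02,
            intercept=1600.0, seed=seed,
        ),
        "thalamus": PhenoSpec(
            roi="thalamus", coupling="null", target_delta_r2=0.0,
            intercept=7500.0, noise_sd=600.0, seed=seed,
        ),
        "lateral_ventricles": PhenoSpec(
            roi="lateral_ventricles", coupling="null", target_delta_r2=0.0,
            intercept=7000.0, beta_age=60.0, noise_sd=1200.0, seed=seed,
        ),
    }
    pheno = sim_phenotypes(gm, arch, specs)

    write_genotypes_tsv(gm, out / "genotypes.tsv")
    write_phenotypes(pheno, out / "phenotypes.tsv")
    ss_paths = {}
    for ts_name, ss in sumstats.items():
        fname = f"sumstats_{ts_name.replace('&', 'and').replace('vs', '_vs_')}.tsv"
        write_sumstats(ss, out / fname)
        ss_paths[ts_name] = fname
    cfg = {
        "sumstats": ss_paths,
        "genotypes": "genotypes.tsv",
        "genotype_format": "tsv",
        "phenotypes": "phenotypes.tsv",
        "rois": list(specs),
        "out_dir": "results",
        "n_perm": 1000,
        "seed": seed,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return out
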