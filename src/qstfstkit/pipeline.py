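"""End-to-end orchestration: simulate or load data, screen traits for
divergence, estimate Fst under both ascertainments, run the univariate and
multivariate Qst-Fst tests, and write tidy reports plus a run manifest.

The pipeline is a pure function of (inputs, config, seed): every stage writes
its table to the output directory so any stage can be re-run from
intermediate files, and the manifest records config, input digests, seed,
package version, per-stage runtimes and all output paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import AnalysisConfig, EstimationError
from .fst import ascertain_snps, fst_bootstrap_ci
from .io import read_genotypes, read_phenotypes, write_genotypes, write_phenotypes
from .multivariate import MULTIVARIATE_TRAITS, multivariate_test
from .qst import divergence_scan, individual_means, qst_for_trait
from .simulate import load_sim_config, simulate_dataset
from .univariate import family_report, run_trait_family

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    runtimes: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _StageTimer:
    def __init__(self, manifest: RunManifest, name: str):
        self.manifest, self.name = manifest, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest.runtimes[self.name] = round(time.perf_counter() - self.t0, 3)
        if exc_type is not None:
            logger.error("stage %s failed: %s", self.name, exc)
        else:
            logger.info(
                "stage %s: done in %.2fs", self.name, self.manifest.runtimes[self.name]
            )
        return False


def run_all(config_path: str | Path) -> RunManifest:
    """Execute the full analysis described by a YAML run config.

    The config names either a simulation (fixture name or simulation YAML)
    or genotype + phenotype files, plus the analysis knobs (seed, n_boot,
    ascertainment, mating system, FDR level, output directory).
    """
    config_path = Path(config_path)
    raw = yaml.safe_load(config_path.read_text())
    cfg = AnalysisConfig(
        n_boot=int(raw.get("n_boot", 1000)),
        seed=int(raw.get("seed", 0)),
        ascertainment=raw.get("ascertainment", "all"),
        mating_system=raw.get("mating_system", "selfing"),
        eigenvalue_floor=float(raw.get("eigenvalue_floor", 1e-10)),
        fdr_alpha=float(raw.get("fdr_alpha", 0.05)),
    )
    outdir = Path(raw.get("output_dir", "qstfst_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=raw, seed=cfg.seed, version=__version__)
    logger.info("resolved config: %s (seed %d)", dict(raw), cfg.seed)

    # ---- stage: inputs -------------------------------------------------
    with _StageTimer(manifest, "inputs"):
        if raw.get("simulation"):
            sim_cfg = load_sim_config(raw["simulation"])
            sim_cfg = dataclasses.replace(sim_cfg, seed=cfg.seed)
            g, p = simulate_dataset(sim_cfg)
            gpath = write_genotypes(g, outdir / "genotypes.vcf", "vcf")
            ppath = write_phenotypes(p, outdir / "phenotypes.tsv")
            manifest.outputs["genotypes"] = str(gpath)
            manifest.outputs["phenotypes"] = str(ppath)
        else:
            gpath = Path(raw["genotypes"])
            ppath = Path(raw["phenotypes"])
            for path in (gpath, ppath):
                if not path.exists():
                    raise FileNotFoundError(f"input file not found: {path}")
            g = read_genotypes(gpath, raw.get("genotype_format", "vcf"))
            p = read_phenotypes(ppath)
        manifest.input_digests = {
            "genotypes": _sha256(gpath),
            "phenotypes": _sha256(ppath),
        }
        means = individual_means(p)

    # ---- stage: divergence screen -------------------------------------
    with _StageTimer(manifest, "divergence"):
        screen_traits = raw.get("traits") or [
            t for t in means.traits if t != "internode_sum"
        ]
        div = divergence_scan(means, screen_traits, fdr_alpha=cfg.fdr_alpha)
        diverged = [r.trait for r in div if r.p_fdr <= cfg.fdr_alpha]
        if not raw.get("screen", True):
            diverged = list(screen_traits)

    # ---- stage: Fst ----------------------------------------------------
    with _StageTimer(manifest, "fst"):
        fst_rows = []
        fst_by_mode = {}
        for mode in ("all", "shared"):
            try:
                est = fst_bootstrap_ci(
                    ascertain_snps(g, mode),
                    n_boot=cfg.n_boot,
                    seed=cfg.seed,
                    ascertainment=mode,
                )
            except EstimationError as exc:
                logger.warning("Fst (%s) unavailable: %s", mode, exc)
                continue
            fst_by_mode[mode] = est
            fst_rows.append(dataclasses.asdict(est))
        fst_df = pd.DataFrame(fst_rows)
        fst_path = outdir / "fst.tsv"
        fst_df.to_csv(fst_path, sep="\t", index=False)
        manifest.outputs["fst"] = str(fst_path)

    # ---- stage: Qst + trait table -------------------------------------
    with _StageTimer(manifest, "qst"):
        qst_by_trait = {}
        for trait in diverged:
            try:
                qst_by_trait[trait] = qst_for_trait(means, trait).qst_star
            except EstimationError as exc:
                logger.warning("Qst* unavailable for %s: %s", trait, exc)
        trait_df = pd.DataFrame(
            [
                {
                    "trait": r.trait,
                    "mean_1": r.mean_1,
                    "sd_1": r.sd_1,
                    "n_1": r.n_1,
                    "mean_2": r.mean_2,
                    "sd_2": r.sd_2,
                    "n_2": r.n_2,
                    "f_ratio": r.f_ratio,
                    "p_raw": r.p_raw,
                    "p_fdr": r.p_fdr,
                    "significant": r.p_fdr <= cfg.fdr_alpha,
                    "relative_divergence": r.relative_divergence,
                    "qst_star": qst_by_trait.get(r.trait, float("nan")),
                }
                for r in div
            ]
        )
        trait_path = outdir / "trait_divergence.tsv"
        trait_df.to_csv(trait_path, sep="\t", index=False)
        manifest.outputs["trait_divergence"] = str(trait_path)

    # ---- stage: univariate tests --------------------------------------
    with _StageTimer(manifest, "univariate"):
        uni = run_trait_family(means, g, diverged, cfg)
        uni_df = family_report(uni)
        uni_path = outdir / "qstfst_univariate.tsv"
        uni_df.to_csv(uni_path, sep="\t", index=False)
        manifest.outputs["univariate"] = str(uni_path)

    # ---- stage: multivariate test -------------------------------------
    with _StageTimer(manifest, "multivariate"):
        mv_traits = raw.get("multivariate_traits") or [
            t for t in MULTIVARIATE_TRAITS if t in means.traits
        ]
        if len(mv_traits) < 2:
            mv_traits = [t for t in diverged if t in means.traits]
        mv_result = None
        if len(mv_traits) >= 2:
            try:
                mv_result = multivariate_test(means, g, mv_traits, cfg)
            except EstimationError as exc:
                logger.warning("multivariate test unavailable: %s", exc)
        if mv_result is not None:
            mv_path = outdir / "multivariate.json"
            mv_path.write_text(
                json.dumps(
                    {
                        "rho_obs": mv_result.rho_obs,
                        "rho_ci": list(mv_result.rho_ci),
                        "rho_exp": mv_result.rho_exp,
                        "rho_exp_ci": list(mv_result.rho_exp_ci),
                        "mating_system": mv_result.mating_system,
                        "verdict": mv_result.verdict,
                        "traits": mv_result.trait_names,
                    },
                    indent=2,
                )
            )
            manifest.outputs["multivariate"] = str(mv_path)

    manifest_path = outdir / "manifest.json"
    manifest.to_json(manifest_path)
    manifest.outputs["manifest"] = str(manifest_path)
    return manifest


def report(manifest: RunManifest) -> str:
    """Render the run's three report tables as human-readable text, starring
    traits whose divergence survives the FDR correction."""
    lines: list[str] = [f"qstfstkit {manifest.version} run (seed {manifest.seed})", ""]
    trait_path = manifest.outputs.get("trait_divergence")
    if trait_path and Path(trait_path).exists():
        df = pd.read_csv(trait_path, sep="\t")
        lines.append("Trait divergence (nested ANOVA; * = significant after FDR):")
        if df.empty:
            lines.append("  (no traits)")
        for _, r in df.iterrows():
            star = "*" if bool(r.get("significant")) else " "
            qst = f"{r['qst_star']:.3f}" if np.isfinite(r["qst_star"]) else "   NA"
            lines.append(
                f"  {star} {r['trait']:<22} F={r['f_ratio']:>9.3f} "
                f"p_fdr={r['p_fdr']:.4g} reldiv={r['relative_divergence']:.2f} "
                f"Qst*={qst}"
            )
        lines.append("")
    fst_path = manifest.outputs.get("fst")
    if fst_path and Path(fst_path).exists():
        df = pd.read_csv(fst_path, sep="\t")
        lines.append("Fst (Weir-Cockerham, percentile bootstrap CI over loci):")
        for _, r in df.iterrows():
            lines.append(
                f"    {r['ascertainment']:<7} Fst={r['value']:.3f} "
                f"95% CI ({r['ci_low']:.3f}, {r['ci_high']:.3f}) "
                f"n_loci={int(r['n_loci'])}"
            )
        lines.append("")
    uni_path = manifest.outputs.get("univariate")
    if uni_path and Path(uni_path).exists():
        df = pd.read_csv(uni_path, sep="\t")
        lines.append("Univariate Qst-Fst p-values:")
        if df.empty:
            lines.append("  (no diverged traits)")
        else:
            pcols = [c for c in df.columns if c.startswith("p_")]
            for _, r in df.iterrows():
                cells = " ".join(f"{c[2:]}={r[c]:.3f}" for c in pcols if np.isfinite(r[c]))
                lines.append(f"    {r['trait']:<22} Qst*={r['qst']:.3f} {cells}")
        lines.append("")
    mv_path = manifest.outputs.get("multivariate")
    if mv_path and Path(mv_path).exists():
        mv = json.loads(Path(mv_path).read_text())
        lines.append(
            "Multivariate proportionality: "
            f"rho_obs={mv['rho_obs']:.3f} CI ({mv['rho_ci'][0]:.3f}, {mv['rho_ci'][1]:.3f}) "
            f"vs rho_exp={mv['rho_exp']:.4f} CI ({mv['rho_exp_ci'][0]:.4f}, "
            f"{mv['rho_exp_ci'][1]:.4f}) -> {mv['verdict']}"
        )
    return "\n".join(lines)
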