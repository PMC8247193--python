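"""End-to-end orchestration: simulate -> QC -> REML -> WssGWAS ->
tissue-specificity -> enrichment, with per-stage derived seeds and a run
manifest for provenance.

Stage seeds are derived from the global seed by a labeled SHA-256 hash so
any stage can be re-run independently yet reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io, genotype_qc, synthetic_data, tissue_expression, wssgwas
from .data_io import write_table
from .enrichment import enrich_all
from .relationships import numerator_relationship
from .variance_components import ModelSpec, VarianceComponents, reml_fit

__all__ = ["PipelineConfig", "run_pipeline", "derive_seed"]

log = logging.getLogger(__name__)

ALL_STAGES = ["simulate", "qc", "reml", "wssgwas", "tissuespec", "enrich"]


def derive_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the standard analysis settings
    (20-SNP windows, one reweighting iteration, top-10 QTL windows, top-1%
    window genes, top-10% tissue-specific genes, 20-kb gene extension,
    10,000 permutations)."""

    out_dir: str = "runs/run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # simulation
    sim: dict = field(default_factory=dict)
    n_atlas_genes: int = 2000
    atlas_spec_fraction: float = 0.1
    atlas_fold_change: float = 8.0
    # qc
    snp_call_min: float = 0.90
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    ind_call_min: float = 0.90
    outlier_k_sd: float = 3.0
    # reml
    reml_tol: float = 1e-8
    reml_max_iter: int = 200
    fit_correlations: bool = True
    # wssgwas
    window_size: int = 20
    n_reweight: int = 1
    top_k_windows: int = 10
    top_window_fraction: float = 0.01
    blend_weight: float = 0.95
    # tissue specificity
    tissue_top_fraction: float = 0.10
    # enrichment
    extension_bp: int = 20_000
    n_perm: int = 10_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def sim_config(self) -> synthetic_data.SimConfig:
        return synthetic_data.SimConfig(seed=derive_seed(self.seed, "simulate"), **self.sim)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in dependency order; returns the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "config": asdict(config)}
    _write_json(asdict(config), out / "config.json")

    ctx: dict = {}
    order = [s for s in ALL_STAGES if s in config.stages]
    deps = {
        "qc": ["simulate"],
        "reml": ["qc"],
        "wssgwas": ["reml"],
        "tissuespec": ["simulate"],
        "enrich": ["wssgwas", "tissuespec"],
    }
    for s in order:
        for d in deps.get(s, []):
            if d not in order[: order.index(s)]:
                raise RuntimeError(f"stage {s!r} requires stage {d!r} to be enabled before it")

    for stage in order:
        t0 = time.time()
        _STAGE_FUNCS[stage](config, out, ctx)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}
        log.info("stage %s done in %.1fs", stage, time.time() - t0)
    _write_json(manifest, out / "manifest.json")
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(config: PipelineConfig, out: Path, ctx: dict) -> None:
    sim = config.sim_config()
    ped, sexes = synthetic_data.simulate_pedigree(sim)
    mmap = synthetic_data.simulate_marker_map(sim)
    geno_all, founder_p = synthetic_data.simulate_genotypes(ped, mmap, sim)
    phen, truth = synthetic_data.simulate_phenotypes(ped, geno_all, sim, sexes)
    genotyped = synthetic_data.sample_genotyped_ids(phen, sim)
    idx = ped.index_of(genotyped)
    geno = data_io.GenotypeMatrix(geno_all.dosage[idx].copy(), genotyped)
    genes = synthetic_data.simulate_gene_annotation(config.n_atlas_genes, sim)
    expr, meta, atlas_truth = synthetic_data.simulate_expression_atlas(
        config.n_atlas_genes,
        spec_fraction=config.atlas_spec_fraction,
        fold_change=config.atlas_fold_change,
        seed=derive_seed(config.seed, "atlas"),
    )

    data_io.write_pedigree(ped, out / "pedigree.tsv")
    data_io.write_genotypes(geno, mmap, str(out / "genotypes"), dialect="plink_text")
    write_table(phen.data, out / "phenotypes.tsv")
    data_io.write_gene_annotation_bed(genes, out / "genes.bed")
    data_io.write_expression(expr, out / "expression_tpm.tsv")
    write_table(meta.table, out / "sample_metadata.tsv")
    _write_json(
        {
            "qtl": truth.qtl.to_dict(orient="list"),
            "sigma2_a": truth.sigma2_a,
            "sigma2_e": truth.sigma2_e,
            "planted_tissue_specific_genes": {
                t: sorted(g) for t, g in atlas_truth.planted_tissue_specific_genes.items()
            },
        },
        out / "truth.json",
    )
    ctx.update(
        pedigree=ped,
        marker_map=mmap,
        genotypes=geno,
        phenotypes=phen,
        truth=truth,
        genes=genes,
        expression=expr,
        metadata=meta,
        atlas_truth=atlas_truth,
        sim=sim,
    )


def _stage_qc(config: PipelineConfig, out: Path, ctx: dict) -> None:
    geno, mmap, report = genotype_qc.qc_filter(
        ctx["genotypes"],
        ctx["marker_map"],
        snp_call_min=config.snp_call_min,
        maf_min=config.maf_min,
        hwe_p_min=config.hwe_p_min,
        ind_call_min=config.ind_call_min,
    )
    phen = genotype_qc.phenotype_outlier_filter(ctx["phenotypes"], k_sd=config.outlier_k_sd)
    _write_json(report.to_dict(), out / "qc_report.json")
    write_table(phen.data, out / "phenotypes_qc.tsv")
    ctx.update(genotypes=geno, marker_map=mmap, phenotypes=phen, qc_report=report)


def _stage_reml(config: PipelineConfig, out: Path, ctx: dict) -> None:
    ped = ctx["pedigree"]
    phen = ctx["phenotypes"]
    a = numerator_relationship(ped)
    ctx["a_matrix"] = a
    rows = []
    vcs: dict[str, VarianceComponents] = {}
    for trait in phen.trait_names:
        res = reml_fit(
            ModelSpec([trait]),
            phen,
            a.values,
            a.animals,
            mode="single",
            tol=config.reml_tol,
            max_iter=config.reml_max_iter,
        )
        vcs[trait] = res.vc
        rows.append(
            {
                "trait": trait,
                "n": int(phen.data[trait].notna().sum()),
                "sigma2_a": res.vc.sigma2_a,
                "sigma2_e": res.vc.sigma2_e,
                "h2": res.h2[trait],
                "h2_se": res.h2_se[trait],
                "converged": res.converged,
                "n_iterations": res.n_iterations,
            }
        )
        log.info("reml %s: h2=%.3f (%d iter)", trait, res.h2[trait], res.n_iterations)
    write_table(pd.DataFrame(rows), out / "variance_components.tsv")
    ctx["vcs"] = vcs

    if config.fit_correlations and len(phen.trait_names) > 1:
        corr_rows = []
        for t1, t2 in combinations(phen.trait_names, 2):
            res = reml_fit(
                ModelSpec([t1, t2]),
                phen,
                a.values,
                a.animals,
                mode="bivariate",
                tol=max(config.reml_tol, 1e-6),
                max_iter=config.reml_max_iter,
            )
            corr_rows.append(
                {
                    "trait_1": t1,
                    "trait_2": t2,
                    "r_g": res.r_g,
                    "r_g_se": res.r_g_se,
                    "r_p": res.r_p,
                    "converged": res.converged,
                }
            )
        write_table(pd.DataFrame(corr_rows), out / "correlations.tsv")


def _stage_wssgwas(config: PipelineConfig, out: Path, ctx: dict) -> None:
    phen = ctx["phenotypes"]
    effects: dict[str, np.ndarray] = {}
    all_windows = []
    all_qtl = []
    for trait in phen.trait_names:
        state, _ = wssgwas.run_wssgwas(
            ModelSpec([trait]),
            phen,
            ctx["pedigree"],
            ctx["genotypes"],
            ctx["vcs"][trait],
            n_reweight=config.n_reweight,
            blend_weight=config.blend_weight,
        )
        win = wssgwas.window_variances(
            state, ctx["marker_map"], ctx["vcs"][trait], window_size=config.window_size
        )
        win.insert(0, "trait", trait)
        qtl = wssgwas.top_windows(win, k=config.top_k_windows)
        qtl.insert(0, "trait", trait)
        effects[trait] = state.u_hat
        all_windows.append(win)
        all_qtl.append(qtl)
    write_table(pd.concat(all_windows, ignore_index=True), out / "window_variances.tsv")
    write_table(pd.concat(all_qtl, ignore_index=True), out / "qtl_regions.tsv")
    eff = pd.DataFrame({"snp_id": ctx["marker_map"].snp_id, **effects})
    write_table(eff, out / "snp_effects.tsv")
    ctx["effects"] = effects


def _stage_tissuespec(config: PipelineConfig, out: Path, ctx: dict) -> None:
    scaled, genes = tissue_expression.scale_expression(ctx["expression"])
    meta = ctx["metadata"]
    gene_sets: dict[str, list[str]] = {}
    rows = []
    for system in meta.organ_systems():
        res = tissue_expression.fit_tissue_models(scaled, genes, meta, system)
        gene_sets[system] = tissue_expression.tissue_specific_genes(
            res, fraction=config.tissue_top_fraction
        )
        res.insert(0, "target", system)
        rows.append(res)
    write_table(pd.concat(rows, ignore_index=True), out / "tissue_t_statistics.tsv")
    sets_dir = out / "tissue_gene_sets"
    sets_dir.mkdir(exist_ok=True)
    for name, ids in gene_sets.items():
        (sets_dir / f"{name}.txt").write_text("\n".join(ids) + "\n")
    ctx["gene_sets"] = gene_sets


def _stage_enrich(config: PipelineConfig, out: Path, ctx: dict) -> None:
    table = enrich_all(
        ctx["effects"],
        ctx["gene_sets"],
        ctx["genes"],
        ctx["marker_map"],
        extension_bp=config.extension_bp,
        n_perm=config.n_perm,
        seed=derive_seed(config.seed, "enrich"),
    )
    write_table(table, out / "enrichment.tsv")
    ctx["enrichment"] = table


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "reml": _stage_reml,
    "wssgwas": _stage_wssgwas,
    "tissuespec": _stage_tissuespec,
    "enrich": _stage_enrich,
}
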