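"""End-to-end workflow: trait derivation -> precorrection -> QC -> GRM ->
null REML -> MLMA -> AWM per key trait -> gene tables, genomic
correlations and heritability contrasts, with a reproducibility manifest.

Each stage writes its outputs before the next starts, so a failed run
leaves partial results plus a manifest naming the failed stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import awm as awm_mod
from . import gwas as gwas_mod
from . import io as io_mod
from . import metrics as metrics_mod
from . import phenotypes as phen_mod
from .containers import TRAITS, FeednetError
from .simulate import SimConfig, simulate_population

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``simulate`` is set (a synthetic population is generated and
    written under ``outdir/inputs``) or the three input paths point at
    existing files.
    """

    outdir: str = "feednet_run"
    simulate: Optional[SimConfig] = None
    genotype_prefix: Optional[str] = None
    phenotype_path: Optional[str] = None
    annotation_path: Optional[str] = None
    r2_path: Optional[str] = None
    key_traits: tuple = ("RFI", "RG", "FE")
    qc: gwas_mod.QCThresholds = field(default_factory=gwas_mod.QCThresholds)
    p_threshold: float = 0.001
    r_threshold: float = 0.25
    min_other_traits: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def validate(self):
        if self.simulate is None:
            for name in ("genotype_prefix", "phenotype_path", "annotation_path"):
                p = getattr(self, name)
                if p is None:
                    raise FeednetError(
                        f"either 'simulate' or input path {name!r} must be set"
                    )
            for p in (
                f"{self.genotype_prefix}.bed",
                self.phenotype_path,
                self.annotation_path,
            ):
                if not Path(p).exists():
                    raise FeednetError(f"input path does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: RunConfig) -> str:
    d = {k: repr(v) for k, v in sorted(cfg.__dict__.items())}
    return hashlib.sha256(json.dumps(d).encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns the run manifest (also written
    to ``outdir/manifest.json``)."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "feednet 0.1.0",
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "outputs": {},
    }

    def _record(stage, paths):
        manifest["stages"].append(stage)
        for p in paths:
            p = Path(p)
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
        _write_manifest(out, manifest)

    try:
        # ---------------------------------------------- stage: inputs
        if cfg.simulate is not None:
            pop = simulate_population(cfg.simulate)
            inputs = out / "inputs"
            inputs.mkdir(exist_ok=True)
            io_mod.write_plink(pop.genotypes, str(inputs / "genotypes"))
            io_mod.write_phenotypes(pop.traits, str(inputs / "phenotypes.tsv"))
            io_mod.write_annotation_bed(pop.annotation, str(inputs / "annotation.bed"))
            truth = {
                "causal_ids": pop.causal_ids,
                "heritabilities": cfg.simulate.heritabilities,
                "seed": cfg.simulate.seed,
            }
            (inputs / "truth.json").write_text(json.dumps(truth, indent=2))
            g = pop.genotypes
            raw = pop.traits
            annotation = pop.annotation
            _record(
                "simulate",
                [
                    inputs / "genotypes.bed",
                    inputs / "genotypes.bim",
                    inputs / "genotypes.fam",
                    inputs / "phenotypes.tsv",
                    inputs / "annotation.bed",
                    inputs / "truth.json",
                ],
            )
        else:
            g = io_mod.read_plink(cfg.genotype_prefix)
            raw = io_mod.read_phenotypes(cfg.phenotype_path)
            annotation = io_mod.read_annotation(cfg.annotation_path)
            _record("load", [])

        # ---------------------------------------- stage: derive traits
        traits = phen_mod.derive_traits(raw)
        io_mod.write_phenotypes(traits, str(out / "traits.tsv"))
        _record("derive_traits", [out / "traits.tsv"])

        # ----------------------------------------- stage: precorrection
        corrected = phen_mod.precorrect_phenotypes(traits)
        corr_out = corrected[["animal_id", *TRAITS]].rename(
            columns={t: f"{t}_corrected" for t in TRAITS}
        )
        io_mod.write_phenotypes(corr_out, str(out / "traits_corrected.tsv"))
        _record("precorrect", [out / "traits_corrected.tsv"])

        # ----------------------------------------------------- stage: QC
        r2 = None
        if cfg.r2_path:
            r2tab = pd.read_csv(cfg.r2_path, sep="\t")
            r2 = r2tab.set_index("variant_id")["imputation_r2"]
        qc_table = gwas_mod.compute_qc_table(g, r2=r2)
        retained, qc_report = gwas_mod.qc_filter_variants(qc_table, cfg.qc)
        qc_table.to_csv(out / "qc_table.tsv", sep="\t", index=False)
        (out / "qc_report.json").write_text(json.dumps(qc_report, indent=2))
        if not retained:
            raise FeednetError("QC removed every variant; nothing to analyse")
        g_qc = g.subset_variants(retained)
        _record("qc", [out / "qc_table.tsv", out / "qc_report.json"])

        # ----------------------------------------- stage: GRM + GWAS
        grm = gwas_mod.compute_grm(g_qc)
        eig = gwas_mod.GRMEigen(grm)
        results = {}
        vc_rows = []
        for t in TRAITS:
            y = corrected[t].to_numpy(dtype=float)
            vc = gwas_mod.fit_null_reml(y, eig)
            res = gwas_mod.run_mlma(g_qc, y, eig, vc)
            results[t] = res
            res.to_csv(out / f"gwas_{t}.tsv", sep="\t", index=False)
            vc_rows.append(
                {
                    "trait": t,
                    "sigma_u2": vc.sigma_u2,
                    "sigma_e2": vc.sigma_e2,
                    "h2": vc.h2,
                    "se_h2": vc.se_h2,
                    "loglik": vc.loglik,
                }
            )
        pd.DataFrame(vc_rows).to_csv(
            out / "variance_components.tsv", sep="\t", index=False
        )
        _record(
            "gwas",
            [out / f"gwas_{t}.tsv" for t in TRAITS]
            + [out / "variance_components.tsv"],
        )

        # --------------------------------------------- stage: AWM runs
        summaries = {}
        gene_tables = {}
        awm_snp_sets = {}
        files = []
        for key in cfg.key_traits:
            acfg = awm_mod.AWMConfig(
                key_trait=key,
                p_threshold=cfg.p_threshold,
                r_threshold=cfg.r_threshold,
                min_other_traits=cfg.min_other_traits,
            )
            matrix = awm_mod.build_awm(results, acfg)
            awm_df = matrix.z.add_suffix("_z").join(
                matrix.assoc.add_suffix("_assoc")
            )
            awm_df.insert(0, "origin", matrix.origin)
            awm_df.to_csv(out / f"awm_{key}.tsv", sep="\t")
            files.append(out / f"awm_{key}.tsv")
            awm_snp_sets[key] = matrix.z.index.tolist()
            if matrix.is_empty():
                summaries[key] = awm_mod.summarize_network(pd.DataFrame(), key)
                gene_tables[key] = pd.DataFrame(columns=["gene_id"])
                continue
            gene_map = awm_mod.assign_genes(
                matrix.variants.reset_index(), annotation
            )
            table, unassigned = awm_mod.select_snp_per_gene(matrix, gene_map)
            table.to_csv(out / f"genes_{key}.tsv", sep="\t", index=False)
            files.append(out / f"genes_{key}.tsv")
            gene_tables[key] = table
            summary = awm_mod.summarize_network(table, key)
            summary["retained_traits"] = matrix.retained_traits
            summary["n_awm_variants"] = matrix.n_variants
            summary["n_variants_in_genes"] = int(matrix.n_variants - len(unassigned))
            summaries[key] = summary
            if matrix.n_variants >= 3 and len(matrix.retained_traits) >= 2:
                gc = metrics_mod.genomic_correlation(matrix)
                gc.to_csv(out / f"genomic_corr_{key}.tsv", sep="\t")
                files.append(out / f"genomic_corr_{key}.tsv")
        _record("awm", files)

        # --------------------------------- stage: cross-run gene overlap
        sets = {k: set(t["gene_id"]) for k, t in gene_tables.items()}
        keys = list(sets)
        overlap = {
            "shared_all": sorted(set.intersection(*sets.values())) if sets else [],
            "pairwise": {
                f"{a}&{b}": len(sets[a] & sets[b])
                for i, a in enumerate(keys)
                for b in keys[i + 1:]
            },
        }
        summary_json = {"awm": summaries, "overlap": overlap}
        (out / "summary.json").write_text(json.dumps(summary_json, indent=2))
        _record("summary", [out / "summary.json"])

        # ------------------------------- stage: heritability contrast
        rows = []
        rng = np.random.default_rng(cfg.seed)
        for key in cfg.key_traits:
            sel = awm_snp_sets.get(key, [])
            if not sel or len(sel) * 2 > g_qc.n_variants:
                continue
            hc = metrics_mod.heritability_contrast(
                corrected[key].to_numpy(dtype=float),
                g_qc,
                sel,
                seed=int(rng.integers(0, 2**31 - 1)),
                trait=key,
            )
            rows.append(
                {
                    "trait": key,
                    "h2_selected": hc.selected.h2,
                    "se_selected": hc.selected.se_h2,
                    "h2_random": hc.random.h2,
                    "se_random": hc.random.se_h2,
                    "n_snps": hc.n_snps,
                    "seed": hc.seed,
                }
            )
        if rows:
            pd.DataFrame(rows).to_csv(out / "h2_contrast.tsv", sep="\t", index=False)
            _record("h2_contrast", [out / "h2_contrast.tsv"])

        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest["status"] = "ok"
        _write_manifest(out, manifest)
        return manifest
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = (
            manifest["stages"][-1] + "+1" if manifest["stages"] else "inputs"
        )
        manifest["error"] = str(exc)
        _write_manifest(out, manifest)
        raise


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
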