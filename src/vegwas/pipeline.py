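"""End-to-end orchestration: simulate (optional) -> phenotype -> QC ->
SMR -> BayesB -> method intersection -> validation -> regions -> variant
screen, with a manifest of every output."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from vegwas import gwas_bmmr, gwas_smr, phenotype, regions as regions_mod, validation, variant_screen
from vegwas.genotype_qc import compute_grm, compute_pcs, impute_missing, qc_filter, read_plink
from vegwas.simulate import SimConfig, simulate_all

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "vegwas_out"
    seed: int = 1
    # inputs (non-simulate mode)
    litters: str | None = None
    plink_prefix: str | None = None
    vcf: str | None = None
    gff3: str | None = None
    # simulate mode
    simulate: dict | None = None
    # thresholds, paper defaults
    p_threshold: float = 1e-4
    p_relaxed: float = 2e-4
    bf_threshold: float = 10.0
    n_permutations: int = 10_000
    emp1_max: float = 0.0005
    group_window_bp: int = 500_000
    region_pad_bp: int = 1_000_000
    r2_threshold: float = 0.7
    min_depth: int = 5
    min_call_rate: float = 0.97
    min_maf: float = 0.05
    max_snp_missing: float = 0.05
    bayesb: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def validate(self) -> None:
        for name in ("p_threshold", "bf_threshold", "n_permutations", "r2_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.simulate is None:
            for name in ("litters", "plink_prefix", "vcf", "gff3"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} path required in non-simulate mode")
                probe = Path(p + ".map") if name == "plink_prefix" else Path(p)
                if not probe.exists():
                    stage = "variant_screen" if name in ("vcf", "gff3") else name
                    raise FileNotFoundError(f"missing input for stage {stage}: {probe}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to
    manifest.json). Reruns with an identical config are bit-identical."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name):
        logger.info("stage: %s", name)

    if cfg.simulate is not None:
        stage("simulate")
        sim_cfg = SimConfig(**{**cfg.simulate, "seed": cfg.seed})
        paths = simulate_all(sim_cfg, out / "sim")
        cfg.litters = paths["litters"]
        cfg.plink_prefix = paths["plink_prefix"]
        cfg.vcf = paths["vcf"]
        cfg.gff3 = paths["gff3"]
        outputs.update({f"sim_{k}": Path(v) for k, v in paths.items() if k != "plink_prefix"})

    stage("phenotype")
    litters = pd.read_csv(cfg.litters, sep="\t")
    pheno = phenotype.build_phenotypes(litters)
    outputs["phenotypes"] = out / "phenotypes.tsv"
    pheno.to_csv(outputs["phenotypes"], sep="\t", index=False)

    stage("qc")
    gs = read_plink(cfg.plink_prefix)
    gs = qc_filter(gs, cfg.min_call_rate, cfg.min_maf, cfg.max_snp_missing)
    gs = impute_missing(gs, seed=cfg.seed + 101)
    pheno = pheno[pheno["doe_id"].isin(gs.samples["doe_id"])].reset_index(drop=True)
    gs = gs.subset(individuals=gs.samples["doe_id"].isin(pheno["doe_id"]).to_numpy())

    grm = compute_grm(gs)
    pcs = compute_pcs(grm, k=min(5, gs.n_individuals - 1))
    outputs["grm"] = out / "grm.tsv"
    np.savetxt(outputs["grm"], grm.matrix, delimiter="\t")
    outputs["pcs"] = out / "pcs.tsv"
    np.savetxt(outputs["pcs"], pcs, delimiter="\t")

    stage("gwas-smr")
    smr = gwas_smr.mlma_loco(pheno, gs)
    wsmr = gwas_smr.weighted_smr(pheno, gs, pcs)
    outputs["smr_results"] = out / "smr_results.tsv"
    pd.concat([smr, wsmr]).to_csv(outputs["smr_results"], sep="\t", index=False)
    sig_smr = gwas_smr.smr_significant(smr, cfg.p_threshold, cfg.p_relaxed)

    stage("gwas-bayesb")
    bb_cfg = gwas_bmmr.BayesBConfig(**{"seed": cfg.seed + 202, **cfg.bayesb})
    bb = gwas_bmmr.run_bayesb(pheno, gs, bb_cfg)
    outputs["bmmr_results"] = out / "bmmr_results.tsv"
    bb.to_frame().to_csv(outputs["bmmr_results"], sep="\t", index=False)
    windows = gwas_bmmr.window_variance(bb, gs)
    outputs["windows"] = out / "windows.tsv"
    windows.to_csv(outputs["windows"], sep="\t", index=False)

    stage("intersect")
    bf_set = set(gwas_bmmr.bmmr_significant(bb, cfg.bf_threshold))
    strict = sig_smr[sig_smr["tier"] == "strict"]
    near = sig_smr[sig_smr["tier"] == "near"]
    both = sig_smr[sig_smr["snp"].isin(bf_set)].copy()
    logger.info(
        "intersection: %d strict-SMR, %d near-tier, %d BF>%g, %d retained",
        len(strict), len(near), len(bf_set), len(both),
    )
    outputs["candidates"] = out / "candidate_snps.tsv"
    both.to_csv(outputs["candidates"], sep="\t", index=False)

    validated = both
    if len(both):
        stage("validation")
        loco_grm = compute_grm(gs)
        vc = gwas_smr.estimate_variance_components(
            gs.samples[["doe_id"]].merge(pheno, on="doe_id")["ve"].to_numpy(), loco_grm
        )
        perm = validation.permutation_test(
            pheno, gs, both["snp"].tolist(), n_perm=cfg.n_permutations,
            seed=cfg.seed + 303, grm=loco_grm, vc=vc,
        )
        effects = validation.within_population_gwas(pheno, gs, both["snp"].tolist())
        verdict = validation.ci_overlap_filter(effects, perm, cfg.emp1_max)
        outputs["validation"] = out / "validation.tsv"
        verdict.merge(perm[["snp", "b", "n_perm"]], on="snp").to_csv(
            outputs["validation"], sep="\t", index=False
        )
        validated = both[both["snp"].isin(verdict[verdict["pass"]]["snp"])]

    stage("regions")
    region_list: list = []
    if len(validated):
        blocks = regions_mod.group_snps(validated, cfg.group_window_bp)
        sig_p = dict(zip(validated["snp"], validated["p"]))
        region_list = regions_mod.define_vqtl_regions(
            blocks, gs, sig_p, cfg.r2_threshold, cfg.region_pad_bp
        )
    outputs["regions"] = out / "regions.tsv"
    regions_mod.regions_frame(region_list).to_csv(outputs["regions"], sep="\t", index=False)

    stage("variant_screen")
    variants = variant_screen.read_vcf(cfg.vcf)
    retained, _, reject_counts = variant_screen.hard_filter(variants)
    relevant, table2 = variant_screen.select_relevant(retained, region_list)
    genes = variant_screen.read_gff3_genes(cfg.gff3)
    candidates = variant_screen.map_to_genes(relevant, genes)
    outputs["table2"] = out / "table2.tsv"
    table2.to_csv(outputs["table2"], sep="\t")
    outputs["relevant_variants"] = out / "relevant_variants.tsv"
    pd.DataFrame(
        [
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "type": v.vtype,
                "class": v.consequence_class(),
                "pattern": variant_screen.classify_segregation(v, cfg.min_depth).pattern,
            }
            for v in relevant
        ],
        columns=["chrom", "pos", "ref", "alt", "type", "class", "pattern"],
    ).to_csv(outputs["relevant_variants"], sep="\t", index=False)
    outputs["candidate_genes"] = out / "candidates.tsv"
    candidates.to_csv(outputs["candidate_genes"], sep="\t", index=False)

    manifest = {
        "config": {k: v for k, v in asdict(cfg).items()},
        "filter_rejections": reject_counts,
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
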