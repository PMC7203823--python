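"""Synthetic litter records, genotypes, and pooled-line VCF/GFF3 generation.

Everything downstream of raw data collection is exercised on data produced
here: three populations (base plus divergent high/low lines), repeated
litter-size records whose within-doe residual variance is under genetic
control at planted variance QTL, SNP panels with copy-process LD and
line-differentiated allele frequencies, and a two-pool VCF whose sites have
designated filter fates, consequence annotations, and line segregation
classes. All generators are deterministic under the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from vegwas.genotype_qc import GenotypeSet

#: consequence vocabulary accepted in site plans (SnpEff sequence-ontology terms)
CONSEQUENCE_VOCAB = {
    "missense_variant",
    "frameshift_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "splice_region_variant",
    "synonymous_variant",
    "intron_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
}

SNV_FAIL_RULES = {"QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum"}
INDEL_FAIL_RULES = {"QD", "FS", "ReadPosRankSum"}
SEG_CLASSES = {"absent", "fixed", "segregating", "no_call"}


@dataclass
class CausalVariant:
    """A planted QTL: effect applies per alt-allele copy."""

    chrom: str
    bp: int
    effect: float
    freq_divergence: float = 0.0


@dataclass
class SimConfig:
    n_base: int = 96
    n_high: int = 149
    n_low: int = 139
    parity_range: tuple = (2, 12)
    n_chrom: int = 2
    snps_per_chrom: int = 100
    marker_spacing_bp: int = 100_000
    causal_vqtl: list = field(default_factory=list)
    causal_mean_qtl: list = field(default_factory=list)
    mu_tnb: float = 8.0
    sigma2_doe: float = 0.5
    base_log_resvar: float = float(np.log(4.0))
    n_yearseason: int = 47
    n_paritylact: int = 3
    copy_prob: float = 0.7
    missing_rate: float = 0.0
    pool_depth: float = 27.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.causal_vqtl = [
            c if isinstance(c, CausalVariant) else CausalVariant(*c) for c in self.causal_vqtl
        ]
        self.causal_mean_qtl = [
            c if isinstance(c, CausalVariant) else CausalVariant(*c) for c in self.causal_mean_qtl
        ]
        if self.parity_range[0] < 2:
            raise ValueError("minimum parities per doe is 2")
        if self.parity_range[1] < self.parity_range[0]:
            raise ValueError("invalid parity range")
        if self.n_chrom < 1 or self.snps_per_chrom < 1:
            raise ValueError("need at least one chromosome and one SNP")
        if self.n_base + self.n_high + self.n_low < 1:
            raise ValueError("need at least one individual")
        if not (0.0 <= self.copy_prob <= 1.0):
            raise ValueError("copy_prob must be in [0, 1]")
        if self.sigma2_doe < 0 or self.pool_depth <= 0:
            raise ValueError("variance/depth parameters must be positive")
        for c in self.causal_vqtl + self.causal_mean_qtl:
            if not (0.0 <= c.freq_divergence < 1.0):
                raise ValueError("freq divergence must be in [0, 1)")


@dataclass
class SiteSpec:
    """One planned VCF site with its intended downstream fate."""

    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    gene_id: str = ""
    gene_name: str = ""
    fail_rule: str | None = None  # None = passes hard filters
    low_class: str = "segregating"
    high_class: str = "absent"

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCE_VOCAB:
            raise ValueError(f"unknown consequence term: {self.consequence}")
        if self.low_class not in SEG_CLASSES or self.high_class not in SEG_CLASSES:
            raise ValueError("unknown segregation class")
        vtype = "SNV" if len(self.ref) == len(self.alt) else "INDEL"
        allowed = SNV_FAIL_RULES if vtype == "SNV" else INDEL_FAIL_RULES
        if self.fail_rule is not None and self.fail_rule not in allowed:
            raise ValueError(f"rule {self.fail_rule} not applicable to {vtype}")

    @property
    def vtype(self) -> str:
        return "SNV" if len(self.ref) == len(self.alt) else "INDEL"


@dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic data."""

    causal_vqtl_ids: list = field(default_factory=list)
    causal_mean_ids: list = field(default_factory=list)
    line_freqs: dict = field(default_factory=dict)  # snp_id -> {pop: freq}
    doe_log_resvar: dict = field(default_factory=dict)
    vcf_sites: list = field(default_factory=list)  # dicts, see simulate_pooled_vcf
    screen_regions: list = field(default_factory=list)  # (chrom, start, end)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


# ---------------------------------------------------------------------------
# genotypes


def _snp_positions(cfg: SimConfig, chrom: str) -> np.ndarray:
    pos = (np.arange(cfg.snps_per_chrom) + 1) * cfg.marker_spacing_bp
    extra = [c.bp for c in cfg.causal_vqtl + cfg.causal_mean_qtl if str(c.chrom) == chrom]
    return np.unique(np.concatenate([pos, np.asarray(extra, dtype=int)]) if extra else pos)


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeSet, SimTruth]:
    """Draw dosages for all three populations.

    Haplotypes follow a first-order copying process along each chromosome:
    the allele at a SNP copies the previous SNP's allele with probability
    ``copy_prob`` and is otherwise drawn fresh at the SNP's line-specific
    frequency. Causal SNPs are always drawn fresh so their planted
    line-frequency divergence is realised exactly in expectation.
    """
    rng = np.random.default_rng([cfg.seed, 11])
    chroms = [str(c + 1) for c in range(cfg.n_chrom)]
    causal = {(str(c.chrom), int(c.bp)): c for c in cfg.causal_vqtl + cfg.causal_mean_qtl}

    map_rows = []
    base_freq, freq = [], {"base": [], "high": [], "low": []}
    fresh_always = []
    for chrom in chroms:
        for bp in _snp_positions(cfg, chrom):
            snp_id = f"snp_{chrom}_{bp}"
            map_rows.append({"snp_id": snp_id, "chrom": chrom, "bp": int(bp)})
            p0 = rng.uniform(0.1, 0.9)
            cv = causal.get((chrom, int(bp)))
            div = cv.freq_divergence if cv is not None else 0.0
            freq["base"].append(p0)
            freq["high"].append(float(np.clip(p0 + div / 2.0, 0.02, 0.98)))
            freq["low"].append(float(np.clip(p0 - div / 2.0, 0.02, 0.98)))
            base_freq.append(p0)
            fresh_always.append(cv is not None)
    snp_map = pd.DataFrame(map_rows)
    m = len(snp_map)
    fresh_always = np.asarray(fresh_always)

    pops = ["base"] * cfg.n_base + ["high"] * cfg.n_high + ["low"] * cfg.n_low
    ids = (
        [f"base_{i:04d}" for i in range(cfg.n_base)]
        + [f"high_{i:04d}" for i in range(cfg.n_high)]
        + [f"low_{i:04d}" for i in range(cfg.n_low)]
    )
    n = len(pops)
    chrom_arr = snp_map["chrom"].to_numpy()
    dosages = np.zeros((n, m))
    for i, pop in enumerate(pops):
        p = np.asarray(freq[pop])
        hap = np.zeros((2, m))
        for h in range(2):
            prev_chrom = None
            for j in range(m):
                new_chrom = chrom_arr[j] != prev_chrom
                prev_chrom = chrom_arr[j]
                if new_chrom or fresh_always[j] or rng.random() >= cfg.copy_prob:
                    hap[h, j] = rng.random() < p[j]
                else:
                    hap[h, j] = hap[h, j - 1]
        dosages[i] = hap.sum(axis=0)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = np.nan

    gs = GenotypeSet(
        dosages=dosages,
        snp_map=snp_map,
        samples=pd.DataFrame({"doe_id": ids, "population": pops}),
    )
    truth = SimTruth(
        causal_vqtl_ids=[f"snp_{c.chrom}_{c.bp}" for c in cfg.causal_vqtl],
        causal_mean_ids=[f"snp_{c.chrom}_{c.bp}" for c in cfg.causal_mean_qtl],
        line_freqs={
            sid: {pop: freq[pop][j] for pop in freq}
            for j, sid in enumerate(snp_map["snp_id"])
        },
        screen_regions=[
            (str(c.chrom), max(1, c.bp - 1_000_000), c.bp + 1_000_000) for c in cfg.causal_vqtl
        ]
        or [(chroms[0], 1, 2_000_000)],
    )
    return gs, truth


# ---------------------------------------------------------------------------
# litters


def simulate_litters(
    cfg: SimConfig, genotypes: GenotypeSet, truth: SimTruth | None = None
) -> pd.DataFrame:
    """Repeated TNB records per doe.

    TNB_ij = round_nonneg(mu + yearseason + paritylact + u_j + qtl_mean_j + e_ij)
    with u_j ~ N(0, sigma2_doe) and e_ij ~ N(0, exp(base_log_resvar +
    sum_k g_jk v_k)) over the planted variance-QTL dosages g_jk.
    """
    rng = np.random.default_rng([cfg.seed, 23])
    snp_idx = {sid: j for j, sid in enumerate(genotypes.snp_map["snp_id"])}
    vq = [(snp_idx[f"snp_{c.chrom}_{c.bp}"], c.effect) for c in cfg.causal_vqtl]
    mq = [(snp_idx[f"snp_{c.chrom}_{c.bp}"], c.effect) for c in cfg.causal_mean_qtl]

    ys_eff = rng.normal(0.0, 0.7, size=cfg.n_yearseason)
    pl_eff = rng.normal(0.0, 0.3, size=cfg.n_paritylact)

    p_obs = genotypes.alt_freq()
    rows = []
    lo, hi = cfg.parity_range
    for i in range(genotypes.n_individuals):
        doe = genotypes.samples["doe_id"].iloc[i]
        pop = genotypes.samples["population"].iloc[i]
        g = genotypes.dosages[i].copy()
        nanmask = np.isnan(g)
        if nanmask.any():  # expected dosage stands in for missing calls
            g[nanmask] = 2.0 * p_obs[nanmask]
        log_rv = cfg.base_log_resvar + sum(g[j] * v for j, v in vq)
        mean_shift = sum(g[j] * a for j, a in mq)
        u = rng.normal(0.0, np.sqrt(cfg.sigma2_doe))
        n_par = int(rng.integers(lo, hi + 1))
        sd = np.sqrt(np.exp(log_rv))
        if truth is not None:
            truth.doe_log_resvar[str(doe)] = float(log_rv)
        for parity in range(1, n_par + 1):
            ys = int(rng.integers(cfg.n_yearseason))
            pl = int(rng.integers(cfg.n_paritylact))
            raw = cfg.mu_tnb + ys_eff[ys] + pl_eff[pl] + u + mean_shift + rng.normal(0.0, sd)
            rows.append(
                {
                    "doe_id": doe,
                    "parity": parity,
                    "tnb": int(max(0, round(raw))),
                    "yearseason": f"ys{ys}",
                    "paritylact": f"pl{pl}",
                    "population": pop,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene models


GENE_STEP_BP = 200_000
GENE_LEN_BP = 50_000
GENE_FIRST_BP = 10_001


def gene_grid(cfg: SimConfig) -> pd.DataFrame:
    """Deterministic gene models: on every chromosome a gene of 50 kb starts
    every 200 kb, so region-gene intersections are predictable."""
    span = (cfg.snps_per_chrom + 1) * cfg.marker_spacing_bp + 2_000_000
    rows = []
    for c in range(cfg.n_chrom):
        chrom = str(c + 1)
        k = 0
        start = GENE_FIRST_BP
        while start + GENE_LEN_BP <= span:
            rows.append(
                {
                    "gene_id": f"G{chrom}_{k:04d}",
                    "gene_name": f"GENE{chrom}_{k:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + GENE_LEN_BP - 1,
                    "strand": "+" if k % 2 == 0 else "-",
                }
            )
            k += 1
            start += GENE_STEP_BP
    return pd.DataFrame(rows)


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g['gene_id']};Name={g['gene_name']};biotype=protein_coding"
            fh.write(
                f"{g['chrom']}\tvegwas_sim\tgene\t{g['start']}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# pooled VCF


_PASS_STATS = {"QD": 20.0, "FS": 5.0, "MQ": 60.0, "MQRankSum": 0.5, "ReadPosRankSum": 0.5}
_FAIL_STATS = {
    "SNV": {"QD": 1.2, "FS": 80.0, "MQ": 30.0, "MQRankSum": -13.0, "ReadPosRankSum": -9.0},
    "INDEL": {"QD": 1.2, "FS": 250.0, "ReadPosRankSum": -25.0},
}

_GT = {"absent": "0/0", "fixed": "1/1", "segregating": "0/1", "no_call": "./."}


def default_site_plan(cfg: SimConfig, truth: SimTruth) -> list[SiteSpec]:
    """A plan exercising every screen path: relevant and irrelevant
    consequences inside the planted regions, relevant consequences outside
    them, one failing site per hard-filter rule, every segregation pattern,
    and at least one INDEL."""
    genes = gene_grid(cfg)
    plan: list[SiteSpec] = []
    rng = np.random.default_rng([cfg.seed, 37])

    def genes_in(chrom, start, end):
        sub = genes[(genes["chrom"] == chrom) & (genes["start"] >= start) & (genes["end"] <= end)]
        return sub.reset_index(drop=True)

    seg_cycle = [
        ("segregating", "absent"),
        ("absent", "segregating"),
        ("segregating", "fixed"),
        ("fixed", "absent"),  # echoes the fixed-in-one / absent-in-other pattern
        ("segregating", "segregating"),
    ]
    relevant_terms = [
        "missense_variant",
        "frameshift_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "splice_region_variant",
    ]
    background_terms = ["synonymous_variant", "intron_variant", "upstream_gene_variant"]

    k = 0
    for chrom, start, end in truth.screen_regions:
        sub = genes_in(str(chrom), start, end)
        if len(sub) == 0:
            continue
        for t, term in enumerate(relevant_terms + background_terms):
            g = sub.iloc[t % len(sub)]
            pos = int(g["start"]) + 100 + 137 * k
            low_c, high_c = seg_cycle[k % len(seg_cycle)]
            if term == "frameshift_variant":
                ref, alt = "CA", "C"  # left-anchored 1-bp deletion
            else:
                ref, alt = "A", "G"
            plan.append(
                SiteSpec(
                    chrom=str(chrom),
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    consequence=term,
                    gene_id=str(g["gene_id"]),
                    gene_name=str(g["gene_name"]),
                    low_class=low_c,
                    high_class=high_c,
                )
            )
            k += 1
        # one intergenic site between genes
        plan.append(
            SiteSpec(
                chrom=str(chrom),
                pos=int(sub.iloc[0]["end"]) + 1_000,
                ref="T",
                alt="C",
                consequence="intergenic_variant",
                low_class="segregating",
                high_class="segregating",
            )
        )
        # failing sites, one per SNV rule plus the INDEL FS rule
        g = sub.iloc[0]
        for r, rule in enumerate(sorted(SNV_FAIL_RULES)):
            plan.append(
                SiteSpec(
                    chrom=str(chrom),
                    pos=int(g["start"]) + 20_000 + 13 * r + 137 * k,
                    ref="G",
                    alt="T",
                    consequence="missense_variant",
                    gene_id=str(g["gene_id"]),
                    gene_name=str(g["gene_name"]),
                    fail_rule=rule,
                    low_class="segregating",
                    high_class="absent",
                )
            )
        plan.append(
            SiteSpec(
                chrom=str(chrom),
                pos=int(g["start"]) + 30_000 + 137 * k,
                ref="TG",
                alt="T",
                consequence="3_prime_UTR_variant",
                gene_id=str(g["gene_id"]),
                gene_name=str(g["gene_name"]),
                fail_rule="FS",
                low_class="fixed",
                high_class="absent",
            )
        )
        k += 3

    # relevant consequence outside every region: must be excluded by the gate
    chrom0 = str(truth.screen_regions[0][0])
    ends = [e for c, s, e in truth.screen_regions if str(c) == chrom0]
    far = max(ends) + 500_000
    g_far = genes[genes["chrom"] == chrom0]
    g_far = g_far[g_far["start"] > far]
    if len(g_far):
        g = g_far.iloc[0]
        plan.append(
            SiteSpec(
                chrom=chrom0,
                pos=int(g["start"]) + 500,
                ref="A",
                alt="T",
                consequence="missense_variant",
                gene_id=str(g["gene_id"]),
                gene_name=str(g["gene_name"]),
                low_class="segregating",
                high_class="absent",
            )
        )
    _ = rng  # reserved for future jitter
    return sorted(plan, key=lambda s: (int(s.chrom), s.pos))


def simulate_pooled_vcf(
    cfg: SimConfig,
    truth: SimTruth,
    path: str | Path,
    site_plan: list[SiteSpec] | None = None,
    min_depth: int = 5,
) -> list[SiteSpec]:
    """Write a two-pool VCF v4.2 ('low' and 'high' samples) realising the
    site plan, and record each site's intended fate in ``truth.vcf_sites``.

    Pool depths are Poisson(pool_depth) per line with allele depths drawn to
    guarantee the designated segregation class at the given ``min_depth``.
    """
    plan = default_site_plan(cfg, truth) if site_plan is None else site_plan
    rng = np.random.default_rng([cfg.seed, 41])
    relevant = {
        "missense_variant",
        "frameshift_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "splice_region_variant",
    }

    def depths(seg_class):
        if seg_class == "no_call":
            total = int(rng.integers(0, min_depth))
            alt = int(rng.integers(0, total + 1)) if total else 0
            return total - alt, alt
        total = max(int(rng.poisson(cfg.pool_depth)), min_depth + 1)
        if seg_class == "absent":
            return total, 0
        if seg_class == "fixed":
            return 0, total
        f = rng.uniform(0.2, 0.8)
        alt = int(np.clip(rng.binomial(total, f), 1, total - 1))
        return total - alt, alt

    def in_region(chrom, pos):
        return any(
            str(chrom) == str(c) and s <= pos <= e for c, s, e in truth.screen_regions
        )

    truth.vcf_sites = []
    lines = []
    for s in plan:
        stats = dict(_PASS_STATS)
        if s.vtype == "INDEL":
            stats.pop("MQRankSum")
            stats.pop("MQ")
        if s.fail_rule is not None:
            stats[s.fail_rule] = _FAIL_STATS[s.vtype][s.fail_rule]
        lr, la = depths(s.low_class)
        hr, ha = depths(s.high_class)
        ann = "|".join(
            [
                s.alt,
                s.consequence,
                "MODIFIER",
                s.gene_name,
                s.gene_id,
                "transcript",
                f"{s.gene_id}.t1" if s.gene_id else "",
                "protein_coding" if s.gene_id else "",
                "1/1",
            ]
            + [""] * 7
        )
        info = ";".join(
            [f"{k}={stats[k]:g}" for k in sorted(stats)] + [f"ANN={ann}"]
        )
        lines.append(
            "\t".join(
                [
                    s.chrom,
                    str(s.pos),
                    ".",
                    s.ref,
                    s.alt,
                    "100",
                    ".",
                    info,
                    "GT:AD:DP",
                    f"{_GT[s.low_class]}:{lr},{la}:{lr + la}",
                    f"{_GT[s.high_class]}:{hr},{ha}:{hr + ha}",
                ]
            )
        )
        passes = s.fail_rule is None
        inside = in_region(s.chrom, s.pos)
        truth.vcf_sites.append(
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref,
                "alt": s.alt,
                "type": s.vtype,
                "consequence": s.consequence,
                "gene_id": s.gene_id,
                "fail_rule": s.fail_rule,
                "pass_filter": passes,
                "in_region": inside,
                "relevant": bool(passes and inside and s.consequence in relevant),
                "low_class": s.low_class,
                "high_class": s.high_class,
                "low_depths": [lr, la],
                "high_depths": [hr, ha],
            }
        )

    contigs = sorted({s.chrom for s in plan}, key=int)
    span = (cfg.snps_per_chrom + 1) * cfg.marker_spacing_bp + 20_000_000
    header = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c},length={span}>" for c in contigs],
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">',
        '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">',
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
        "Allele|Annotation|Annotation_Impact|Gene_Name|Gene_ID|Feature_Type|Feature_ID|"
        'Transcript_BioType|Rank|HGVS.c|HGVS.p|cDNA|CDS|AA|Distance|Errors">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tlow\thigh",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write("\n".join(lines) + "\n")
    return plan


# ---------------------------------------------------------------------------
# convenience: write everything


def simulate_all(cfg: SimConfig, outdir: str | Path) -> dict:
    """Generate litters.tsv, PLINK .ped/.map, pools.vcf, genes.gff3 and
    truth.json under ``outdir``; returns the paths."""
    from vegwas.genotype_qc import write_plink

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gs, truth = simulate_genotypes(cfg)
    litters = simulate_litters(cfg, gs, truth)
    genes = gene_grid(cfg)
    paths = {
        "litters": outdir / "litters.tsv",
        "plink_prefix": outdir / "genotypes",
        "vcf": outdir / "pools.vcf",
        "gff3": outdir / "genes.gff3",
        "truth": outdir / "truth.json",
    }
    litters.to_csv(paths["litters"], sep="\t", index=False)
    write_plink(gs, paths["plink_prefix"])
    simulate_pooled_vcf(cfg, truth, paths["vcf"])
    write_gff3(genes, paths["gff3"])
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
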