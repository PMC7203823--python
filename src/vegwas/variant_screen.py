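"""Pooled-line VCF screening inside vQTL regions.

Applies GATK-style hard filters (strict inequalities, missing statistics
never trigger a rule), keeps variants with consequences affecting the
protein, UTRs, or splicing, classifies the line-level allele status from
pooled depths, and intersects the survivors with gene models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from vegwas.regions import VqtlRegion

logger = logging.getLogger(__name__)

RELEVANT_TERMS = {
    "missense_variant",
    "frameshift_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "splice_region_variant",
}

#: Table rows for the class-count matrix, most severe first
CLASS_ORDER = [
    "frameshift",
    "missense",
    "splicing",
    "five_prime_utr",
    "three_prime_utr",
    "synonymous",
    "intron",
    "upstream",
    "downstream",
    "intergenic",
]

_TERM_TO_CLASS = {
    "frameshift_variant": "frameshift",
    "missense_variant": "missense",
    "splice_acceptor_variant": "splicing",
    "splice_donor_variant": "splicing",
    "splice_region_variant": "splicing",
    "5_prime_UTR_variant": "five_prime_utr",
    "3_prime_UTR_variant": "three_prime_utr",
    "synonymous_variant": "synonymous",
    "intron_variant": "intron",
    "upstream_gene_variant": "upstream",
    "downstream_gene_variant": "downstream",
    "intergenic_variant": "intergenic",
}

SNV_FILTERS = {
    "QD": lambda v: v < 2.0,
    "FS": lambda v: v > 60.0,
    "MQ": lambda v: v < 40.0,
    "MQRankSum": lambda v: v < -12.5,
    "ReadPosRankSum": lambda v: v < -8.0,
}
INDEL_FILTERS = {
    "QD": lambda v: v < 2.0,
    "FS": lambda v: v > 200.0,
    "ReadPosRankSum": lambda v: v < -20.0,
}


@dataclass
class Annotation:
    terms: list  # consequence terms ('&'-joined in ANN split apart)
    gene_name: str
    gene_id: str
    transcript: str


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    stats: dict  # QD/FS/MQ/MQRankSum/ReadPosRankSum; missing keys absent
    annotations: list  # of Annotation
    depths: dict  # line -> (ref_depth, alt_depth)
    filter_rule: str | None = None  # set by hard_filter when rejected

    @property
    def vtype(self) -> str:
        return "SNV" if len(self.ref) == len(self.alt) else "INDEL"

    @property
    def terms(self) -> set:
        return {t for a in self.annotations for t in a.terms}

    @property
    def gene_ids(self) -> set:
        return {a.gene_id for a in self.annotations if a.gene_id}

    def consequence_class(self) -> str:
        """Most severe class over all annotations (SnpEff severity order)."""
        classes = {_TERM_TO_CLASS[t] for t in self.terms if t in _TERM_TO_CLASS}
        for cls in CLASS_ORDER:
            if cls in classes:
                return cls
        return "intergenic"


@dataclass
class SegregationClass:
    per_line: dict  # line -> absent | fixed | segregating | no_call
    pattern: str


def parse_ann(ann: str) -> list[Annotation]:
    """Parse a SnpEff-style ANN INFO value (comma-separated annotations,
    pipe-delimited subfields: Allele|Annotation|Impact|Gene_Name|Gene_ID|
    Feature_Type|Feature_ID|...)."""
    out = []
    for entry in ann.split(","):
        f = entry.split("|")
        if len(f) < 5:
            continue
        out.append(
            Annotation(
                terms=f[1].split("&"),
                gene_name=f[3],
                gene_id=f[4],
                transcript=f[6] if len(f) > 6 else "",
            )
        )
    return out


def read_vcf(path: str | Path, line_names: tuple = ("low", "high")) -> list[VariantRecord]:
    """Read a two-pool VCF via cyvcf2; per-line depths come from the AD
    format field. Multi-allelic sites are not supported."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    order = [samples.index(ln) for ln in line_names]
    records = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"multi-allelic site at {v.CHROM}:{v.POS}")
        stats = {}
        for key in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum"):
            val = v.INFO.get(key)
            if val is not None:
                stats[key] = float(val)
        ann = v.INFO.get("ANN")
        depths = {}
        ad = v.format("AD")
        for ln, i in zip(line_names, order):
            depths[ln] = (int(ad[i][0]), int(ad[i][1]))
        records.append(
            VariantRecord(
                chrom=str(v.CHROM),
                pos=int(v.POS),
                ref=str(v.REF),
                alt=str(v.ALT[0]),
                stats=stats,
                annotations=parse_ann(ann) if ann else [],
                depths=depths,
            )
        )
    return records


def hard_filter(variants: list[VariantRecord]) -> tuple[list, list, dict]:
    """Split variants into retained and rejected by the type-specific hard
    filters; a record fails if ANY rule fires. Absent statistics never
    trigger their rule. Rejected records are labelled with the first firing
    rule, not deleted."""
    retained, rejected = [], []
    counts: dict = {}
    for v in variants:
        if v.vtype == "SNV":
            rules = SNV_FILTERS
        elif v.vtype == "INDEL":
            rules = INDEL_FILTERS
        else:  # pragma: no cover - vtype is total
            raise ValueError(f"unknown variant type at {v.chrom}:{v.pos}")
        fired = None
        for name, rule in rules.items():
            if name in v.stats and rule(v.stats[name]):
                fired = name
                break
        if fired is None:
            retained.append(v)
        else:
            v.filter_rule = fired
            counts[fired] = counts.get(fired, 0) + 1
            rejected.append(v)
    return retained, rejected, counts


def _in_regions(v: VariantRecord, regions: list[VqtlRegion]) -> bool:
    return any(
        v.chrom == r.chrom and r.start <= v.pos <= r.end for r in regions
    )


def select_relevant(
    variants: list[VariantRecord], regions: list[VqtlRegion]
) -> tuple[list, pd.DataFrame]:
    """Keep in-region variants whose consequence terms intersect the relevant
    set (protein/UTR/splicing). Also returns the consequence-class x region
    count table over all in-region variants (one count per variant at its
    most severe class)."""
    region_label = lambda r: f"{r.chrom}:{r.start}-{r.end}"
    counts = {region_label(r): {c: 0 for c in CLASS_ORDER} for r in regions}
    relevant = []
    for v in variants:
        hit = [r for r in regions if v.chrom == r.chrom and r.start <= v.pos <= r.end]
        if not hit:
            continue
        counts[region_label(hit[0])][v.consequence_class()] += 1
        if v.terms & RELEVANT_TERMS:
            relevant.append(v)
    table = pd.DataFrame(counts)
    table.index.name = "class"
    table["total"] = table.sum(axis=1)
    return relevant, table


def classify_segregation(v: VariantRecord, min_depth: int = 5) -> SegregationClass:
    """Line-level allele status from pooled depths: alt depth 0 -> absent,
    ref depth 0 -> fixed, both positive -> segregating; total depth below
    ``min_depth`` -> no_call."""
    per_line = {}
    for line, (ref_d, alt_d) in v.depths.items():
        if ref_d < 0 or alt_d < 0:
            raise ValueError("negative depth")
        if ref_d + alt_d < min_depth:
            per_line[line] = "no_call"
        elif alt_d == 0:
            per_line[line] = "absent"
        elif ref_d == 0:
            per_line[line] = "fixed"
        else:
            per_line[line] = "segregating"
    pattern = "/".join(f"{cls}-in-{line}" for line, cls in sorted(per_line.items()))
    return SegregationClass(per_line=per_line, pattern=pattern)


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Gene records from a GFF3 file: gene_id, gene_name, chrom, start, end."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
        dtype={"chrom": str},
    )
    df = df[df["type"] == "gene"]

    def attr(s, key):
        for part in s.split(";"):
            if part.startswith(key + "="):
                return part[len(key) + 1 :]
        return ""

    return pd.DataFrame(
        {
            "gene_id": df["attrs"].map(lambda s: attr(s, "ID")),
            "gene_name": df["attrs"].map(lambda s: attr(s, "Name")),
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
        }
    ).reset_index(drop=True)


def map_to_genes(relevant: list[VariantRecord], genes: pd.DataFrame) -> pd.DataFrame:
    """Candidate genes: every gene whose 1-based inclusive span contains at
    least one relevant variant. Variants annotated to a gene id missing from
    the models are flagged."""
    counts: dict = {}
    for v in relevant:
        hits = genes[
            (genes["chrom"] == v.chrom) & (genes["start"] <= v.pos) & (genes["end"] >= v.pos)
        ]
        known = set(genes["gene_id"])
        for gid in v.gene_ids:
            if gid not in known:
                logger.warning(
                    "annotation mismatch at %s:%d (gene %s not in models)", v.chrom, v.pos, gid
                )
        for _, g in hits.iterrows():
            key = g["gene_id"]
            if key not in counts:
                counts[key] = {
                    "gene_id": key,
                    "gene_name": g["gene_name"],
                    "chrom": g["chrom"],
                    "start": int(g["start"]),
                    "n_variants": 0,
                }
            counts[key]["n_variants"] += 1
    columns = ["gene_id", "gene_name", "chrom", "start", "n_variants"]
    out = pd.DataFrame(list(counts.values()), columns=columns)
    if len(out):
        out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    return out
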