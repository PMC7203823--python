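"""LD-based definition of vQTL genomic regions around validated SNPs.

Significant SNPs within 0.5 Mb of each other are grouped into blocks, each
block is padded by 1 Mb, and within the padded interval the region is the
connected component of the r-squared > 0.7 genotype-correlation graph that
contains the significant SNPs. A significant SNP with no partner above the
threshold yields a point region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vegwas.genotype_qc import GenotypeSet


@dataclass
class Block:
    chrom: str
    snps: list  # snp ids
    positions: list  # bp, same order

    @property
    def min_bp(self) -> int:
        return min(self.positions)

    @property
    def max_bp(self) -> int:
        return max(self.positions)


@dataclass
class LDMatrix:
    snp_ids: list
    positions: np.ndarray
    r2: np.ndarray  # symmetric, diagonal 1 for polymorphic SNPs

    def pair(self, a: str, b: str) -> float:
        i, j = self.snp_ids.index(a), self.snp_ids.index(b)
        return float(self.r2[i, j])


@dataclass
class VqtlRegion:
    chrom: str
    start: int
    end: int
    member_snps: list
    anchor: str
    genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start after end")


def group_snps(validated: pd.DataFrame, window_bp: int = 500_000) -> list[Block]:
    """Single-linkage grouping: significant SNPs on the same chromosome at
    most ``window_bp`` apart join a block. ``validated`` needs columns
    snp, chrom, bp."""
    blocks: list[Block] = []
    for chrom, grp in validated.groupby("chrom", sort=False):
        grp = grp.sort_values("bp")
        cur_snps, cur_pos = [], []
        for _, row in grp.iterrows():
            if cur_pos and row["bp"] - cur_pos[-1] > window_bp:
                blocks.append(Block(str(chrom), cur_snps, cur_pos))
                cur_snps, cur_pos = [], []
            cur_snps = cur_snps + [row["snp"]]
            cur_pos = cur_pos + [int(row["bp"])]
        if cur_snps:
            blocks.append(Block(str(chrom), cur_snps, cur_pos))
    return blocks


def expand_blocks(blocks: list[Block], pad_bp: int = 1_000_000) -> list[tuple]:
    """Pad each block to [min_bp - pad, max_bp + pad], floored at 1 bp.
    Returns (chrom, start, end, block) tuples; overlapping padded intervals
    stay distinct until LD merging."""
    return [(b.chrom, max(1, b.min_bp - pad_bp), b.max_bp + pad_bp, b) for b in blocks]


def ld_r2(gs: GenotypeSet, chrom: str, start: int, end: int) -> LDMatrix:
    """Squared Pearson correlation of dosage vectors for all SNP pairs in the
    interval (composite genotype r2; genotypes are unphased). Monomorphic
    SNPs are excluded."""
    bp = gs.snp_map["bp"].to_numpy()
    on = (gs.snp_map["chrom"].astype(str) == str(chrom)).to_numpy() & (bp >= start) & (bp <= end)
    idx = np.flatnonzero(on)
    dos = gs.dosages[:, idx]
    if np.isnan(dos).any():
        raise ValueError("impute missing genotypes before LD computation")
    sd = dos.std(axis=0)
    poly = sd > 1e-12
    idx = idx[poly]
    dos = dos[:, poly]
    if idx.size == 0:
        return LDMatrix(snp_ids=[], positions=np.array([], dtype=int), r2=np.zeros((0, 0)))
    corr = np.corrcoef(dos, rowvar=False)
    corr = np.atleast_2d(corr)
    return LDMatrix(
        snp_ids=gs.snp_map["snp_id"].iloc[idx].tolist(),
        positions=gs.snp_map["bp"].iloc[idx].to_numpy(),
        r2=corr**2,
    )


def _components(adj: np.ndarray) -> list[list[int]]:
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.flatnonzero(adj[u]):
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def define_vqtl_regions(
    blocks: list[Block],
    gs: GenotypeSet,
    significance: dict | None = None,
    r2_threshold: float = 0.7,
    pad_bp: int = 1_000_000,
    mode: str = "component",
) -> list[VqtlRegion]:
    """Turn significant-SNP blocks into regions via LD in the padded interval.

    mode='component': the region is the union of connected components (edges
    where r2 > threshold) containing the block's significant SNPs.
    mode='clique': only SNPs with r2 > threshold to every significant member
    join the region. ``significance`` maps snp id -> p-value to pick the
    anchor (lowest p); defaults to the first significant SNP.
    """
    if mode not in ("component", "clique"):
        raise ValueError("mode must be 'component' or 'clique'")
    regions = []
    for chrom, start, end, block in expand_blocks(blocks, pad_bp):
        ld = ld_r2(gs, chrom, start, end)
        sig_set = set(block.snps)
        if significance:
            anchor = min(block.snps, key=lambda s: significance.get(s, np.inf))
        else:
            anchor = block.snps[0]
        if not ld.snp_ids:
            pos = block.positions[block.snps.index(anchor)]
            regions.append(VqtlRegion(chrom, pos, pos, sorted(sig_set), anchor))
            continue
        in_ld = [i for i, s in enumerate(ld.snp_ids) if s in sig_set]
        members: set = set(block.snps)
        if in_ld:
            adj = ld.r2 > r2_threshold
            np.fill_diagonal(adj, False)
            if mode == "component":
                for comp in _components(adj):
                    if any(i in comp for i in in_ld):
                        members |= {ld.snp_ids[i] for i in comp}
            else:
                for i, s in enumerate(ld.snp_ids):
                    if all(ld.r2[i, j] > r2_threshold for j in in_ld if j != i):
                        members.add(s)
        pos_map = dict(zip(ld.snp_ids, ld.positions))
        pos_map.update(dict(zip(block.snps, block.positions)))
        pos = [int(pos_map[s]) for s in members]
        regions.append(
            VqtlRegion(chrom, min(pos), max(pos), sorted(members), anchor)
        )
    return regions


def regions_frame(regions: list[VqtlRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "n_snps": [len(r.member_snps) for r in regions],
            "anchor_snp": [r.anchor for r in regions],
        }
    )
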