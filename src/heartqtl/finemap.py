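"""LD-based collapsing of significant blocks into fine-mapped loci.

Significant blocks from the association scan are clumped greedily, best p
first (PLINK-clump style): the strongest remaining block seeds a region and
absorbs every remaining significant block whose dosage correlation with the
seed reaches r^2 >= threshold or that lies within the merge distance on the
same chromosome. Regions are annotated with overlapping genes from a GFF3
annotation and candidate genes are ranked by association strength plus
differential-expression and loss-of-function evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import FdrThresholds
from .blocks import GenotypeMatrix
from .errors import InvalidSpecError


@dataclass
class FineMappedRegion:
    """A distinct locus collapsed from one or more correlated blocks."""

    region_id: str
    chrom: str
    start: int
    end: int
    lead_block: str
    lead_neg_log10_p: float
    member_blocks: list[str]
    phenotypes: list[str]
    genes: list[dict] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def _dosage_r2(dosage: np.ndarray, i: int, j: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between block i and blocks j (0 if degenerate)."""
    x = dosage[i].astype(float)
    ys = dosage[j].astype(float)
    xc = x - x.mean()
    yc = ys - ys.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ xc) / denom
    return np.where(denom > 0, r**2, 0.0)


def significant_blocks(
    scan: pd.DataFrame, thresholds: dict[str, FdrThresholds], level: float = 0.05
) -> pd.DataFrame:
    """One row per block significant in any phenotype at the given FDR level.

    Keeps the best (smallest) p over phenotypes and the list of phenotypes in
    which the block passes its per-phenotype threshold.
    """
    sig = []
    for name, thr in thresholds.items():
        sub = scan[scan["phenotype"] == name]
        mask = thr.passes(sub["neg_log10_p"].to_numpy(), level)
        sig.append(sub[mask])
    if not sig:
        return pd.DataFrame(columns=list(scan.columns))
    stacked = pd.concat(sig, ignore_index=True)
    if stacked.empty:
        return stacked
    best = (
        stacked.sort_values(["p", "block_id"])
        .groupby("block_id", as_index=False)
        .first()
    )
    phenos = stacked.groupby("block_id")["phenotype"].apply(
        lambda s: sorted(set(s))
    )
    best["phenotypes"] = best["block_id"].map(phenos)
    return best.sort_values(["p", "block_id"]).reset_index(drop=True)


def collapse_loci(
    scan: pd.DataFrame,
    matrix: GenotypeMatrix,
    thresholds: dict[str, FdrThresholds],
    r2_threshold: float = 0.5,
    merge_distance: int = 500_000,
    level: float = 0.05,
) -> list[FineMappedRegion]:
    """Greedy best-p-first clumping of significant blocks into distinct loci."""
    sig = significant_blocks(scan, thresholds, level)
    if sig.empty:
        return []
    block_index = {b: k for k, b in enumerate(matrix.block_table["block_id"])}
    missing = [b for b in sig["block_id"] if b not in block_index]
    if missing:
        raise InvalidSpecError(f"scan blocks absent from matrix: {missing[:3]}")
    dosage = matrix.dosage
    sig = sig.reset_index(drop=True)
    remaining = list(sig.index)
    regions: list[FineMappedRegion] = []
    while remaining:
        seed = remaining[0]  # rows sorted by ascending p
        seed_row = sig.loc[seed]
        same_chrom = [k for k in remaining if sig.at[k, "chrom"] == seed_row["chrom"]]
        rows = np.array([block_index[sig.at[k, "block_id"]] for k in same_chrom])
        r2 = _dosage_r2(dosage, block_index[seed_row["block_id"]], rows)
        members = set()
        for k, r2k in zip(same_chrom, r2):
            dist = max(
                sig.at[k, "start"] - seed_row["end"],
                seed_row["start"] - sig.at[k, "end"],
                0,
            )
            if r2k >= r2_threshold or dist <= merge_distance:
                members.add(k)
        # absorb anything physically inside the member span so that regions
        # on a chromosome never interleave
        changed = True
        while changed:
            start = min(sig.at[k, "start"] for k in members)
            end = max(sig.at[k, "end"] for k in members)
            inside = {
                k
                for k in same_chrom
                if k not in members
                and sig.at[k, "start"] < end
                and sig.at[k, "end"] > start
            }
            changed = bool(inside)
            members |= inside
        member_rows = sig.loc[sorted(members)]
        phenos = sorted({p for ps in member_rows["phenotypes"] for p in ps})
        regions.append(
            FineMappedRegion(
                region_id="",
                chrom=str(seed_row["chrom"]),
                start=int(member_rows["start"].min()),
                end=int(member_rows["end"].max()),
                lead_block=str(seed_row["block_id"]),
                lead_neg_log10_p=float(seed_row["neg_log10_p"]),
                member_blocks=list(member_rows["block_id"]),
                phenotypes=phenos,
            )
        )
        remaining = [k for k in remaining if k not in members]
    regions = _merge_overlaps(regions)
    regions.sort(key=lambda r: (r.chrom, r.start))
    for i, reg in enumerate(regions):
        reg.region_id = f"R{i:03d}"
    return regions


def _merge_overlaps(regions: list[FineMappedRegion]) -> list[FineMappedRegion]:
    """Union any regions whose intervals overlap on the same chromosome."""
    out: list[FineMappedRegion] = []
    for reg in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        if out and out[-1].chrom == reg.chrom and reg.start < out[-1].end:
            prev = out[-1]
            if reg.lead_neg_log10_p > prev.lead_neg_log10_p:
                prev.lead_block = reg.lead_block
                prev.lead_neg_log10_p = reg.lead_neg_log10_p
            prev.end = max(prev.end, reg.end)
            prev.member_blocks = sorted(set(prev.member_blocks) | set(reg.member_blocks))
            prev.phenotypes = sorted(set(prev.phenotypes) | set(reg.phenotypes))
        else:
            out.append(reg)
    return out


def annotate_regions(
    regions: list[FineMappedRegion], genes: pd.DataFrame
) -> list[FineMappedRegion]:
    """Attach genes overlapping each region by >= 1 bp (any-overlap rule).

    ``genes`` is a table (gene_id, chrom, start, end, ...) in 0-based
    half-open coordinates, as produced by :func:`heartqtl.io.read_gff3_genes`.
    """
    for reg in regions:
        sub = genes[
            (genes["chrom"] == reg.chrom)
            & (genes["start"] < reg.end)
            & (genes["end"] > reg.start)
        ]
        reg.genes = [
            {"gene_id": gid, "start": int(s), "end": int(e)}
            for gid, s, e in zip(sub["gene_id"], sub["start"], sub["end"])
        ]
    return regions


def rank_candidates(
    regions: list[FineMappedRegion],
    de_table: pd.DataFrame | None = None,
    lof_table: pd.DataFrame | None = None,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    de_fdr: float = 0.01,
    de_fc: float = 2.0,
    min_log10p: float = 3.0,
    log10p_cap: float = 10.0,
) -> pd.DataFrame:
    """Score and rank genes in strongly associated regions.

    Only regions with lead -log10 p strictly above ``min_log10p`` contribute.
    score = w1 * min(lead -log10 p, cap)
          + w2 * [DE: adjusted p < de_fdr and |fold change| >= de_fc]
          + w3 * [>= 1 predicted loss-of-function variant].
    Ties break by higher -log10 p, then gene id.
    """
    if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
        raise InvalidSpecError("weights must be non-negative and not all zero")
    de_lookup: dict[str, bool] = {}
    if de_table is not None and len(de_table):
        lfc_cut = np.log2(de_fc)
        for row in de_table.itertuples(index=False):
            de_lookup[row.gene_id] = bool(
                row.padj < de_fdr and abs(row.log2fc) >= lfc_cut
            )
    lof_lookup: dict[str, int] = {}
    if lof_table is not None and len(lof_table):
        lof_lookup = dict(zip(lof_table["gene_id"], lof_table["lof_count"].astype(int)))
    w1, w2, w3 = weights
    rows = []
    for reg in regions:
        if not reg.lead_neg_log10_p > min_log10p:
            continue
        for g in reg.genes:
            gid = g["gene_id"]
            de_flag = de_lookup.get(gid, False)
            lof = lof_lookup.get(gid, 0)
            score = (
                w1 * min(reg.lead_neg_log10_p, log10p_cap)
                + w2 * float(de_flag)
                + w3 * float(lof > 0)
            )
            rows.append(
                {
                    "gene_id": gid,
                    "region_id": reg.region_id,
                    "lead_neg_log10_p": reg.lead_neg_log10_p,
                    "de_flag": int(de_flag),
                    "lof_count": lof,
                    "score": score,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "region_id", "lead_neg_log10_p", "de_flag", "lof_count", "score"],
    )
    if table.empty:
        table["rank"] = pd.Series(dtype=int)
        return table
    table = table.sort_values(
        ["score", "lead_neg_log10_p", "gene_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
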