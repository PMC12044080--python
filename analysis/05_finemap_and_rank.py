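#!/usr/bin/env python
"""Stage 5 — collapse significant blocks into loci and rank candidate genes.

Greedy LD clumping around the most significant block, gene annotation of the
resulting regions from GFF3 (a synthetic annotation is generated when none is
configured), and evidence-weighted candidate scoring.
"""

import argparse
from pathlib import Path

from heartqtl import finemap, io, simulate
from heartqtl.pipeline import AnalysisConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", default="analysis/config.yaml")
    args = parser.parse_args()
    cfg = AnalysisConfig.from_yaml(args.config)
    out = Path(cfg.out_dir)

    matrix = io.read_genotype_matrix(out / "genotype_matrix.tsv")
    scan = io.read_scan(out / "scan.tsv")
    thresholds = io.read_thresholds(out / "fdr_thresholds.json")
    regions = finemap.collapse_loci(
        scan, matrix, thresholds,
        r2_threshold=cfg.r2_threshold,
        merge_distance=cfg.merge_distance,
        level=cfg.fdr_level,
    )
    if cfg.gff3 is not None:
        genes = io.read_gff3_genes(cfg.gff3)
    else:
        genes = simulate.simulate_gene_annotation(cfg.genome_spec(), cfg.seed + 6)
        io.write_gff3_genes(genes, out / "genes.gff3")
    finemap.annotate_regions(regions, genes)
    de = io.read_evidence_de(cfg.de_table) if cfg.de_table else None
    lof = io.read_evidence_lof(cfg.lof_table) if cfg.lof_table else None
    candidates = finemap.rank_candidates(
        regions, de, lof,
        de_fdr=cfg.de_fdr, de_fc=cfg.de_fc, min_log10p=cfg.min_log10p,
    )

    io.write_regions(regions, out / "regions.json", out / "regions.bed")
    io.write_candidates(candidates, out / "candidates.tsv")
    print(f"regions: {len(regions)}")
    for r in regions:
        print(
            f"  {r.region_id} {r.chrom}:{r.start}-{r.end} "
            f"lead -log10 p = {r.lead_neg_log10_p:.2f}, genes = {r.n_genes}"
        )
    print(f"ranked candidates: {len(candidates)}")
    print(f"wrote {out}/regions.json, regions.bed, candidates.tsv")


if __name__ == "__main__":
    main()
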