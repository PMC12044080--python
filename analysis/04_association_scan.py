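#!/usr/bin/env python
"""Stage 4 — mixed-model association scan with permutation FDR thresholds.

Estimates kinship from the block dosages, fits a single-variance-component
LMM per phenotype (heart rate at 21/28/35 degrees C and the temperature-
variance phenotype) and calibrates 1% and 5% discovery thresholds by
phenotype permutation.
"""

import argparse
from pathlib import Path

from heartqtl import assoc, io
from heartqtl.pipeline import AnalysisConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", default="analysis/config.yaml")
    args = parser.parse_args()
    cfg = AnalysisConfig.from_yaml(args.config)
    out = Path(cfg.out_dir)

    matrix = io.read_genotype_matrix(out / "genotype_matrix.tsv")
    phenotypes = io.read_phenotypes(out / "phenotypes.tsv")
    kinship = assoc.estimate_kinship(matrix)
    scan, thresholds, h2 = assoc.scan_all_phenotypes(
        matrix, phenotypes, kinship, n_perm=cfg.n_perm, seed=cfg.seed + 5,
        levels=cfg.fdr_levels, phenotype_names=cfg.phenotypes,
    )

    io.write_scan(scan, out / "scan.tsv")
    io.write_thresholds(thresholds, out / "fdr_thresholds.json")
    for name, thr in thresholds.items():
        n_pass = int(
            thr.passes(
                scan.loc[scan["phenotype"] == name, "neg_log10_p"].to_numpy(),
                cfg.fdr_level,
            ).sum()
        )
        print(
            f"{name}: h2 = {h2[name]:.2f}, "
            f"5% FDR threshold = {thr.thresholds[cfg.fdr_level]:.2f}, "
            f"significant blocks = {n_pass}"
        )
    print(f"wrote {out}/scan.tsv, fdr_thresholds.json")


if __name__ == "__main__":
    main()
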