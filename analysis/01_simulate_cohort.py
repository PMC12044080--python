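#!/usr/bin/env python
"""Stage 1 — simulate the F2 cohort.

Generates the marker map, the recombinant cohort, ultra-low-coverage allele
counts and multi-temperature heart-rate phenotypes, and writes them as text
artifacts under the configured output directory.
"""

import argparse
from pathlib import Path

from heartqtl import io, simulate
from heartqtl.pipeline import AnalysisConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", default="analysis/config.yaml")
    args = parser.parse_args()
    cfg = AnalysisConfig.from_yaml(args.config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spec = cfg.genome_spec()
    markers = simulate.simulate_marker_map(spec, cfg.seed + 1)
    truth = simulate.simulate_f2_cohort(markers, cfg.n_individuals, spec, cfg.seed + 2)
    counts = simulate.simulate_allele_counts(truth, markers, spec, cfg.seed + 3)
    phenotypes = simulate.simulate_phenotypes(
        truth, cfg.qtl_list(), cfg.baselines, cfg.noise_sd,
        cfg.arrhythmia_rate, cfg.seed + 4,
    )

    io.write_marker_map(markers, out / "markers.tsv")
    io.write_allele_counts(counts, markers, out / "allele_counts.tsv")
    io.write_phenotypes(phenotypes, out / "phenotypes.tsv")
    print(f"markers: {markers.n_markers}")
    print(f"individuals: {cfg.n_individuals}")
    print(f"total reads: {counts.total_reads()}")
    print(f"wrote {out}/markers.tsv, allele_counts.tsv, phenotypes.tsv")


if __name__ == "__main__":
    main()
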