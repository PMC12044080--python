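#!/usr/bin/env python
"""Stage 2 — window the allele counts and decode genotypes with the HMM.

Reads the marker map and allele counts written by stage 1, aggregates counts
into fixed windows, Viterbi-decodes the three-state genotype path of every
individual and calls crossover breakpoints at state changes.
"""

import argparse
from pathlib import Path

from heartqtl import hmm, io
from heartqtl.pipeline import AnalysisConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", default="analysis/config.yaml")
    args = parser.parse_args()
    cfg = AnalysisConfig.from_yaml(args.config)
    out = Path(cfg.out_dir)

    markers = io.read_marker_map(out / "markers.tsv")
    counts = io.read_allele_counts(out / "allele_counts.tsv", markers)
    windows = hmm.aggregate_windows(counts, markers, cfg.window_size)
    paths = hmm.decode_cohort(
        windows, crossover_rate=cfg.crossover_rate, error=cfg.hmm_error
    )
    crossovers = hmm.call_crossovers(paths)

    io.write_window_states(paths, out / "window_states.tsv")
    io.write_crossovers(crossovers, out / "crossovers.tsv")
    per_ind = len(crossovers) / len(paths.samples)
    print(f"decoded {len(paths.samples)} individuals on {len(paths.chrom_names)} chromosomes")
    print(f"crossovers called: {len(crossovers)} ({per_ind:.2f} per individual)")
    print(f"wrote {out}/window_states.tsv, crossovers.tsv")


if __name__ == "__main__":
    main()
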