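"""Shared fixtures: a desk-scale analogue of the study design.

The heavy session fixture simulates one cohort under the study regime
(2 chromosomes x 25 Mb, 1 marker/kb, coverage 0.78, 1% read error,
1.5 crossovers per gamete per chromosome, n = 300) and runs it through
windowing, HMM decoding and block segmentation once; statistical tests
share it.
"""

from __future__ import annotations

import numpy as np
import pytest

import heartqtl as hq

STUDY_SEED = 11


@pytest.fixture(scope="session")
def study_spec() -> hq.simulate.GenomeSpec:
    return hq.simulate.GenomeSpec(
        chromosomes=(("chr1", 25_000_000), ("chr2", 25_000_000)),
        marker_density=1e-3,
        coverage=0.78,
        read_error=0.01,
        ref_bias=0.0,
        crossover_rate=1.5,
    )


@pytest.fixture(scope="session")
def study_cohort(study_spec):
    """Simulated cohort with truth, decoded paths, blocks, matrix and kinship."""
    spec = study_spec
    markers = hq.simulate.simulate_marker_map(spec, STUDY_SEED)
    truth = hq.simulate.simulate_f2_cohort(markers, 300, spec, STUDY_SEED + 1)
    counts = hq.simulate.simulate_allele_counts(truth, markers, spec, STUDY_SEED + 2)
    windows = hq.hmm.aggregate_windows(counts, markers, 5000)
    paths = hq.hmm.decode_cohort(windows, crossover_rate=spec.crossover_rate, error=0.02)
    crossovers = hq.hmm.call_crossovers(paths)
    blockset = hq.blocks.segment_genome(
        crossovers, spec.chrom_lengths, 10_000, spec.chrom_names
    )
    matrix = hq.blocks.fill_genotype_matrix(blockset, paths)
    kinship = hq.assoc.estimate_kinship(matrix)
    return {
        "spec": spec,
        "markers": markers,
        "truth": truth,
        "counts": counts,
        "windows": windows,
        "paths": paths,
        "crossovers": crossovers,
        "blockset": blockset,
        "matrix": matrix,
        "kinship": kinship,
    }


@pytest.fixture
def tiny_spec() -> hq.simulate.GenomeSpec:
    return hq.simulate.GenomeSpec(
        chromosomes=(("chr1", 1_000_000),),
        marker_density=1e-3,
        coverage=0.78,
        read_error=0.0,
        crossover_rate=1.0,
    )


def resolvable_breakpoints(truth, chrom: str, window_size: int) -> dict[str, np.ndarray]:
    """True crossovers detectable at window resolution, per sample.

    Excludes breakpoints with a neighbouring breakpoint of the same
    individual within one window (their window-level effects cancel or
    merge) and breakpoints within one window of a chromosome end.
    """
    length = truth.chrom_lengths[chrom]
    out = {}
    for i, sample in enumerate(truth.samples):
        bps = truth.breakpoints_of(i, chrom)
        keep = []
        for k, b in enumerate(bps):
            near_prev = k > 0 and b - bps[k - 1] <= window_size
            near_next = k + 1 < len(bps) and bps[k + 1] - b <= window_size
            near_end = b <= window_size or b >= length - window_size
            if not (near_prev or near_next or near_end):
                keep.append(b)
        out[sample] = np.asarray(keep, dtype=np.int64)
    return out
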