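"""Cohort-wide recombination blocks and the block genotype matrix.

Crossover breakpoints from every individual are merged, snapped to a mapping
grid (default 10 kb — the finest resolution the block map can claim), and the
genome is segmented at every distinct boundary. Within a block no sampled
individual recombines, so each individual carries a single AA/AB/BB state
over it, giving a dense blocks x individuals genotype matrix. Segregation
diagnostics test each block against the Mendelian 1:2:1 expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, InvalidSpecError
from .hmm import GenotypePaths
from .simulate import STATE_LABELS


@dataclass
class BlockSet:
    """Non-overlapping intervals exactly tiling each chromosome."""

    grid: int
    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    boundaries: dict[str, np.ndarray]  # per chrom, includes 0 and length

    def __post_init__(self) -> None:
        for chrom in self.chrom_names:
            b = self.boundaries[chrom]
            if b[0] != 0 or b[-1] != self.chrom_lengths[chrom]:
                raise ConsistencyError(f"{chrom}: blocks do not tile the chromosome")
            if (np.diff(b) <= 0).any():
                raise ConsistencyError(f"{chrom}: block boundaries not increasing")

    def table(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chrom_names:
            b = self.boundaries[chrom]
            for s, e in zip(b[:-1], b[1:]):
                rows.append(
                    {
                        "block_id": f"{chrom}:{int(s)}-{int(e)}",
                        "chrom": chrom,
                        "start": int(s),
                        "end": int(e),
                    }
                )
        return pd.DataFrame(rows, columns=["block_id", "chrom", "start", "end"])

    @property
    def n_blocks(self) -> int:
        return sum(len(self.boundaries[c]) - 1 for c in self.chrom_names)

    def block_lengths(self) -> np.ndarray:
        return np.concatenate([np.diff(self.boundaries[c]) for c in self.chrom_names])


def segment_genome(
    crossovers: pd.DataFrame,
    chrom_lengths: dict[str, int],
    grid: int = 10_000,
    chrom_names: list[str] | None = None,
) -> BlockSet:
    """Segment every chromosome at the union of grid-snapped breakpoints.

    Breakpoints are snapped to the nearest grid multiple, duplicates
    collapsed, and any resulting block shorter than the grid (possible only
    at the chromosome end when the length is not a grid multiple) is merged
    into its left neighbor.
    """
    if grid <= 0:
        raise InvalidSpecError("grid must be > 0")
    chrom_names = chrom_names or list(chrom_lengths)
    boundaries: dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        length = chrom_lengths[chrom]
        if len(crossovers):
            bp = crossovers.loc[crossovers["chrom"] == chrom, "pos"].to_numpy()
        else:
            bp = np.array([], dtype=np.int64)
        if len(bp) and ((bp < 0) | (bp > length)).any():
            raise InvalidSpecError(f"{chrom}: breakpoint outside chromosome bounds")
        snapped = np.round(bp / grid).astype(np.int64) * grid
        interior = np.unique(snapped[(snapped > 0) & (snapped < length)])
        kept = [0]
        for b in interior:
            if b - kept[-1] >= grid:
                kept.append(int(b))
        if len(kept) > 1 and length - kept[-1] < grid:
            kept.pop()
        kept.append(length)
        boundaries[chrom] = np.asarray(kept, dtype=np.int64)
    return BlockSet(grid, list(chrom_names), dict(chrom_lengths), boundaries)


@dataclass
class GenotypeMatrix:
    """Blocks x individuals genotype states with an additive dosage view."""

    block_table: pd.DataFrame  # block_id, chrom, start, end
    samples: list[str]
    states: np.ndarray  # (n_blocks, n_samples) int8, 0=AA 1=AB 2=BB

    @property
    def dosage(self) -> np.ndarray:
        """Count of A alleles per cell: AA=2, AB=1, BB=0."""
        return (2 - self.states).astype(np.int8)

    @property
    def n_blocks(self) -> int:
        return self.states.shape[0]

    @property
    def n(self) -> int:
        return self.states.shape[1]


def fill_genotype_matrix(
    blocks: BlockSet, paths: GenotypePaths, strict: bool = False
) -> GenotypeMatrix:
    """Project each individual's window path onto the block segmentation.

    When the grid is a multiple of the HMM window size a decoded transition
    can sit at a window boundary that is not a block boundary; the block call
    is then the majority state over the block's windows, ties resolved toward
    the state of the block's first window. With ``strict=True`` any
    non-constant block raises instead (use when grid == window size).
    """
    w = paths.window_size
    s = len(paths.samples)
    all_states = []
    for chrom in blocks.chrom_names:
        st = paths.states[chrom]
        b = blocks.boundaries[chrom]
        for start, end in zip(b[:-1], b[1:]):
            w0 = int(start) // w
            w1 = min(-(-int(end) // w), st.shape[1])
            sub = st[:, w0:w1]
            if strict and (sub != sub[:, :1]).any():
                raise ConsistencyError(
                    f"{chrom}:{start}-{end}: block straddles a state change"
                )
            counts = np.stack([(sub == k).sum(axis=1) for k in range(3)])
            first = sub[:, 0].astype(np.intp)
            max_count = counts.max(axis=0)
            first_count = counts[first, np.arange(s)]
            call = np.where(first_count == max_count, first, counts.argmax(axis=0))
            all_states.append(call.astype(np.int8))
    return GenotypeMatrix(
        block_table=blocks.table(),
        samples=list(paths.samples),
        states=np.asarray(all_states, dtype=np.int8),
    )


def expand_to_windows(matrix: GenotypeMatrix, window_size: int,
                      chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Re-expand block calls to per-window state tracks (round-trip check)."""
    out: dict[str, np.ndarray] = {}
    bt = matrix.block_table
    for chrom, length in chrom_lengths.items():
        n_win = -(-length // window_size)
        track = np.empty((len(matrix.samples), n_win), dtype=np.int8)
        sel = bt.index[bt["chrom"] == chrom]
        for idx in sel:
            start, end = bt.at[idx, "start"], bt.at[idx, "end"]
            w0 = start // window_size
            w1 = min(-(-end // window_size), n_win)
            track[:, w0:w1] = matrix.states[idx][:, None]
        out[chrom] = track
    return out


@dataclass
class SegregationReport:
    """Per-block Mendelian 1:2:1 diagnostics and the cohort-wide AA excess."""

    table: pd.DataFrame  # block_id, n_aa, n_ab, n_bb, frac_*, chi2, p
    aa_excess: float


def segregation_diagnostics(matrix: GenotypeMatrix) -> SegregationReport:
    """Chi-square each block against expected (n/4, n/2, n/4), df = 2."""
    n = matrix.n
    if n < 1:
        raise InvalidSpecError("at least one individual required")
    counts = np.stack(
        [(matrix.states == k).sum(axis=1) for k in range(3)], axis=1
    ).astype(float)
    expected = np.array([n / 4, n / 2, n / 4])
    chi2 = ((counts - expected) ** 2 / expected).sum(axis=1)
    pval = stats.chi2.sf(chi2, df=2)
    frac = counts / n
    table = matrix.block_table.copy()
    for k, lab in enumerate(STATE_LABELS):
        table[f"n_{lab.lower()}"] = counts[:, k].astype(int)
        table[f"frac_{lab.lower()}"] = frac[:, k]
    table["chi2"] = chi2
    table["p"] = pval
    aa_excess = float(frac[:, 0].mean() - 0.25)
    return SegregationReport(table=table, aa_excess=aa_excess)
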