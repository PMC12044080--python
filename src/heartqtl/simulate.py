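"""Forward simulation of an F2 intercross of two inbred founders.

The generator emulates the study design this package analyses: two fully
inbred founder strains (allele A vs allele B at every marker), an F1
heterozygote, and an F2 cohort in which every individual is a mosaic of the
two founder genomes produced by one round of meiotic recombination per
gamete. Sequencing is ultra-low coverage, so genotypes are observed only as
sparse per-marker allele counts, optionally distorted by a reference bias
toward allele A. Heart-rate phenotypes at three assay temperatures are driven
by planted additive/dominance QTLs plus Gaussian noise, with a configurable
fraction of arrhythmic outliers whose recorded rate is halved (2:1
atrioventricular conduction).

Crossovers are Poisson per gamete per chromosome with uniform placement
(Haldane-consistent, no interference), matching the Markov transition model
used by the genotyping HMM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidSpecError

STATE_AA, STATE_AB, STATE_BB = 0, 1, 2
STATE_LABELS = ("AA", "AB", "BB")
TEMPERATURES = ("hr21", "hr28", "hr35")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeSpec:
    """Genome and sequencing regime of a simulated cross.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    marker_density
        Expected homozygous-divergent markers per bp (e.g. 1/1000).
    coverage
        Expected reads overlapping a marker site (sequencing depth; the
        study regime is 0.78).
    read_error
        Probability a read reports the wrong founder allele, in [0, 0.5).
    ref_bias
        Signed shift applied to the probability a read supports allele A,
        in (-0.5, 0.5). Positive values reproduce an overrepresentation of
        AA calls (reference bias toward the A founder).
    crossover_rate
        Poisson mean of crossovers per gamete per chromosome.
    """

    chromosomes: tuple[tuple[str, int], ...]
    marker_density: float
    coverage: float = 0.78
    read_error: float = 0.0
    ref_bias: float = 0.0
    crossover_rate: float = 1.5

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise InvalidSpecError("at least one chromosome is required")
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise InvalidSpecError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise InvalidSpecError(f"chromosome {name}: length must be > 0")
        if self.marker_density <= 0:
            raise InvalidSpecError("marker_density must be > 0")
        if self.coverage < 0:
            raise InvalidSpecError("coverage must be >= 0")
        if not 0 <= self.read_error < 0.5:
            raise InvalidSpecError("read_error must be in [0, 0.5)")
        if not -0.5 < self.ref_bias < 0.5:
            raise InvalidSpecError("ref_bias must be in (-0.5, 0.5)")
        if self.crossover_rate < 0:
            raise InvalidSpecError("crossover_rate must be >= 0")

    @property
    def chrom_names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)


@dataclass
class MarkerSet:
    """Ordered homozygous-divergent SNP markers with founder-allele labels."""

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    positions: dict[str, np.ndarray]   # sorted, unique, 0-based bp
    allele_a: dict[str, np.ndarray]    # founder-A (HO5-like) base per marker
    allele_b: dict[str, np.ndarray]    # founder-B (reference-like) base

    def __post_init__(self) -> None:
        for chrom in self.chrom_names:
            pos = self.positions[chrom]
            if len(pos) and (np.diff(pos) <= 0).any():
                raise InvalidSpecError(f"{chrom}: positions not strictly increasing")
            if (self.allele_a[chrom] == self.allele_b[chrom]).any():
                raise InvalidSpecError(f"{chrom}: marker not homozygous-divergent")

    @property
    def n_markers(self) -> int:
        return sum(len(p) for p in self.positions.values())


@dataclass(frozen=True)
class QTL:
    """A planted quantitative trait locus.

    ``additive`` is the per-temperature effect in bpm of each A allele
    (dosage coding 0/1/2); ``dominance`` the extra bpm for heterozygotes.
    """

    chrom: str
    pos: int
    additive: tuple[float, float, float]
    dominance: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class SimTruth:
    """Ground truth of a simulated F2 cohort.

    ``gamete_starts[chrom]`` has shape (n, 2) with 1 where the gamete begins
    on the founder-A haplotype; ``gamete_breakpoints[chrom][i][g]`` is the
    sorted array of crossover positions of gamete g of individual i.
    ``dosage[chrom]`` is the (n, m) count of A alleles at every marker.
    """

    samples: list[str]
    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    gamete_starts: dict[str, np.ndarray]
    gamete_breakpoints: dict[str, list[list[np.ndarray]]]
    dosage: dict[str, np.ndarray]
    arrhythmia: np.ndarray | None = None
    latent_rates: np.ndarray | None = None
    qtl_dosage: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.samples)

    def breakpoints_of(self, i: int, chrom: str) -> np.ndarray:
        """All crossover positions of individual ``i`` on ``chrom`` (both gametes)."""
        g1, g2 = self.gamete_breakpoints[chrom][i]
        return np.sort(np.concatenate([g1, g2]))

    def dosage_at(self, chrom: str, pos: int) -> np.ndarray:
        """A-allele dosage of every individual at an arbitrary position."""
        out = np.zeros(self.n, dtype=np.int8)
        starts = self.gamete_starts[chrom]
        for i in range(self.n):
            for g in range(2):
                bps = self.gamete_breakpoints[chrom][i][g]
                flips = np.searchsorted(bps, pos, side="right")
                out[i] += (starts[i, g] + flips) % 2
        return out

    def true_window_states(self, chrom: str, window_size: int) -> np.ndarray:
        """Per-window true state matrix (n, n_windows).

        A window's state is 2 - dosage at its start; windows containing a
        true crossover (state not constant across the window) are -1.
        """
        length = self.chrom_lengths[chrom]
        n_win = -(-length // window_size)
        starts = np.arange(n_win) * window_size
        ends = np.minimum(starts + window_size, length)
        out = np.empty((self.n, n_win), dtype=np.int8)
        for i in range(self.n):
            dos = np.zeros(n_win, dtype=np.int8)
            ambiguous = np.zeros(n_win, dtype=bool)
            for g in range(2):
                bps = self.gamete_breakpoints[chrom][i][g]
                flips = np.searchsorted(bps, starts, side="right")
                dos += (self.gamete_starts[chrom][i, g] + flips) % 2
                inside = np.searchsorted(bps, ends - 1, side="right") - flips
                ambiguous |= inside > 0
            state = (2 - dos).astype(np.int8)
            state[ambiguous] = -1
            out[i] = state
        return out


def simulate_marker_map(spec: GenomeSpec, seed: int) -> MarkerSet:
    """Draw a marker map: Poisson marker counts, uniform unique positions."""
    rng = np.random.default_rng(seed)
    positions: dict[str, np.ndarray] = {}
    allele_a: dict[str, np.ndarray] = {}
    allele_b: dict[str, np.ndarray] = {}
    for chrom, length in spec.chromosomes:
        n = int(rng.poisson(length * spec.marker_density))
        n = min(n, length)
        pos = np.unique(rng.integers(0, length, size=n))
        while len(pos) < n:  # top up collisions; rare at realistic densities
            extra = rng.integers(0, length, size=n - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        positions[chrom] = pos.astype(np.int64)
        a_idx = rng.integers(0, 4, size=len(pos))
        b_idx = (a_idx + rng.integers(1, 4, size=len(pos))) % 4
        allele_a[chrom] = _BASES[a_idx]
        allele_b[chrom] = _BASES[b_idx]
    return MarkerSet(spec.chrom_names, spec.chrom_lengths, positions, allele_a, allele_b)


def simulate_f2_cohort(
    markers: MarkerSet, n: int, spec: GenomeSpec, seed: int
) -> SimTruth:
    """Simulate ``n`` F2 individuals as unions of two recombinant gametes.

    Each gamete starts on a uniformly chosen founder haplotype and switches
    at Poisson(crossover_rate) uniformly placed breakpoints.
    """
    if n < 1:
        raise InvalidSpecError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    samples = [f"F2_{i:05d}" for i in range(n)]
    gamete_starts: dict[str, np.ndarray] = {}
    gamete_breakpoints: dict[str, list[list[np.ndarray]]] = {}
    dosage: dict[str, np.ndarray] = {}
    for chrom, length in spec.chromosomes:
        pos = markers.positions[chrom]
        starts = rng.integers(0, 2, size=(n, 2)).astype(np.int8)
        n_co = rng.poisson(spec.crossover_rate, size=(n, 2))
        bps: list[list[np.ndarray]] = []
        dos = np.zeros((n, len(pos)), dtype=np.int8)
        for i in range(n):
            pair = []
            for g in range(2):
                b = np.sort(rng.uniform(0, length, size=n_co[i, g])).astype(np.int64)
                pair.append(b)
                flips = np.searchsorted(b, pos, side="right")
                dos[i] += ((starts[i, g] + flips) % 2).astype(np.int8)
            bps.append(pair)
        gamete_starts[chrom] = starts
        gamete_breakpoints[chrom] = bps
        dosage[chrom] = dos
    return SimTruth(
        samples=samples,
        chrom_names=markers.chrom_names,
        chrom_lengths=markers.chrom_lengths,
        gamete_starts=gamete_starts,
        gamete_breakpoints=gamete_breakpoints,
        dosage=dosage,
    )


@dataclass
class AlleleCounts:
    """Per individual x marker read counts for alleles A and B."""

    samples: list[str]
    chrom_names: list[str]
    n_a: dict[str, np.ndarray]  # (n, m) int32
    n_b: dict[str, np.ndarray]

    def total_reads(self) -> int:
        return int(
            sum(self.n_a[c].sum() + self.n_b[c].sum() for c in self.chrom_names)
        )


def allele_a_probability(dosage: np.ndarray, read_error: float, ref_bias: float) -> np.ndarray:
    """P(read supports A | genotype): 1-e, 0.5, e for AA/AB/BB, shifted by the bias."""
    base = np.choose(dosage.astype(np.intp), [read_error, 0.5, 1.0 - read_error])
    return np.clip(base + ref_bias, 0.0, 1.0)


def simulate_allele_counts(
    truth: SimTruth, markers: MarkerSet, spec: GenomeSpec, seed: int
) -> AlleleCounts:
    """Sample low-coverage read counts: depth Poisson(coverage), reads i.i.d."""
    rng = np.random.default_rng(seed)
    n_a: dict[str, np.ndarray] = {}
    n_b: dict[str, np.ndarray] = {}
    for chrom in markers.chrom_names:
        dos = truth.dosage[chrom]
        if dos.shape[1] != len(markers.positions[chrom]):
            raise InvalidSpecError(f"{chrom}: truth does not cover all markers")
        depth = rng.poisson(spec.coverage, size=dos.shape)
        p_a = allele_a_probability(dos, spec.read_error, spec.ref_bias)
        a = rng.binomial(depth, p_a)
        n_a[chrom] = a.astype(np.int32)
        n_b[chrom] = (depth - a).astype(np.int32)
    return AlleleCounts(truth.samples, markers.chrom_names, n_a, n_b)


def simulate_phenotypes(
    truth: SimTruth,
    qtls: list[QTL],
    baselines: tuple[float, float, float],
    noise_sd: float,
    arrhythmia_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Per-temperature heart rates from planted QTLs plus Gaussian noise.

    latent(t) = baseline(t) + sum_q a_q(t) * dosage_A + d_q(t) * [het] + N(0, sd);
    with probability ``arrhythmia_rate`` the recorded rate is latent/2 at all
    temperatures (2:1 atrioventricular conduction) and the truth flag is set.
    Returns a table (sample, hr21, hr28, hr35, arrhythmia_flag) and stores the
    latent rates, flags and QTL dosages on ``truth``.
    """
    if any(b <= 0 for b in baselines):
        raise InvalidSpecError("baselines must be positive")
    if noise_sd < 0:
        raise InvalidSpecError("noise_sd must be >= 0")
    if not 0 <= arrhythmia_rate <= 1:
        raise InvalidSpecError("arrhythmia_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = truth.n
    latent = np.tile(np.asarray(baselines, dtype=float), (n, 1))
    qtl_dos = np.zeros((n, len(qtls)), dtype=np.int8)
    for q_idx, q in enumerate(qtls):
        if q.chrom not in truth.chrom_names or not 0 <= q.pos < truth.chrom_lengths[q.chrom]:
            raise InvalidSpecError(f"QTL at {q.chrom}:{q.pos} outside the genome")
        dos = truth.dosage_at(q.chrom, q.pos)
        qtl_dos[:, q_idx] = dos
        het = (dos == 1).astype(float)
        latent += np.outer(dos, q.additive) + np.outer(het, q.dominance)
    latent += rng.normal(0.0, noise_sd, size=(n, 3))
    flags = rng.random(n) < arrhythmia_rate
    recorded = np.where(flags[:, None], latent / 2.0, latent)
    truth.arrhythmia = flags
    truth.latent_rates = latent
    truth.qtl_dosage = qtl_dos
    table = pd.DataFrame({"sample": truth.samples})
    for t_idx, name in enumerate(TEMPERATURES):
        table[name] = recorded[:, t_idx]
    table["arrhythmia_flag"] = flags.astype(int)
    return table


def simulate_gene_annotation(
    spec: GenomeSpec,
    seed: int,
    genes_per_mb: float = 10.0,
    mean_length: int = 20_000,
) -> pd.DataFrame:
    """Random non-overlapping gene models (for annotation tests and demos).

    Returns a table (gene_id, chrom, start, end, strand, name) in 0-based
    half-open coordinates.
    """
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for chrom, length in spec.chromosomes:
        n_genes = int(rng.poisson(genes_per_mb * length / 1e6))
        starts = np.sort(rng.integers(0, max(1, length - mean_length), size=n_genes))
        prev_end = 0
        for s in starts:
            glen = max(200, int(rng.exponential(mean_length)))
            start = max(int(s), prev_end)
            end = min(start + glen, length)
            if end <= start:
                continue
            rows.append(
                {
                    "gene_id": f"GENE{k:05d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "name": f"gene{k}",
                }
            )
            prev_end = end
            k += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "name"])
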