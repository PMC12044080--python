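"""Configuration and deterministic orchestration of the full analysis chain.

simulate -> genotype (windowed HMM) -> blocks -> scan (LMM + permutation FDR)
-> finemap -> rank. Every stage writes text artifacts under the output
directory and records them, with SHA-256 hashes and the stage parameters, in
a run manifest; reruns with an identical configuration reproduce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import assoc, blocks, finemap, hmm, io, simulate
from .errors import InvalidSpecError

__version__ = "0.1.0"


@dataclass
class AnalysisConfig:
    """Everything needed to run the pipeline end to end.

    Stage seeds are derived deterministically from ``seed``; no stage ever
    seeds from the wall clock.
    """

    chromosomes: list[tuple[str, int]]
    n_individuals: int
    out_dir: str
    marker_density: float = 1e-3
    coverage: float = 0.78
    read_error: float = 0.01
    ref_bias: float = 0.0
    crossover_rate: float = 1.5
    qtls: list[dict] = field(default_factory=list)
    baselines: tuple[float, float, float] = (120.0, 160.0, 210.0)
    noise_sd: float = 10.0
    arrhythmia_rate: float = 0.0
    window_size: int = 5000
    hmm_error: float = 0.02
    grid: int = 10_000
    phenotypes: tuple[str, ...] = (*simulate.TEMPERATURES, "variance")
    n_perm: int = 100
    fdr_levels: tuple[float, ...] = (0.01, 0.05)
    fdr_level: float = 0.05
    r2_threshold: float = 0.5
    merge_distance: int = 500_000
    min_log10p: float = 3.0
    de_fdr: float = 0.01
    de_fc: float = 2.0
    seed: int = 0
    gff3: str | None = None
    de_table: str | None = None
    lof_table: str | None = None

    def __post_init__(self) -> None:
        self.chromosomes = [(str(c), int(l)) for c, l in self.chromosomes]
        if not all(0 < lvl < 1 for lvl in self.fdr_levels):
            raise InvalidSpecError("fdr_levels must lie in (0, 1)")
        if self.fdr_level not in self.fdr_levels:
            raise InvalidSpecError("fdr_level must be one of fdr_levels")
        for name in ("gff3", "de_table", "lof_table"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise InvalidSpecError(f"config field {name}: file not found: {value}")
        # construct eagerly so invalid values fail at config time
        self.genome_spec()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def genome_spec(self) -> simulate.GenomeSpec:
        return simulate.GenomeSpec(
            chromosomes=tuple(self.chromosomes),
            marker_density=self.marker_density,
            coverage=self.coverage,
            read_error=self.read_error,
            ref_bias=self.ref_bias,
            crossover_rate=self.crossover_rate,
        )

    def qtl_list(self) -> list[simulate.QTL]:
        return [
            simulate.QTL(
                chrom=str(q["chrom"]),
                pos=int(q["pos"]),
                additive=tuple(q.get("additive", (0, 0, 0))),
                dominance=tuple(q.get("dominance", (0, 0, 0))),
            )
            for q in self.qtls
        ]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: AnalysisConfig, quiet: bool = True) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.genome_spec()
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    def log(msg: str) -> None:
        if not quiet:
            import sys

            print(msg, file=sys.stderr)

    def record(stage: str, files: list[Path], params: dict, seed: int | None) -> None:
        manifest["stages"][stage] = {
            "seed": seed,
            "parameters": params,
            "outputs": {str(f.relative_to(out)): _sha256(f) for f in files},
        }

    # --- simulate -----------------------------------------------------------
    log("[simulate] generating markers, cohort, counts, phenotypes")
    markers = simulate.simulate_marker_map(spec, config.seed + 1)
    truth = simulate.simulate_f2_cohort(markers, config.n_individuals, spec, config.seed + 2)
    counts = simulate.simulate_allele_counts(truth, markers, spec, config.seed + 3)
    phen = simulate.simulate_phenotypes(
        truth, config.qtl_list(), config.baselines, config.noise_sd,
        config.arrhythmia_rate, config.seed + 4,
    )
    io.write_marker_map(markers, out / "markers.tsv")
    io.write_allele_counts(counts, markers, out / "allele_counts.tsv")
    io.write_phenotypes(phen, out / "phenotypes.tsv")
    record(
        "simulate",
        [out / "markers.tsv", out / "allele_counts.tsv", out / "phenotypes.tsv"],
        {"n": config.n_individuals, "coverage": config.coverage,
         "read_error": config.read_error, "ref_bias": config.ref_bias},
        config.seed + 1,
    )

    # --- genotype -----------------------------------------------------------
    log("[genotype] windowing counts and decoding state paths")
    windows = hmm.aggregate_windows(counts, markers, config.window_size)
    paths = hmm.decode_cohort(
        windows, crossover_rate=config.crossover_rate, error=config.hmm_error
    )
    crossovers = hmm.call_crossovers(paths)
    io.write_window_states(paths, out / "window_states.tsv")
    io.write_crossovers(crossovers, out / "crossovers.tsv")
    record(
        "genotype",
        [out / "window_states.tsv", out / "crossovers.tsv"],
        {"window_size": config.window_size, "hmm_error": config.hmm_error},
        None,
    )

    # --- blocks -------------------------------------------------------------
    log("[blocks] segmenting the genome and filling the genotype matrix")
    blockset = blocks.segment_genome(
        crossovers, spec.chrom_lengths, config.grid, spec.chrom_names
    )
    matrix = blocks.fill_genotype_matrix(blockset, paths)
    report = blocks.segregation_diagnostics(matrix)
    io.write_blockset(blockset, out / "blocks.bed")
    io.write_genotype_matrix(
        matrix, out / "genotype_matrix.tsv", out / "dosage_matrix.tsv"
    )
    report.table.to_csv(
        out / "segregation.tsv", sep="\t", index=False, float_format="%.10g"
    )
    record(
        "blocks",
        [out / "blocks.bed", out / "genotype_matrix.tsv",
         out / "dosage_matrix.tsv", out / "segregation.tsv"],
        {"grid": config.grid, "n_blocks": blockset.n_blocks,
         "aa_excess": report.aa_excess},
        None,
    )

    # --- scan ---------------------------------------------------------------
    log("[scan] mixed-model association with permutation FDR")
    kinship = assoc.estimate_kinship(matrix)
    scan, thresholds, h2 = assoc.scan_all_phenotypes(
        matrix, phen, kinship, n_perm=config.n_perm, seed=config.seed + 5,
        levels=config.fdr_levels, phenotype_names=config.phenotypes,
    )
    io.write_scan(scan, out / "scan.tsv")
    io.write_thresholds(thresholds, out / "fdr_thresholds.json")
    record(
        "scan",
        [out / "scan.tsv", out / "fdr_thresholds.json"],
        {"n_perm": config.n_perm, "h2": h2},
        config.seed + 5,
    )

    # --- finemap ------------------------------------------------------------
    log("[finemap] collapsing significant blocks into regions")
    regions = finemap.collapse_loci(
        scan, matrix, thresholds,
        r2_threshold=config.r2_threshold,
        merge_distance=config.merge_distance,
        level=config.fdr_level,
    )
    if config.gff3 is not None:
        genes = io.read_gff3_genes(config.gff3)
    else:
        genes = simulate.simulate_gene_annotation(spec, config.seed + 6)
        io.write_gff3_genes(genes, out / "genes.gff3")
    finemap.annotate_regions(regions, genes)
    io.write_regions(regions, out / "regions.json", out / "regions.bed")
    record(
        "finemap",
        [out / "regions.json", out / "regions.bed"],
        {"r2_threshold": config.r2_threshold,
         "merge_distance": config.merge_distance,
         "n_regions": len(regions)},
        None,
    )

    # --- rank ---------------------------------------------------------------
    log("[rank] scoring candidate genes")
    de = io.read_evidence_de(config.de_table) if config.de_table else None
    lof = io.read_evidence_lof(config.lof_table) if config.lof_table else None
    candidates = finemap.rank_candidates(
        regions, de, lof,
        de_fdr=config.de_fdr, de_fc=config.de_fc, min_log10p=config.min_log10p,
    )
    io.write_candidates(candidates, out / "candidates.tsv")
    record(
        "rank",
        [out / "candidates.tsv"],
        {"min_log10p": config.min_log10p, "de_fdr": config.de_fdr,
         "de_fc": config.de_fc, "n_candidates": len(candidates)},
        None,
    )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
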