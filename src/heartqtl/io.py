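"""Round-trip-safe readers and writers for every on-disk artifact.

All artifacts are plain text (TSV / BED / GFF3 / VCF / JSON) so that reruns
diff cleanly; floats are serialized with 10 significant digits. Coordinates
are 0-based half-open everywhere except VCF and GFF3, which use their native
1-based conventions and are converted on the way in and out.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import FdrThresholds
from .blocks import BlockSet, GenotypeMatrix
from .errors import ConsistencyError, ParseError
from .finemap import FineMappedRegion
from .hmm import GenotypePaths, n_windows_for
from .simulate import STATE_LABELS, AlleleCounts, MarkerSet

_FLOAT_FMT = "%.10g"
_STATE_INDEX = {lab: i for i, lab in enumerate(STATE_LABELS)}


# ---------------------------------------------------------------- marker map

def write_marker_map(markers: MarkerSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in markers.chrom_names:
            fh.write(f"##length\t{chrom}\t{markers.chrom_lengths[chrom]}\n")
        fh.write("chrom\tpos0\talleleA\talleleB\n")
        for chrom in markers.chrom_names:
            for p, a, b in zip(
                markers.positions[chrom], markers.allele_a[chrom], markers.allele_b[chrom]
            ):
                fh.write(f"{chrom}\t{p}\t{a}\t{b}\n")


def read_marker_map(path: str | Path) -> MarkerSet:
    lengths: dict[str, int] = {}
    with open(path) as fh:
        header_lines = 0
        for line in fh:
            if line.startswith("##length"):
                _, chrom, length = line.rstrip("\n").split("\t")
                lengths[chrom] = int(length)
                header_lines += 1
            else:
                break
    df = pd.read_csv(
        path, sep="\t", skiprows=header_lines,
        dtype={"chrom": str, "pos0": np.int64, "alleleA": str, "alleleB": str},
    )
    chroms = list(lengths)
    positions = {c: df.loc[df["chrom"] == c, "pos0"].to_numpy() for c in chroms}
    allele_a = {
        c: df.loc[df["chrom"] == c, "alleleA"].to_numpy(dtype="U1") for c in chroms
    }
    allele_b = {
        c: df.loc[df["chrom"] == c, "alleleB"].to_numpy(dtype="U1") for c in chroms
    }
    return MarkerSet(chroms, lengths, positions, allele_a, allele_b)


# ------------------------------------------------------------- allele counts

def write_allele_counts(
    counts: AlleleCounts, markers: MarkerSet, path: str | Path
) -> None:
    """Long TSV (sample, chrom, pos0, nA, nB); zero-depth rows are omitted."""
    with open(path, "w") as fh:
        fh.write("##samples\t" + ",".join(counts.samples) + "\n")
        fh.write("sample\tchrom\tpos0\tnA\tnB\n")
        for chrom in counts.chrom_names:
            pos = markers.positions[chrom]
            a, b = counts.n_a[chrom], counts.n_b[chrom]
            covered = (a + b) > 0
            for i, sample in enumerate(counts.samples):
                idx = np.nonzero(covered[i])[0]
                for j in idx:
                    fh.write(f"{sample}\t{chrom}\t{pos[j]}\t{a[i, j]}\t{b[i, j]}\n")


def read_allele_counts(path: str | Path, markers: MarkerSet) -> AlleleCounts:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("##samples\t"):
        raise ParseError(f"{path}: line 1: missing ##samples header")
    samples = first.rstrip("\n").split("\t", 1)[1].split(",")
    df = pd.read_csv(
        path, sep="\t", skiprows=1,
        dtype={"sample": str, "chrom": str, "pos0": np.int64, "nA": np.int64, "nB": np.int64},
    )
    sample_idx = {s: i for i, s in enumerate(samples)}
    n_a = {
        c: np.zeros((len(samples), len(markers.positions[c])), dtype=np.int32)
        for c in markers.chrom_names
    }
    n_b = {c: np.zeros_like(n_a[c]) for c in markers.chrom_names}
    for chrom, sub in df.groupby("chrom"):
        if chrom not in markers.chrom_names:
            raise ConsistencyError(f"{path}: unknown chromosome {chrom}")
        pos = markers.positions[chrom]
        j = np.searchsorted(pos, sub["pos0"].to_numpy())
        bad = (j >= len(pos)) | (pos[np.minimum(j, len(pos) - 1)] != sub["pos0"].to_numpy())
        if bad.any():
            p = sub["pos0"].to_numpy()[bad][0]
            raise ConsistencyError(f"{path}: {chrom}:{p} is not a known marker")
        i = sub["sample"].map(sample_idx).to_numpy()
        n_a[chrom][i, j] = sub["nA"].to_numpy()
        n_b[chrom][i, j] = sub["nB"].to_numpy()
    return AlleleCounts(samples, list(markers.chrom_names), n_a, n_b)


# ------------------------------------------------------------------ VCF

def write_counts_vcf(
    counts: AlleleCounts, markers: MarkerSet, path: str | Path
) -> None:
    """Sites + per-sample allele-depth (AD) VCF; REF is the B (reference) allele."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in markers.chrom_names:
            fh.write(
                f"##contig=<ID={chrom},length={markers.chrom_lengths[chrom]}>\n"
            )
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref=B allele, alt=A allele)">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(counts.samples)
            + "\n"
        )
        for chrom in markers.chrom_names:
            pos = markers.positions[chrom]
            ref = markers.allele_b[chrom]
            alt = markers.allele_a[chrom]
            a, b = counts.n_a[chrom], counts.n_b[chrom]
            for j in range(len(pos)):
                cells = "\t".join(f"{b[i, j]},{a[i, j]}" for i in range(len(counts.samples)))
                fh.write(
                    f"{chrom}\t{pos[j] + 1}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tAD\t{cells}\n"
                )


def read_counts_vcf(path: str | Path, markers: MarkerSet) -> AlleleCounts:
    """Import per-sample AD fields at marker sites (requires cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n_a = {
        c: np.zeros((len(samples), len(markers.positions[c])), dtype=np.int32)
        for c in markers.chrom_names
    }
    n_b = {c: np.zeros_like(n_a[c]) for c in markers.chrom_names}
    for variant in vcf:
        chrom = variant.CHROM
        if chrom not in markers.chrom_names:
            raise ConsistencyError(f"{path}: unknown chromosome {chrom}")
        pos = markers.positions[chrom]
        j = int(np.searchsorted(pos, variant.POS - 1))
        if j >= len(pos) or pos[j] != variant.POS - 1:
            raise ConsistencyError(f"{path}: {chrom}:{variant.POS} is not a marker site")
        ad = variant.format("AD")
        n_b[chrom][:, j] = np.maximum(ad[:, 0], 0)
        n_a[chrom][:, j] = np.maximum(ad[:, 1], 0)
    return AlleleCounts(samples, list(markers.chrom_names), n_a, n_b)


# -------------------------------------------------------------- window paths

def write_window_states(paths: GenotypePaths, path: str | Path) -> None:
    """Run-length encoded per-sample state tracks (sample, chrom, start, end, state)."""
    with open(path, "w") as fh:
        fh.write(f"##window_size\t{paths.window_size}\n")
        for chrom in paths.chrom_names:
            fh.write(f"##length\t{chrom}\t{paths.chrom_lengths[chrom]}\n")
        for chrom in paths.chrom_names:
            for i, sample in enumerate(paths.samples):
                fh.write(
                    f"##log_prob\t{sample}\t{chrom}\t"
                    + (_FLOAT_FMT % paths.log_prob[chrom][i])
                    + "\n"
                )
        fh.write("sample\tchrom\tstart\tend\tstate\n")
        for chrom in paths.chrom_names:
            length = paths.chrom_lengths[chrom]
            w = paths.window_size
            st = paths.states[chrom]
            for i, sample in enumerate(paths.samples):
                run_starts = np.concatenate(
                    [[0], np.nonzero(np.diff(st[i]) != 0)[0] + 1]
                )
                run_ends = np.concatenate([run_starts[1:], [st.shape[1]]])
                for rs, re_ in zip(run_starts, run_ends):
                    fh.write(
                        f"{sample}\t{chrom}\t{rs * w}\t{min(re_ * w, length)}\t"
                        f"{STATE_LABELS[st[i, rs]]}\n"
                    )


def read_window_states(path: str | Path) -> GenotypePaths:
    window_size = None
    lengths: dict[str, int] = {}
    log_prob_entries: list[tuple[str, str, float]] = []
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            header_lines += 1
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "##window_size":
                window_size = int(parts[1])
            elif parts[0] == "##length":
                lengths[parts[1]] = int(parts[2])
            elif parts[0] == "##log_prob":
                log_prob_entries.append((parts[1], parts[2], float(parts[3])))
    if window_size is None:
        raise ParseError(f"{path}: missing ##window_size header")
    df = pd.read_csv(
        path, sep="\t", skiprows=header_lines,
        dtype={"sample": str, "chrom": str, "start": np.int64, "end": np.int64, "state": str},
    )
    samples = list(dict.fromkeys(df["sample"]))
    sample_idx = {s: i for i, s in enumerate(samples)}
    chroms = list(lengths)
    states: dict[str, np.ndarray] = {}
    for chrom in chroms:
        n_win = n_windows_for(lengths[chrom], window_size)
        track = np.full((len(samples), n_win), -1, dtype=np.int8)
        sub = df[df["chrom"] == chrom]
        for sample, start, end, state in zip(
            sub["sample"], sub["start"], sub["end"], sub["state"]
        ):
            w0 = start // window_size
            w1 = n_windows_for(end, window_size)
            track[sample_idx[sample], w0:w1] = _STATE_INDEX[state]
        if (track < 0).any():
            raise ParseError(f"{path}: {chrom}: state runs do not tile the chromosome")
        states[chrom] = track
    log_prob = {c: np.zeros(len(samples)) for c in chroms}
    for sample, chrom, value in log_prob_entries:
        log_prob[chrom][sample_idx[sample]] = value
    return GenotypePaths(samples, chroms, lengths, window_size, states, log_prob)


# ---------------------------------------------------------------- crossovers

def write_crossovers(crossovers: pd.DataFrame, path: str | Path) -> None:
    """BED-like TSV: chrom, pos0, pos0+1, sample, from_state, to_state, distance."""
    out = pd.DataFrame(
        {
            "chrom": crossovers["chrom"],
            "start": crossovers["pos"],
            "end": crossovers["pos"] + 1,
            "sample": crossovers["sample"],
            "from_state": crossovers["from_state"],
            "to_state": crossovers["to_state"],
            "distance": crossovers["distance"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_crossovers(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    return pd.DataFrame(
        {
            "sample": df["sample"],
            "chrom": df["chrom"],
            "pos": df["start"].astype(np.int64),
            "from_state": df["from_state"],
            "to_state": df["to_state"],
            "distance": df["distance"].astype(int),
            "double": df["distance"].astype(int) == 2,
        }
    )


# -------------------------------------------------------------------- blocks

def write_blockset(blocks: BlockSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"##grid\t{blocks.grid}\n")
        for chrom in blocks.chrom_names:
            fh.write(f"##length\t{chrom}\t{blocks.chrom_lengths[chrom]}\n")
        blocks.table()[["chrom", "start", "end", "block_id"]].to_csv(
            fh, sep="\t", index=False
        )


def read_blockset(path: str | Path) -> BlockSet:
    grid = None
    lengths: dict[str, int] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            header_lines += 1
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "##grid":
                grid = int(parts[1])
            elif parts[0] == "##length":
                lengths[parts[1]] = int(parts[2])
    if grid is None:
        raise ParseError(f"{path}: missing ##grid header")
    df = pd.read_csv(path, sep="\t", skiprows=header_lines, dtype={"chrom": str})
    boundaries = {}
    for chrom in lengths:
        sub = df[df["chrom"] == chrom].sort_values("start")
        if len(sub) == 0:
            raise ParseError(f"{path}: no blocks for chromosome {chrom}")
        boundaries[chrom] = np.concatenate(
            [sub["start"].to_numpy(np.int64), [sub["end"].to_numpy(np.int64)[-1]]]
        )
    return BlockSet(grid, list(lengths), lengths, boundaries)


def write_genotype_matrix(matrix: GenotypeMatrix, path: str | Path,
                          dosage_path: str | Path | None = None) -> None:
    meta = matrix.block_table[["block_id", "chrom", "start", "end"]]
    labels = np.array(STATE_LABELS)
    wide = pd.concat(
        [meta, pd.DataFrame(labels[matrix.states], columns=matrix.samples)], axis=1
    )
    wide.to_csv(path, sep="\t", index=False)
    if dosage_path is not None:
        dos = pd.concat(
            [meta, pd.DataFrame(matrix.dosage, columns=matrix.samples)], axis=1
        )
        dos.to_csv(dosage_path, sep="\t", index=False)


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["block_id", "chrom", "start", "end"]
    samples = [c for c in df.columns if c not in meta_cols]
    states = np.stack(
        [df[s].map(_STATE_INDEX).to_numpy(dtype=np.int8) for s in samples], axis=1
    )
    return GenotypeMatrix(
        block_table=df[meta_cols].reset_index(drop=True),
        samples=samples,
        states=states,
    )


# ---------------------------------------------------------------- phenotypes

def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str})


# ---------------------------------------------------------------------- scan

def write_scan(scan: pd.DataFrame, path: str | Path) -> None:
    scan.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_scan(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "phenotype": str})


def write_thresholds(thresholds: dict[str, FdrThresholds], path: str | Path) -> None:
    payload = {
        name: {
            "thresholds": {str(k): v for k, v in thr.thresholds.items()},
            "n_perm": thr.n_perm,
            "seed": thr.seed,
        }
        for name, thr in thresholds.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_thresholds(path: str | Path) -> dict[str, FdrThresholds]:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        name: FdrThresholds(
            phenotype=name,
            thresholds={float(k): v for k, v in entry["thresholds"].items()},
            n_perm=entry["n_perm"],
            seed=entry["seed"],
        )
        for name, entry in payload.items()
    }


# ------------------------------------------------------------------- regions

def write_regions(regions: list[FineMappedRegion], json_path: str | Path,
                  bed_path: str | Path | None = None) -> None:
    payload = [
        {
            "region_id": r.region_id,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "lead_block": r.lead_block,
            "lead_neg_log10_p": r.lead_neg_log10_p,
            "member_blocks": r.member_blocks,
            "phenotypes": r.phenotypes,
            "genes": r.genes,
        }
        for r in regions
    ]
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            fh.write("chrom\tstart\tend\tregion_id\n")
            for r in regions:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


def read_regions(json_path: str | Path) -> list[FineMappedRegion]:
    with open(json_path) as fh:
        payload = json.load(fh)
    return [FineMappedRegion(**entry) for entry in payload]


# ---------------------------------------------------------------- annotation

def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Parse `gene` features from a GFF3 file into 0-based half-open intervals."""
    from gffutils.feature import feature_from_line

    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # malformed feature
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if feat.featuretype != "gene":
                continue
            attrs = feat.attributes
            gene_id = (attrs.get("ID") or attrs.get("gene_id") or [None])[0]
            if gene_id is None:
                raise ParseError(f"{path}: line {lineno}: gene without ID attribute")
            name = (attrs.get("Name") or [gene_id])[0]
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": feat.seqid,
                    "start": feat.start - 1,
                    "end": feat.end,
                    "strand": feat.strand,
                    "name": name,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "name"]
    )


def write_gff3_genes(genes: pd.DataFrame, path: str | Path) -> None:
    """Write a gene table (0-based half-open) as GFF3 `gene` features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\theartqtl\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id};Name={row.name}\n"
            )


def read_evidence_de(path: str | Path) -> pd.DataFrame:
    """Differential-expression evidence: TSV (gene_id, log2fc, padj)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if df["gene_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene ids in DE table")
    return df


def read_evidence_lof(path: str | Path) -> pd.DataFrame:
    """Loss-of-function evidence: TSV (gene_id, lof_count)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if df["gene_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene ids in LoF table")
    if (df["lof_count"] < 0).any():
        raise ParseError(f"{path}: negative LoF count")
    return df


def write_candidates(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_candidates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "region_id": str})
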