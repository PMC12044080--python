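"""LD collapsing, gene annotation and candidate ranking."""

import numpy as np
import pandas as pd
import pytest

from heartqtl.assoc import FdrThresholds
from heartqtl.blocks import GenotypeMatrix
from heartqtl.errors import InvalidSpecError
from heartqtl.finemap import (
    FineMappedRegion,
    annotate_regions,
    collapse_loci,
    rank_candidates,
)


def make_matrix(dosage_rows, starts, chrom="chr1", width=10_000):
    dosage = np.asarray(dosage_rows, dtype=np.int8)
    table = pd.DataFrame(
        {
            "block_id": [f"{chrom}:{s}-{s + width}" for s in starts],
            "chrom": chrom,
            "start": starts,
            "end": [s + width for s in starts],
        }
    )
    samples = [f"s{i}" for i in range(dosage.shape[1])]
    return GenotypeMatrix(table, samples, (2 - dosage).astype(np.int8))


def make_scan(matrix, neg_log10_ps, phenotype="hr28"):
    table = matrix.block_table.copy()
    table["phenotype"] = phenotype
    table["neg_log10_p"] = neg_log10_ps
    table["p"] = 10.0 ** (-table["neg_log10_p"])
    table["beta"] = 1.0
    table["se"] = 0.1
    return table


def thresholds_at(value, phenotype="hr28"):
    return {
        phenotype: FdrThresholds(
            phenotype=phenotype,
            thresholds={0.01: value + 1.0, 0.05: value},
            n_perm=100,
            seed=0,
        )
    }


class TestCollapseLoci:
    def test_single_significant_block_forms_its_own_region(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.integers(0, 3, (4, 40)), [0, 10_000, 20_000, 30_000])
        scan = make_scan(m, [1.0, 6.0, 1.0, 0.5])
        regions = collapse_loci(scan, m, thresholds_at(4.0))
        assert len(regions) == 1
        assert regions[0].lead_block == m.block_table["block_id"].iloc[1]
        assert (regions[0].start, regions[0].end) == (10_000, 20_000)

    def test_perfect_ld_blocks_merge_with_best_p_as_lead(self):
        rng = np.random.default_rng(1)
        shared = rng.integers(0, 3, 40)
        m = make_matrix([shared, shared], [0, 10_000])
        scan = make_scan(m, [5.0, 7.0])
        regions = collapse_loci(scan, m, thresholds_at(4.0))
        assert len(regions) == 1
        assert regions[0].lead_neg_log10_p == 7.0
        assert (regions[0].start, regions[0].end) == (0, 20_000)

    def test_blocks_on_different_chromosomes_stay_distinct(self):
        rng = np.random.default_rng(2)
        m1 = make_matrix(rng.integers(0, 3, (1, 40)), [0], chrom="chr1")
        m2 = make_matrix(rng.integers(0, 3, (1, 40)), [0], chrom="chr2")
        m = GenotypeMatrix(
            pd.concat([m1.block_table, m2.block_table], ignore_index=True),
            m1.samples,
            np.vstack([m1.states, m2.states]),
        )
        scan = make_scan(m, [6.0, 6.5])
        regions = collapse_loci(scan, m, thresholds_at(4.0))
        assert len(regions) == 2
        assert {r.chrom for r in regions} == {"chr1", "chr2"}

    def test_two_planted_loci_with_satellites_collapse_to_two_regions(self):
        """Each locus drags its perfect-LD satellites; independent loci stay apart."""
        rng = np.random.default_rng(3)
        locus1 = rng.integers(0, 3, 60)
        locus2 = rng.integers(0, 3, 60)
        noise = [rng.integers(0, 3, 60) for _ in range(2)]
        rows = [locus1, locus1, locus1, noise[0], locus2, locus2, noise[1]]
        starts = [0, 10_000, 20_000, 1_000_000, 5_000_000, 5_010_000, 8_000_000]
        m = make_matrix(rows, starts)
        scan = make_scan(m, [8.0, 7.5, 7.0, 1.0, 6.5, 6.0, 0.5])
        regions = collapse_loci(scan, m, thresholds_at(5.0), merge_distance=100_000)
        assert len(regions) == 2
        assert regions[0].member_blocks == list(m.block_table["block_id"][:3])
        assert regions[1].member_blocks == list(m.block_table["block_id"][4:6])

    def test_collapse_is_idempotent_on_its_own_leads(self):
        rng = np.random.default_rng(4)
        rows = [rng.integers(0, 3, 60) for _ in range(6)]
        starts = [0, 10_000, 2_000_000, 2_010_000, 6_000_000, 6_010_000]
        m = make_matrix(rows, starts)
        scan = make_scan(m, [6.0, 5.5, 7.0, 1.0, 6.2, 0.2])
        regions = collapse_loci(scan, m, thresholds_at(5.0), merge_distance=100_000)
        leads = {r.lead_block for r in regions}
        scan2 = scan[scan["block_id"].isin(leads)]
        regions2 = collapse_loci(scan2, m, thresholds_at(5.0), merge_distance=100_000)
        assert {r.lead_block for r in regions2} == leads
        assert len(regions2) == len(regions)

    def test_no_significant_block_yields_empty_list(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.integers(0, 3, (3, 40)), [0, 10_000, 20_000])
        scan = make_scan(m, [1.0, 2.0, 0.5])
        assert collapse_loci(scan, m, thresholds_at(4.0)) == []

    def test_regions_never_overlap_within_a_chromosome(self):
        rng = np.random.default_rng(6)
        rows = [rng.integers(0, 3, 60) for _ in range(8)]
        starts = [k * 200_000 for k in range(8)]
        m = make_matrix(rows, starts)
        scan = make_scan(m, rng.uniform(4.5, 8.0, 8))
        regions = collapse_loci(scan, m, thresholds_at(4.0), merge_distance=150_000)
        regions.sort(key=lambda r: r.start)
        for a, b in zip(regions[:-1], regions[1:]):
            assert a.end <= b.start


def region(lead_p=6.0, chrom="chr1", start=0, end=1000, genes=()):
    return FineMappedRegion(
        region_id="R000",
        chrom=chrom,
        start=start,
        end=end,
        lead_block=f"{chrom}:{start}-{end}",
        lead_neg_log10_p=lead_p,
        member_blocks=[f"{chrom}:{start}-{end}"],
        phenotypes=["hr28"],
        genes=[{"gene_id": g, "start": start, "end": end} for g in genes],
    )


def gene_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "name"])


class TestAnnotateRegions:
    GENES = gene_table(
        [
            ("g_inside", "chr1", 100, 200, "+", "g_inside"),
            ("g_boundary", "chr1", 900, 1100, "+", "g_boundary"),
            ("g_outside", "chr1", 5000, 6000, "+", "g_outside"),
            ("g_other_chrom", "chr2", 100, 200, "+", "g_other_chrom"),
        ]
    )

    def test_any_overlap_rule(self):
        regs = annotate_regions([region(start=0, end=1000)], self.GENES)
        ids = {g["gene_id"] for g in regs[0].genes}
        assert ids == {"g_inside", "g_boundary"}

    def test_region_without_genes_gets_empty_list(self):
        regs = annotate_regions([region(start=2000, end=3000)], self.GENES)
        assert regs[0].genes == [] and regs[0].n_genes == 0

    def test_gene_counts_conserve_totals(self):
        regs = annotate_regions(
            [region(start=0, end=1000), region(start=4500, end=7000)], self.GENES
        )
        per_region = sum(r.n_genes for r in regs)
        distinct = {
            g["gene_id"] for r in regs for g in r.genes
        }
        assert per_region == len(distinct) == 3


class TestRankCandidates:
    def test_evidence_strictly_improves_rank_at_equal_association(self):
        regs = [
            region(lead_p=6.0, start=0, end=1000, genes=("gA",)),
            region(lead_p=6.0, start=2000, end=3000, genes=("gB",)),
        ]
        de = pd.DataFrame({"gene_id": ["gA"], "log2fc": [2.5], "padj": [1e-4]})
        lof = pd.DataFrame({"gene_id": ["gA"], "lof_count": [1]})
        table = rank_candidates(regs, de, lof)
        assert table.loc[table["gene_id"] == "gA", "rank"].iloc[0] == 1
        assert table.loc[table["gene_id"] == "gB", "rank"].iloc[0] == 2

    def test_monotone_in_each_evidence_component(self):
        regs = [region(lead_p=5.0, genes=("gA", "gB"))]
        base = rank_candidates(regs)
        rank_a0 = base.loc[base["gene_id"] == "gA", "rank"].iloc[0]
        for evidence in (
            dict(de_table=pd.DataFrame({"gene_id": ["gA"], "log2fc": [3.0], "padj": [1e-5]})),
            dict(lof_table=pd.DataFrame({"gene_id": ["gA"], "lof_count": [2]})),
        ):
            table = rank_candidates(regs, **evidence)
            assert table.loc[table["gene_id"] == "gA", "rank"].iloc[0] <= rank_a0

    def test_empty_evidence_reduces_to_association_order(self):
        regs = [
            region(lead_p=4.5, start=0, end=1000, genes=("g_weak",)),
            region(lead_p=8.0, start=2000, end=3000, genes=("g_strong",)),
        ]
        table = rank_candidates(regs)
        assert list(table["gene_id"]) == ["g_strong", "g_weak"]

    def test_block_filter_uses_strict_inequality_at_three(self):
        regs = [region(lead_p=3.0, genes=("g_at_boundary",))]
        assert rank_candidates(regs).empty

    def test_weak_de_evidence_does_not_count(self):
        regs = [region(lead_p=6.0, genes=("gA",))]
        de = pd.DataFrame({"gene_id": ["gA"], "log2fc": [0.5], "padj": [1e-5]})
        table = rank_candidates(regs, de)
        assert table["de_flag"].iloc[0] == 0

    def test_all_zero_weights_rejected(self):
        with pytest.raises(InvalidSpecError):
            rank_candidates([region(genes=("gA",))], weights=(0, 0, 0))
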