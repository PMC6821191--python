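"""Simulator: reference construction, truncation geometry, SAM placement."""

import dataclasses

import numpy as np
import pysam
import pytest

from ficcseq.readproc import dedup
from ficcseq.simdata import (
    CANONICAL_REGION_TABLE,
    T_LOOP_MOTIF,
    ConfigError,
    Gene,
    Reference,
    SimConfig,
    align_synthetic,
    build_reference,
    revcomp,
    simulate_reads,
    write_fastq,
    write_reference,
)
from ficcseq.xlink import extract_crosslinks


def test_canonical_table_places_tloop_at_53():
    cfg = SimConfig()
    assert cfg.t_loop_start() == 53
    assert cfg.m5u_position() == 54
    assert cfg.m1a_position() == 58


def test_every_trna_carries_tloop_motif(small_ref):
    """GTTCGAA occupies mature 53-59 (1-based) of every simulated tRNA."""
    for g in small_ref.genes:
        if g.gene_class != "tRNA":
            continue
        tx = g.transcript_seq(small_ref.genome)
        assert tx[52:59] == T_LOOP_MOTIF
        assert tx[53] == "T"  # m5U target at mature 54
        assert tx[57] == "A"  # m1A at mature 58


def test_no_trna_genes_is_valid():
    cfg = SimConfig(n_trna_genes=0, n_other_genes=2, seed=3)
    ref = build_reference(cfg)
    assert all(g.gene_class == "other" for g in ref.genes)


def test_at_least_one_minus_strand_other_gene(small_ref):
    assert any(
        g.gene_class == "other" and g.strand == "-" for g in small_ref.genes
    )


def test_reference_outputs_deterministic(tmp_path):
    cfg = SimConfig(n_trna_genes=3, n_other_genes=1, seed=42)
    for sub in ("a", "b"):
        d = tmp_path / sub
        d.mkdir()
        ref = build_reference(cfg)
        write_reference(ref, str(d / "g.fa"), str(d / "g.bed"), str(d / "r.tsv"))
    for name in ("g.fa", "g.bed", "r.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        SimConfig(frac_major=0.5, frac_m1a=0.5, frac_background=0.5).validate()
    with pytest.raises(ConfigError):
        SimConfig(mature_len=70).validate()  # table sums to 71
    with pytest.raises(ConfigError):
        SimConfig(region_table=[("t_loop", 7), ("x", -1)], mature_len=6).validate()


@pytest.mark.parametrize("strand", ["+", "-"])
def test_truncation_geometry_per_mode(strand):
    """5'-end placement and expected annotated site follow the mode contract."""
    cfg = SimConfig(n_trna_genes=8, n_other_genes=0, reads_per_gene=60,
                    pcr_dup_mean=0.0, seed=17)
    ref = build_reference(cfg)
    reads = simulate_reads(ref, cfg)
    genes = {g.gene_id: g for g in ref.genes}
    checked = set()
    for row in reads.truth.itertuples():
        g = genes[row.gene_id]
        if g.strand != strand:
            continue
        u_g = g.mature_to_genomic(cfg.m5u_position() - 1)
        a_g = g.mature_to_genomic(cfg.m1a_position() - 1)
        step = -1 if g.strand == "+" else 1
        if row.mode == "ficc_readthrough":
            # RT copies the methylated base: 5' end IS the methylated base,
            # so the annotated site is one base upstream of it
            assert row.five_prime_genomic == u_g
            assert row.methylated_base == u_g
            assert row.expected_annotated_site == u_g + step
        elif row.mode == "m1a_stall":
            # stall immediately before the m1A: annotated site IS the m1A
            assert row.five_prime_genomic == a_g - step
            assert row.methylated_base == a_g
            assert row.expected_annotated_site == a_g
        else:
            assert np.isnan(row.methylated_base)
        checked.add((g.strand, row.mode))
    assert (strand, "ficc_readthrough") in checked
    assert (strand, "m1a_stall") in checked


def test_uv_mode_annotates_the_crosslinked_base():
    cfg = SimConfig(n_trna_genes=2, n_other_genes=0, reads_per_gene=20,
                    library_mode="uv", frac_major=1.0, frac_m1a=0.0,
                    frac_background=0.0, pcr_dup_mean=0.0, seed=2)
    ref = build_reference(cfg)
    reads = simulate_reads(ref, cfg)
    for row in reads.truth.itertuples():
        assert row.expected_annotated_site == row.methylated_base


def test_background_only_truth_has_no_methylated_base():
    cfg = SimConfig(n_trna_genes=4, n_other_genes=0, reads_per_gene=200,
                    frac_major=0.0, frac_m1a=0.0, frac_background=1.0, seed=9)
    ref = build_reference(cfg)
    reads = simulate_reads(ref, cfg)
    assert reads.truth["methylated_base"].isna().all()


def test_intron_excision_shifts_downstream_mature_positions():
    cfg = SimConfig(n_trna_genes=4, n_other_genes=0, n_intron_genes=2,
                    intron_len=13, seed=21)
    ref = build_reference(cfg)
    with_intron = [g for g in ref.genes if g.introns]
    assert len(with_intron) == 2
    for g in with_intron:
        assert g.mature_len == cfg.mature_len
        # motif still at mature 53-59 after excision
        assert g.transcript_seq(ref.genome)[52:59] == T_LOOP_MOTIF
        # positions downstream of the intron shift by its length
        before = g.mature_to_genomic(36)
        after = g.mature_to_genomic(37)
        expected_jump = 1 + cfg.intron_len
        assert abs(after - before) == expected_jump
        # intron interior maps to no mature position
        istart, iend = g.introns[0]
        assert g.genomic_to_mature(istart) is None
        assert g.genomic_to_mature(iend - 1) is None


def test_duplicate_structure(small_reads):
    """FASTQ count >= truth rows; dedup recovers one cDNA per truth row."""
    assert len(small_reads.fastq) >= len(small_reads.truth)
    ids = {p.read_id for p in small_reads.placements}
    base_ids = {i.rsplit("_d", 1)[0] for i in ids}
    assert base_ids == set(small_reads.truth["read_id"])


def test_fastq_and_truth_deterministic(small_cfg, small_ref):
    a = simulate_reads(small_ref, small_cfg)
    b = simulate_reads(small_ref, small_cfg)
    assert a.fastq == b.fastq
    assert a.truth.equals(b.truth)


def _toy_two_read_reference():
    """Hand-built 40-nt genome with one minus-strand gene at [10, 30)."""
    genome = {"c": "ACGTACGTAC" + "A" * 20 + "GTACGTACGT"}
    gene = Gene("g1", "c", 10, 30, "-", "tRNA")
    return Reference(genome=genome, genes=[gene])


def test_minus_strand_sam_records_match_hand_written_expectation(tmp_path):
    """Two reads on a minus-strand gene, checked against SAM lines derived
    by hand: reversed flag set, POS = leftmost base, 5' end = rightmost."""
    from ficcseq.simdata import SimRead, SimReads
    import pandas as pd

    ref = _toy_two_read_reference()
    placements = [
        SimRead("r1", "s", "AAAA", "g1", 0, 5),   # transcript [0,5) -> genomic [25,30)
        SimRead("r2", "s", "CCCC", "g1", 3, 6),   # transcript [3,9) -> genomic [21,27)
    ]
    reads = SimReads(fastq=[], truth=pd.DataFrame(), placements=placements, layout="")
    sam = tmp_path / "toy.sam"
    align_synthetic(reads, ref, str(sam))
    recs = list(pysam.AlignmentFile(str(sam), "r"))
    # hand-derived: r1 at POS 26 (1-based), r2 at POS 22, both flag 16, 5M/6M
    assert [(r.query_name, r.flag, r.reference_start + 1, r.cigarstring) for r in recs] == [
        ("r1", 16, 26, "5M"),
        ("r2", 16, 22, "6M"),
    ]
    # transcript-orientation 5' end is the rightmost aligned base
    assert recs[0].reference_end - 1 == 29
    # SAM stores the reverse complement of the transcript sequence
    tx = ref.genes[0].transcript_seq(ref.genome)
    assert recs[0].query_sequence == revcomp(tx[0:5])


def test_identical_gene_sequences_are_multimapped(tmp_path):
    """Two genes with identical sequences: every read flagged non-unique,
    so downstream unique-only dedup yields nothing for them."""
    cfg = SimConfig(n_trna_genes=2, n_other_genes=0, reads_per_gene=30,
                    pcr_dup_mean=0.0, seed=5)
    ref = build_reference(cfg)
    g0, g1 = ref.genes
    # overwrite gene 1's locus with gene 0's sequence (both plus strand)
    seq = list(ref.genome[cfg.chrom])
    tx0 = ref.genome[cfg.chrom][g0.start:g0.end]
    g0.strand = "+"
    g1.strand = "+"
    seq[g0.start:g0.end] = tx0
    seq[g1.start:g1.end] = tx0
    ref.genome[cfg.chrom] = "".join(seq)
    reads = simulate_reads(ref, cfg)
    sam = tmp_path / "mm.sam"
    align_synthetic(reads, ref, str(sam))
    recs = list(pysam.AlignmentFile(str(sam), "r"))
    assert recs and all(r.get_tag("NH") > 1 for r in recs)
    assert dedup(str(sam)).empty


def test_distinct_gene_sequences_map_uniquely(tmp_path, small_ref, small_cfg, small_reads):
    sam = tmp_path / "uniq.sam"
    align_synthetic(small_reads, small_ref, str(sam))
    recs = list(pysam.AlignmentFile(str(sam), "r"))
    n_unique = sum(1 for r in recs if r.get_tag("NH") == 1)
    assert n_unique / len(recs) > 0.99


def test_roundtrip_maximal_site_matches_truth(tmp_path):
    """End-to-end signal recovery: for >= 99% of tRNA genes the maximal
    crosslink site equals the truth's expected annotated site."""
    cfg = SimConfig(n_trna_genes=10, n_other_genes=0, reads_per_gene=500,
                    frac_major=0.85, frac_m1a=0.05, frac_background=0.10,
                    barcode_map={"r1": "ACGT"}, seed=13)
    ref = build_reference(cfg)
    reads = simulate_reads(ref, cfg)
    sam = tmp_path / "rt.sam"
    align_synthetic(reads, ref, str(sam))
    cdnas = dedup(str(sam))
    sites, _ = extract_crosslinks(cdnas)
    ok = 0
    for g in ref.genes:
        sub = sites[(sites["strand"] == g.strand)
                    & (sites["pos"] >= g.start) & (sites["pos"] < g.end)]
        top = int(sub.loc[sub["count"].idxmax(), "pos"])
        expected = reads.truth[
            (reads.truth["gene_id"] == g.gene_id)
            & (reads.truth["mode"] == "ficc_readthrough")
        ]["expected_annotated_site"].iloc[0]
        ok += top == expected
    assert ok / len(ref.genes) >= 0.99


def test_read_clipping_at_gene_end():
    cfg = SimConfig(n_trna_genes=2, n_other_genes=0, read_len=500, seed=8,
                    reads_per_gene=20, pcr_dup_mean=0.0)
    ref = build_reference(cfg)
    reads = simulate_reads(ref, cfg)
    layout_len = len(reads.layout)
    for _rid, seq, _q in reads.fastq:
        assert len(seq) - layout_len <= cfg.mature_len
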