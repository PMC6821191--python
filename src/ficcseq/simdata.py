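"""Synthetic FICC-Seq / iCLIP-style data generator.

Builds toy genomes with structured tRNA genes, simulates truncation-based
reads with known crosslink geometry, and places them into SAM records so the
whole downstream pipeline (demux -> dedup -> crosslink extraction -> FDR
calling -> peaks -> consensus metagene -> motif) can be tested offline with
full ground truth.

Three truncation geometries are modelled, all stated in transcript
orientation for the 5' end of the cDNA:

* ``ficc_readthrough`` -- the reverse transcriptase copies the catalytically
  crosslinked (methylated) base and then truncates, so the read 5' end IS the
  methylated base.  Downstream annotation (5' end minus one) therefore lands
  one base upstream, and the methylated base is recovered as annotated
  position plus one.
* ``uv_stall`` -- classical UV-iCLIP: the RT stalls immediately before the
  crosslinked base, so the read starts one base 3' of the crosslink and the
  annotated position is the crosslink itself.
* ``m1a_stall`` -- RT stalls immediately before an m1A (tRNA position A58),
  so the read starts one base 3' of the m1A and the annotated position is the
  m1A itself.  This produces the characteristic sub-peak a few nucleotides
  downstream of the major signal.

Background reads truncate uniformly over the gene body.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pysam

__all__ = [
    "CANONICAL_REGION_TABLE",
    "T_LOOP_MOTIF",
    "SimConfig",
    "Gene",
    "Reference",
    "SimReads",
    "build_reference",
    "simulate_reads",
    "align_synthetic",
    "write_fastq",
    "default_umi_layout",
]


class ConfigError(ValueError):
    """Raised for inconsistent simulation configuration."""


# Canonical mature-tRNA secondary-structure segmentation.  The cumulative
# layout puts the T-loop at mature positions 53-59 (1-based), so the forced
# T-loop motif GTTCGAA places the m5U target at mature 54 and the m1A at 58.
CANONICAL_REGION_TABLE: list[tuple[str, int]] = [
    ("acceptor_stem_5p", 7),
    ("d_stem_5p", 4),
    ("d_loop", 8),
    ("d_stem_3p", 4),
    ("linker", 2),
    ("anticodon_stem_5p", 5),
    ("anticodon_loop", 7),
    ("anticodon_stem_3p", 5),
    ("variable_loop", 5),
    ("t_stem_5p", 5),
    ("t_loop", 7),
    ("t_stem_3p", 5),
    ("acceptor_stem_3p", 7),
]

T_LOOP_MOTIF = "GTTCGAA"

_MATURE_LEN_DEFAULT = sum(l for _, l in CANONICAL_REGION_TABLE)  # 71 nt

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def default_umi_layout(umi_len: int, barcode_len: int) -> str:
    """Read 5'-end layout string: ``N`` = UMI base, ``B`` = barcode base."""
    return "N" * umi_len + "B" * barcode_len


@dataclass
class SimConfig:
    """All knobs of the synthetic library.

    Fractions refer to reads on tRNA genes; non-tRNA genes receive only
    uniform background truncations (plus, for the designated binding-only
    gene, nothing enzyme-specific -- binding without catalysis leaves no
    FICC signal).
    """

    n_trna_genes: int = 20
    n_other_genes: int = 3
    mature_len: int = _MATURE_LEN_DEFAULT
    region_table: list[tuple[str, int]] = field(
        default_factory=lambda: list(CANONICAL_REGION_TABLE)
    )
    reads_per_gene: int = 1000
    reads_per_other_gene: int = 200
    frac_major: float = 0.80
    frac_m1a: float = 0.15
    frac_background: float = 0.05
    library_mode: str = "ficc"  # "ficc" (read-through major) or "uv" (stall major)
    pcr_dup_mean: float = 1.0
    umi_len: int = 8
    barcode_map: dict[str, str] = field(
        default_factory=lambda: {"rep1": "ACGT", "rep2": "TGCA"}
    )
    read_len: int = 30
    n_intron_genes: int = 0
    intron_len: int = 11
    other_gene_len: int = 300
    gap_len: int = 100
    chrom: str = "chrS"
    seed: int = 0

    def validate(self) -> None:
        fr = self.frac_major + self.frac_m1a + self.frac_background
        if abs(fr - 1.0) > 1e-9:
            raise ConfigError(
                f"mode fractions must sum to 1 (got {fr!r})"
            )
        for name, val in [
            ("mature_len", self.mature_len),
            ("reads_per_gene", self.reads_per_gene),
            ("umi_len", self.umi_len),
            ("read_len", self.read_len),
        ]:
            if val <= 0:
                raise ConfigError(f"{name} must be > 0 (got {val})")
        region_sum = sum(l for _, l in self.region_table)
        if region_sum != self.mature_len:
            raise ConfigError(
                f"region_table lengths sum to {region_sum}, "
                f"but mature_len is {self.mature_len}"
            )
        if any(l <= 0 for _, l in self.region_table):
            raise ConfigError("all region lengths must be > 0")
        if self.library_mode not in ("ficc", "uv"):
            raise ConfigError(f"unknown library_mode {self.library_mode!r}")
        tloop = [(n, l) for n, l in self.region_table if n == "t_loop"]
        if not tloop:
            raise ConfigError("region_table must contain a 't_loop' region")
        if tloop[0][1] < len(T_LOOP_MOTIF):
            raise ConfigError(
                f"t_loop region must hold the {len(T_LOOP_MOTIF)}-nt motif"
            )
        if self.n_intron_genes > self.n_trna_genes:
            raise ConfigError("n_intron_genes exceeds n_trna_genes")

    # -- derived coordinates (1-based mature) ------------------------------
    def t_loop_start(self) -> int:
        off = 0
        for name, l in self.region_table:
            if name == "t_loop":
                return off + 1
            off += l
        raise ConfigError("no t_loop region")

    def m5u_position(self) -> int:
        """Mature 1-based position of the targeted uridine (U54 canonically)."""
        return self.t_loop_start() + 1

    def m1a_position(self) -> int:
        """Mature 1-based position of the m1A (A58 canonically)."""
        return self.t_loop_start() + 5


@dataclass
class Gene:
    """A gene with optional introns and a mature-coordinate region layout."""

    gene_id: str
    chrom: str
    start: int  # genomic, 0-based
    end: int  # genomic, half-open
    strand: str
    gene_class: str  # "tRNA" | "other"
    introns: list[tuple[int, int]] = field(default_factory=list)  # genomic
    regions: list[tuple[str, int, int]] = field(default_factory=list)
    # regions: (name, mature_start, mature_end), 0-based half-open

    def exon_blocks(self) -> list[tuple[int, int]]:
        """Genomic exon intervals in ascending order (introns excised)."""
        blocks = []
        pos = self.start
        for istart, iend in sorted(self.introns):
            if istart > pos:
                blocks.append((pos, istart))
            pos = iend
        if pos < self.end:
            blocks.append((pos, self.end))
        return blocks

    @property
    def mature_len(self) -> int:
        return sum(e - s for s, e in self.exon_blocks())

    def mature_to_genomic(self, m: int) -> int:
        """Map a 0-based mature (transcript) position to its genomic base."""
        if not 0 <= m < self.mature_len:
            raise IndexError(f"mature position {m} outside gene {self.gene_id}")
        blocks = self.exon_blocks()
        if self.strand == "-":
            blocks = [(s, e) for s, e in reversed(blocks)]
            for s, e in blocks:
                if m < e - s:
                    return e - 1 - m
                m -= e - s
        else:
            for s, e in blocks:
                if m < e - s:
                    return s + m
                m -= e - s
        raise AssertionError("unreachable")

    def genomic_to_mature(self, g: int) -> int | None:
        """Inverse of :meth:`mature_to_genomic`; None for intronic/outside."""
        if not self.start <= g < self.end:
            return None
        off = 0
        blocks = self.exon_blocks()
        if self.strand == "-":
            for s, e in reversed(blocks):
                if s <= g < e:
                    return off + (e - 1 - g)
                off += e - s
        else:
            for s, e in blocks:
                if s <= g < e:
                    return off + (g - s)
                off += e - s
        return None

    def transcript_seq(self, genome: dict[str, str]) -> str:
        seq = "".join(genome[self.chrom][s:e] for s, e in self.exon_blocks())
        return revcomp(seq) if self.strand == "-" else seq

    def mature_interval_blocks(self, mstart: int, mend: int) -> list[tuple[int, int]]:
        """Genomic blocks (ascending) covered by mature [mstart, mend)."""
        positions = [self.mature_to_genomic(m) for m in range(mstart, mend)]
        positions.sort()
        blocks: list[list[int]] = []
        for p in positions:
            if blocks and p == blocks[-1][1]:
                blocks[-1][1] = p + 1
            else:
                blocks.append([p, p + 1])
        return [(s, e) for s, e in blocks]


@dataclass
class Reference:
    genome: dict[str, str]
    genes: list[Gene]

    def gene(self, gene_id: str) -> Gene:
        return next(g for g in self.genes if g.gene_id == gene_id)


@dataclass
class SimRead:
    """Placement record for one emitted FASTQ read (PCR copies included)."""

    read_id: str
    sample: str
    umi: str
    gene_id: str
    t5: int  # 0-based mature position of the read 5' end
    insert_len: int


@dataclass
class SimReads:
    fastq: list[tuple[str, str, str]]  # (read_id, sequence, quality)
    truth: "object"  # pandas.DataFrame, one row per unique cDNA
    placements: list[SimRead]
    layout: str


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def build_reference(cfg: SimConfig) -> Reference:
    """Construct the toy genome, gene annotation, and tRNA region layout.

    Every tRNA gene carries the T-loop motif GTTCGAA at its T-loop region
    (second motif base at mature position 54 under the canonical table);
    a configurable subset receives an intron inserted after mature position
    37 (the canonical anticodon-loop insertion point).  Deterministic for a
    fixed seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # mature-coordinate region spans
    regions: list[tuple[str, int, int]] = []
    off = 0
    for name, l in cfg.region_table:
        regions.append((name, off, off + l))
        off += l
    tloop_span = next((s, e) for n, s, e in regions if n == "t_loop")

    # choose which tRNA genes get an intron (first n_intron_genes, for
    # reproducibility independent of strand draws)
    intron_flags = [i < cfg.n_intron_genes for i in range(cfg.n_trna_genes)]
    # canonical insertion point: after mature position 37 (1-based), clipped
    ins_point = min(37, max(1, cfg.mature_len - 1))

    chrom_parts: list[str] = []
    genes: list[Gene] = []
    cursor = 0
    seen_transcripts: set[str] = set()

    def _push(seq: str) -> int:
        nonlocal cursor
        chrom_parts.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    for i in range(cfg.n_trna_genes):
        _push(_random_seq(rng, cfg.gap_len))
        while True:
            mature = list(_random_seq(rng, cfg.mature_len))
            mstart = tloop_span[0]
            mature[mstart : mstart + len(T_LOOP_MOTIF)] = T_LOOP_MOTIF
            mature_s = "".join(mature)
            if mature_s not in seen_transcripts:
                seen_transcripts.add(mature_s)
                break
        strand = "+" if rng.random() < 0.5 else "-"
        introns_mature: list[tuple[int, str]] = []
        if intron_flags[i]:
            introns_mature.append((ins_point, _random_seq(rng, cfg.intron_len)))
        # build genomic (pre-mRNA) sequence in transcript orientation
        tx = mature_s
        for ip, iseq in sorted(introns_mature, reverse=True):
            tx = tx[:ip] + iseq + tx[ip:]
        gseq = revcomp(tx) if strand == "-" else tx
        gstart = _push(gseq)
        gend = gstart + len(gseq)
        introns: list[tuple[int, int]] = []
        for ip, iseq in introns_mature:
            if strand == "+":
                s = gstart + ip
            else:
                s = gend - ip - len(iseq)
            introns.append((s, s + len(iseq)))
        genes.append(
            Gene(
                gene_id=f"trna_{i:04d}",
                chrom=cfg.chrom,
                start=gstart,
                end=gend,
                strand=strand,
                gene_class="tRNA",
                introns=introns,
                regions=list(regions),
            )
        )

    for j in range(cfg.n_other_genes):
        _push(_random_seq(rng, cfg.gap_len))
        while True:
            mature_s = _random_seq(rng, cfg.other_gene_len)
            if mature_s not in seen_transcripts:
                seen_transcripts.add(mature_s)
                break
        # last non-tRNA gene is forced to the minus strand ("binding-only"
        # genes in real data include minus-strand cases)
        if j == cfg.n_other_genes - 1:
            strand = "-"
        else:
            strand = "+" if rng.random() < 0.5 else "-"
        gseq = revcomp(mature_s) if strand == "-" else mature_s
        gstart = _push(gseq)
        genes.append(
            Gene(
                gene_id=f"other_{j:04d}",
                chrom=cfg.chrom,
                start=gstart,
                end=gstart + len(gseq),
                strand=strand,
                gene_class="other",
            )
        )
    _push(_random_seq(rng, cfg.gap_len))

    genome = {cfg.chrom: "".join(chrom_parts)}
    return Reference(genome=genome, genes=genes)


def _truth_columns():
    return [
        "read_id",
        "sample",
        "gene_id",
        "chrom",
        "strand",
        "mode",
        "methylated_base",
        "expected_annotated_site",
        "five_prime_genomic",
        "umi",
    ]


def simulate_reads(ref: Reference, cfg: SimConfig):
    """Simulate UMI-tagged, barcode-prefixed truncation reads with truth.

    Returns a :class:`SimReads` with raw FASTQ tuples (barcode and UMI still
    attached), one ground-truth row per unique cDNA, and per-read placement
    records used by :func:`align_synthetic`.
    """
    import pandas as pd

    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    layout = default_umi_layout(cfg.umi_len, len(next(iter(cfg.barcode_map.values()))))
    bc_lens = {len(b) for b in cfg.barcode_map.values()}
    if len(bc_lens) != 1:
        raise ConfigError("all barcodes must share one length")

    major_mode = "ficc_readthrough" if cfg.library_mode == "ficc" else "uv_stall"
    modes = np.array([major_mode, "m1a_stall", "background"])
    probs = np.array([cfg.frac_major, cfg.frac_m1a, cfg.frac_background])

    fastq: list[tuple[str, str, str]] = []
    placements: list[SimRead] = []
    truth_rows: list[dict] = []

    for sample in sorted(cfg.barcode_map):
        barcode = cfg.barcode_map[sample]
        for gene in ref.genes:
            tx = gene.transcript_seq(ref.genome)
            L = gene.mature_len
            if gene.gene_class == "tRNA":
                n_reads = cfg.reads_per_gene
                u_m = cfg.m5u_position() - 1  # 0-based mature
                a_m = cfg.m1a_position() - 1
                gene_modes = modes[
                    rng.choice(len(modes), size=n_reads, p=probs)
                ]
            else:
                n_reads = cfg.reads_per_other_gene
                gene_modes = np.array(["background"] * n_reads)

            for k, mode in enumerate(gene_modes):
                if mode == "ficc_readthrough":
                    t5 = u_m
                    meth_m = u_m
                elif mode == "uv_stall":
                    t5 = min(u_m + 1, L - 1)
                    meth_m = u_m
                elif mode == "m1a_stall":
                    t5 = min(a_m + 1, L - 1)
                    meth_m = a_m
                else:
                    t5 = int(rng.integers(0, L))
                    meth_m = None
                ilen = min(cfg.read_len, L - t5)
                insert = tx[t5 : t5 + ilen]
                umi = _random_seq(rng, cfg.umi_len)
                read_id = f"{sample}:{gene.gene_id}:{k:06d}"

                g5 = gene.mature_to_genomic(t5)
                step = -1 if gene.strand == "+" else 1
                annotated = g5 + step
                meth_g = (
                    gene.mature_to_genomic(meth_m) if meth_m is not None else None
                )
                truth_rows.append(
                    dict(
                        read_id=read_id,
                        sample=sample,
                        gene_id=gene.gene_id,
                        chrom=gene.chrom,
                        strand=gene.strand,
                        mode=mode,
                        methylated_base=meth_g,
                        expected_annotated_site=annotated,
                        five_prime_genomic=g5,
                        umi=umi,
                    )
                )

                raw_prefix = _fill_layout(layout, umi, barcode)
                n_copies = 1 + int(rng.poisson(cfg.pcr_dup_mean))
                for d in range(n_copies):
                    rid = f"{read_id}_d{d}"
                    fastq.append((rid, raw_prefix + insert, "I" * (len(layout) + ilen)))
                    placements.append(
                        SimRead(
                            read_id=rid,
                            sample=sample,
                            umi=umi,
                            gene_id=gene.gene_id,
                            t5=t5,
                            insert_len=ilen,
                        )
                    )

    truth = pd.DataFrame(truth_rows, columns=_truth_columns())
    return SimReads(fastq=fastq, truth=truth, placements=placements, layout=layout)


def _fill_layout(layout: str, umi: str, barcode: str) -> str:
    out = []
    iu = ib = 0
    for c in layout:
        if c == "N":
            out.append(umi[iu])
            iu += 1
        elif c == "B":
            out.append(barcode[ib])
            ib += 1
        else:
            raise ConfigError(f"layout character {c!r} not in {{N,B}}")
    return "".join(out)


def write_fastq(reads: SimReads, path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads.fastq:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def _count_occurrences(hay: str, needle: str) -> int:
    n = start = 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def align_synthetic(reads: SimReads, ref: Reference, sam_path: str) -> None:
    """Write SAM records placing every simulated read at its true locus.

    Reads whose insert sequence occurs at more than one annotated locus are
    emitted with ``NH > 1`` and mapping quality 0, so the downstream
    unique-mapping filter is exercised; unique reads get ``NH:i:1``.
    Spliced placements (reads crossing an intron) receive ``N`` CIGAR ops.
    """
    transcripts = {g.gene_id: g.transcript_seq(ref.genome) for g in ref.genes}
    searchable = {gid: (tx, revcomp(tx)) for gid, tx in transcripts.items()}
    genes = {g.gene_id: g for g in ref.genes}
    samples = sorted({p.sample for p in reads.placements})

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": chrom, "LN": len(seq)} for chrom, seq in sorted(ref.genome.items())
        ],
        "RG": [{"ID": s, "SM": s} for s in samples],
    }
    sq_index = {chrom: i for i, chrom in enumerate(sorted(ref.genome))}

    multiplicity_cache: dict[str, int] = {}

    with pysam.AlignmentFile(sam_path, "w", header=header) as out:
        for p in reads.placements:
            gene = genes[p.gene_id]
            tx = transcripts[p.gene_id]
            insert = tx[p.t5 : p.t5 + p.insert_len]
            blocks = gene.mature_interval_blocks(p.t5, p.t5 + p.insert_len)
            genomic = "".join(
                ref.genome[gene.chrom][s:e] for s, e in blocks
            )
            if gene.strand == "-":
                genomic = revcomp(genomic)
            if not insert or genomic != insert:
                raise RuntimeError(f"read {p.read_id} not derivable from reference")
            if insert not in multiplicity_cache:
                hits = 0
                for fwd, rev in searchable.values():
                    hits += _count_occurrences(fwd, insert)
                    hits += _count_occurrences(rev, insert)
                multiplicity_cache[insert] = hits
            nh = multiplicity_cache[insert]
            if nh < 1:
                raise RuntimeError(f"read {p.read_id} not derivable from reference")

            ref_start = blocks[0][0]
            cigar = []
            prev_end = None
            for s, e in blocks:
                if prev_end is not None and s > prev_end:
                    cigar.append((3, s - prev_end))  # N
                cigar.append((0, e - s))  # M
                prev_end = e

            a = pysam.AlignedSegment()
            a.query_name = p.read_id
            a.query_sequence = revcomp(insert) if gene.strand == "-" else insert
            a.flag = 16 if gene.strand == "-" else 0
            a.reference_id = sq_index[gene.chrom]
            a.reference_start = ref_start
            a.mapping_quality = 255 if nh == 1 else 0
            a.cigar = cigar
            a.query_qualities = pysam.qualitystring_to_array("I" * p.insert_len)
            a.set_tag("NH", nh)
            a.set_tag("RG", p.sample)
            a.set_tag("RX", p.umi)
            out.write(a)


# ---------------------------------------------------------------------------
# plain-text writers for the reference


def write_reference(ref: Reference, fasta_path: str, bed_path: str, regions_path: str) -> None:
    """Write genome FASTA, BED6 gene annotation, and tRNA region table TSV."""
    with open(fasta_path, "w") as fh:
        for chrom in sorted(ref.genome):
            fh.write(f">{chrom}\n")
            seq = ref.genome[chrom]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(bed_path, "w") as fh:
        for g in ref.genes:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
            )
    with open(regions_path, "w") as fh:
        fh.write(
            "gene_id\tregion_name\tmature_start\tmature_end\t"
            "chrom\tgenomic_start\tgenomic_end\tstrand\n"
        )
        for g in ref.genes:
            if g.gene_class != "tRNA":
                continue
            for name, ms, me in g.regions:
                gpos = sorted(g.mature_to_genomic(m) for m in range(ms, me))
                fh.write(
                    f"{g.gene_id}\t{name}\t{ms}\t{me}\t{g.chrom}\t"
                    f"{gpos[0]}\t{gpos[-1] + 1}\t{g.strand}\n"
                )
            for istart, iend in g.introns:
                # intron rows: mature span is the (empty) insertion point
                ip = g.genomic_to_mature(iend if g.strand == "+" else istart - 1)
                fh.write(
                    f"{g.gene_id}\tintron\t{ip}\t{ip}\t{g.chrom}\t"
                    f"{istart}\t{iend}\t{g.strand}\n"
                )


def load_genes_bed(bed_path: str) -> list[Gene]:
    """Read the BED6 annotation back into Gene records (no region layout)."""
    genes = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.split()[:6]
            genes.append(
                Gene(
                    gene_id=name,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    gene_class="tRNA" if name.startswith("trna") else "other",
                )
            )
    return genes
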