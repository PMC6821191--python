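"""Demultiplexing, UMI extraction, and PCR-duplicate collapsing.

Raw reads carry an in-line layout at the 5' end (``N`` bases are the random
UMI, ``B`` bases the sample barcode).  After alignment, PCR duplicates are
collapsed to unique cDNAs keyed on (sample, chrom, strand, 5'-end position,
UMI) -- exact UMI match, no edit-distance clustering.  Only uniquely mapping
alignments are admitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pysam

__all__ = ["TaggedRead", "DemuxResult", "demultiplex_trim", "dedup", "read_fastq"]

UNDETERMINED = "undetermined"


@dataclass
class TaggedRead:
    read_id: str
    sample: str
    umi: str
    sequence: str
    quality: str = ""


@dataclass
class DemuxResult:
    by_sample: dict[str, list[TaggedRead]]
    counts: dict[str, int]
    n_too_short: int = 0


def read_fastq(path: str):
    """Yield (read_id, sequence, quality) from an uncompressed FASTQ."""
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head:
                return
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            yield head[1:].split()[0], seq, qual


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex_trim(
    reads,
    barcode_map: dict[str, str],
    umi_layout: str,
    max_mismatch: int = 1,
) -> DemuxResult:
    """Split reads by in-line barcode and strip the barcode+UMI prefix.

    ``reads`` is an iterable of (read_id, sequence, quality) tuples (e.g.
    from :func:`read_fastq`).  A read is assigned to the unique barcode
    within ``max_mismatch`` Hamming distance; ambiguous or distant barcodes
    go to the ``undetermined`` bin.  Reads shorter than the layout are
    discarded and counted.
    """
    n_pos = [i for i, c in enumerate(umi_layout) if c == "N"]
    b_pos = [i for i, c in enumerate(umi_layout) if c == "B"]
    layout_len = len(umi_layout)
    for sample, bc in barcode_map.items():
        if len(bc) != len(b_pos):
            raise ValueError(
                f"barcode for {sample!r} has length {len(bc)}, layout expects {len(b_pos)}"
            )

    by_sample: dict[str, list[TaggedRead]] = {s: [] for s in barcode_map}
    by_sample[UNDETERMINED] = []
    n_too_short = 0

    for rid, seq, qual in reads:
        if len(seq) < layout_len:
            n_too_short += 1
            continue
        umi = "".join(seq[i] for i in n_pos)
        bc_obs = "".join(seq[i] for i in b_pos)
        best, best_d, ties = None, None, 0
        for sample, bc in barcode_map.items():
            d = _hamming(bc_obs, bc)
            if best_d is None or d < best_d:
                best, best_d, ties = sample, d, 1
            elif d == best_d:
                ties += 1
        if best_d is None or best_d > max_mismatch or ties > 1:
            target = UNDETERMINED
        else:
            target = best
        by_sample[target].append(
            TaggedRead(
                read_id=rid,
                sample=target,
                umi=umi,
                sequence=seq[layout_len:],
                quality=qual[layout_len:] if qual else "",
            )
        )

    counts = {s: len(v) for s, v in by_sample.items()}
    return DemuxResult(by_sample=by_sample, counts=counts, n_too_short=n_too_short)


_CDNA_COLS = [
    "sample",
    "chrom",
    "strand",
    "five_prime_pos",
    "umi",
    "support",
    "start",
    "end",
]


def dedup(alignments) -> pd.DataFrame:
    """Collapse aligned reads to unique cDNAs.

    ``alignments`` is a SAM/BAM path, an iterable of
    ``pysam.AlignedSegment``, or a DataFrame already in unique-cDNA form
    (in which case collapsing is idempotent).  Multi-mapping records
    (``NH > 1`` or secondary/supplementary flags) are excluded.

    Returns a DataFrame with columns sample, chrom, strand, five_prime_pos
    (transcript-orientation 5' end: leftmost base on +, rightmost on -),
    umi, support (number of collapsed duplicates) and the alignment span
    [start, end) of the representative read.
    """
    if isinstance(alignments, pd.DataFrame):
        if alignments.empty:
            return pd.DataFrame(columns=_CDNA_COLS)
        grouped = (
            alignments.groupby(
                ["sample", "chrom", "strand", "five_prime_pos", "umi"], sort=True
            )
            .agg(support=("support", "sum"), start=("start", "min"), end=("end", "max"))
            .reset_index()
        )
        return grouped[_CDNA_COLS]

    if isinstance(alignments, str):
        with pysam.AlignmentFile(alignments, "r") as fh:
            return _dedup_segments(fh)
    return _dedup_segments(alignments)


def _dedup_segments(segments) -> pd.DataFrame:
    rows: dict[tuple, list] = {}
    for a in segments:
        if a.is_unmapped or a.is_secondary or a.is_supplementary:
            continue
        if a.has_tag("NH") and a.get_tag("NH") > 1:
            continue
        strand = "-" if a.is_reverse else "+"
        fpp = a.reference_end - 1 if a.is_reverse else a.reference_start
        sample = a.get_tag("RG") if a.has_tag("RG") else "sample"
        umi = a.get_tag("RX") if a.has_tag("RX") else ""
        key = (sample, a.reference_name, strand, fpp, umi)
        rec = rows.get(key)
        if rec is None:
            rows[key] = [1, a.reference_start, a.reference_end]
        else:
            rec[0] += 1
            rec[1] = min(rec[1], a.reference_start)
            rec[2] = max(rec[2], a.reference_end)
    out = [
        dict(
            sample=k[0],
            chrom=k[1],
            strand=k[2],
            five_prime_pos=k[3],
            umi=k[4],
            support=v[0],
            start=v[1],
            end=v[2],
        )
        for k, v in sorted(rows.items())
    ]
    return pd.DataFrame(out, columns=_CDNA_COLS)
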