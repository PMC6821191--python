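"""Single-nucleotide crosslink extraction from unique cDNAs.

The truncation rule: the annotated crosslink site is the nucleotide
immediately preceding the cDNA 5' end in transcript orientation (reverse
transcription stalls immediately before the crosslinked base).  On the plus
strand that is genomic position minus one; on the minus strand, plus one.
Counts are unique cDNAs — PCR-duplicate support is never multiplied in.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["extract_crosslinks", "write_tracks", "read_bed6_sites"]

_SITE_COLS = ["sample", "chrom", "strand", "pos", "count"]


def extract_crosslinks(
    cdnas: pd.DataFrame, chrom_lengths: dict[str, int] | None = None
) -> tuple[pd.DataFrame, int]:
    """Convert unique cDNAs to per-sample crosslink-site counts.

    Returns (sites, n_skipped) where sites has one row per
    (sample, chrom, strand, pos) with the number of unique cDNAs whose
    truncation annotates that nucleotide; cDNAs whose site would fall
    outside the chromosome are skipped and counted.
    """
    if cdnas.empty:
        return pd.DataFrame(columns=_SITE_COLS), 0
    df = cdnas.copy()
    step = df["strand"].map({"+": -1, "-": 1})
    df["pos"] = df["five_prime_pos"] + step
    ok = df["pos"] >= 0
    if chrom_lengths is not None:
        ok &= df["pos"] < df["chrom"].map(chrom_lengths)
    n_skipped = int((~ok).sum())
    df = df[ok]
    sites = (
        df.groupby(["sample", "chrom", "strand", "pos"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return sites[_SITE_COLS], n_skipped


def write_tracks(sites: pd.DataFrame, prefix: str) -> list[str]:
    """Write strand-split bedGraph files per sample plus one combined BED6.

    bedGraph lines are 0-based half-open single-nucleotide intervals;
    the BED6 carries the count in the score column and strand in column 6.
    Returns the list of written paths.
    """
    paths = []
    samples = sorted(sites["sample"].unique()) if not sites.empty else []
    for sample in samples or ["all"]:
        sub = sites[sites["sample"] == sample] if samples else sites
        for strand, tag in (("+", "plus"), ("-", "minus")):
            path = f"{prefix}.{sample}.{tag}.bedgraph"
            ss = sub[sub["strand"] == strand].sort_values(["chrom", "pos"])
            with open(path, "w") as fh:
                fh.write(f'track type=bedGraph name="{sample} ({strand})"\n')
                for row in ss.itertuples():
                    fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.count}\n")
            paths.append(path)
    bed_path = f"{prefix}.sites.bed"
    with open(bed_path, "w") as fh:
        for row in sites.sort_values(["sample", "chrom", "pos"]).itertuples():
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.sample}\t"
                f"{row.count}\t{row.strand}\n"
            )
    paths.append(bed_path)
    return paths


def read_bed6_sites(path: str) -> pd.DataFrame:
    """Read back a BED6 written by :func:`write_tracks`."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, _end, name, score, strand = line.split()[:6]
            rows.append(
                dict(
                    sample=name,
                    chrom=chrom,
                    strand=strand,
                    pos=int(start),
                    count=int(score),
                )
            )
    return pd.DataFrame(rows, columns=_SITE_COLS)
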