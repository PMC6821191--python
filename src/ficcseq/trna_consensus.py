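"""Structural consensus metagene for mature tRNAs.

Mature tRNAs differ in length but share a secondary-structure layout
(acceptor stem, D-arm, anticodon arm, variable loop, T-arm).  To aggregate
single-nucleotide signal across genes, each gene's mature positions are
binned relative to the structural region they belong to: per region the
consensus length is the rounded mean over genes, a mature offset o in a
region of length l maps to consensus offset floor(o * l_cons / l), and the
consensus base at each position is the most frequent base (ties become
IUPAC ambiguity codes).  Introns are excised before segmentation.  Report
coordinates are 1-based so that the canonical T-loop motif reads
G53-T54-T55-C56-G57-A58-A59 (m5U54 and m1A58 at their textbook numbers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import Gene

__all__ = [
    "ConsensusModel",
    "ConsensusProfile",
    "build_consensus",
    "project_sites",
    "infer_methylated_base",
]

_IUPAC = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


@dataclass
class ConsensusModel:
    regions: list[tuple[str, int]]  # (region_name, consensus_length)
    sequence: str  # IUPAC max-frequency consensus
    offset_map: dict[tuple[str, int], int]  # (gene_id, mature 0-based) -> cons 0-based

    @property
    def length(self) -> int:
        return sum(l for _, l in self.regions)

    def region_of(self, cons_pos: int) -> str:
        off = 0
        for name, l in self.regions:
            if cons_pos < off + l:
                return name
            off += l
        raise IndexError(cons_pos)


@dataclass
class ConsensusProfile:
    values: np.ndarray  # per consensus position (0-based), aggregated counts
    n_genes: int
    mode: str  # "annotated_site" | "inferred_methylation"
    n_dropped: int = 0

    def to_frame(self, model: ConsensusModel) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "consensus_pos": np.arange(1, len(self.values) + 1),
                "region_name": [model.region_of(i) for i in range(len(self.values))],
                "count": self.values,
            }
        )


def build_consensus(genes: list[Gene], genome: dict[str, str]) -> ConsensusModel:
    """Build the consensus coordinate system from segmented tRNA genes.

    Genes whose region lengths do not sum to their mature length are
    rejected.  Consensus region length = round(mean over genes); consensus
    base = max-frequency base among the gene bases mapping there.
    """
    trnas = [g for g in genes if g.regions]
    if not trnas:
        raise ValueError("no segmented tRNA genes supplied")
    names = [n for n, _s, _e in trnas[0].regions]
    for g in trnas:
        if [n for n, _s, _e in g.regions] != names:
            raise ValueError(f"gene {g.gene_id} has a different region ordering")
        if g.regions[-1][2] != g.mature_len:
            raise ValueError(
                f"gene {g.gene_id}: region lengths do not sum to mature length"
            )

    cons_regions = []
    for idx, name in enumerate(names):
        lens = [g.regions[idx][2] - g.regions[idx][1] for g in trnas]
        cons_len = int(np.floor(np.mean(lens) + 0.5))
        cons_regions.append((name, max(1, cons_len)))

    # per-gene offset map and per-consensus-position base tallies
    offset_map: dict[tuple[str, int], int] = {}
    total_len = sum(l for _, l in cons_regions)
    tallies: list[dict[str, int]] = [dict() for _ in range(total_len)]
    for g in trnas:
        tx = g.transcript_seq(genome)
        cons_start = 0
        for (name, l_cons), (_n, ms, me) in zip(cons_regions, g.regions):
            l = me - ms
            for o in range(l):
                cpos = cons_start + min(l_cons - 1, (o * l_cons) // l)
                offset_map[(g.gene_id, ms + o)] = cpos
                base = tx[ms + o]
                tallies[cpos][base] = tallies[cpos].get(base, 0) + 1
            cons_start += l_cons

    seq = []
    for tally in tallies:
        if not tally:
            seq.append("N")
            continue
        best = max(tally.values())
        winners = frozenset(b for b, c in tally.items() if c == best)
        seq.append(_IUPAC.get(winners, "N"))
    return ConsensusModel(regions=cons_regions, sequence="".join(seq), offset_map=offset_map)


def project_sites(
    sites: pd.DataFrame,
    genes: list[Gene],
    model: ConsensusModel,
    mode: str = "annotated_site",
) -> ConsensusProfile:
    """Project crosslink sites onto the consensus and aggregate counts.

    ``mode='annotated_site'`` projects the sites as given;
    ``mode='inferred_methylation'`` first applies the catalytic +1 shift in
    transcript orientation (the methylated base is one base 3' of the
    annotated truncation site).  Intronic sites, sites in unsegmented
    genes, and shifted positions leaving the gene are dropped and counted.
    Projection conserves mass over the non-dropped sites.
    """
    if mode not in ("annotated_site", "inferred_methylation"):
        raise ValueError(f"unknown mode {mode!r}")
    seg = [g for g in genes if g.regions]
    values = np.zeros(model.length)
    n_dropped = 0
    gene_ids = set()
    for row in sites.itertuples():
        gene = None
        for g in seg:
            if (
                g.chrom == row.chrom
                and g.strand == row.strand
                and g.start <= row.pos < g.end
            ):
                gene = g
                break
        if gene is None:
            n_dropped += 1
            continue
        m = gene.genomic_to_mature(row.pos)
        if m is None:  # intronic
            n_dropped += 1
            continue
        if mode == "inferred_methylation":
            m += 1
            if m >= gene.mature_len:
                n_dropped += 1
                continue
        cpos = model.offset_map.get((gene.gene_id, m))
        if cpos is None:
            n_dropped += 1
            continue
        values[cpos] += row.count
        gene_ids.add(gene.gene_id)
    return ConsensusProfile(
        values=values, n_genes=len(gene_ids), mode=mode, n_dropped=n_dropped
    )


def infer_methylated_base(
    pos: int, strand: str, mode: str, gene: Gene | None = None, model: ConsensusModel | None = None
) -> tuple[int | None, int | None]:
    """Predicted methylated base for an annotated peak position.

    Catalytic crosslinking (FICC, miCLIP): the RT copies the crosslinked
    base before truncating, so the methylated base is the annotated site
    plus one in transcript orientation (genomic +1 on plus, -1 on minus).
    UV crosslinking: the annotated site is the crosslink itself (identity).

    Returns (genomic position, 1-based consensus position or None).  If the
    shift leaves the gene, both are None (boundary case).
    """
    if mode not in ("catalytic", "uv"):
        raise ValueError(f"unknown experiment mode {mode!r}")
    if mode == "catalytic":
        g = pos + (1 if strand == "+" else -1)
    else:
        g = pos
    cons = None
    if gene is not None:
        if not gene.start <= g < gene.end:
            return None, None
        if model is not None:
            m = gene.genomic_to_mature(g)
            if m is not None:
                cpos = model.offset_map.get((gene.gene_id, m))
                cons = cpos + 1 if cpos is not None else None
    return g, cons
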