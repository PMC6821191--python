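"""Small readers shared by the CLI: FASTA genomes and region tables."""

from __future__ import annotations

from Bio import SeqIO

from .simdata import Gene

__all__ = ["read_fasta", "load_segmented_genes"]


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def load_segmented_genes(regions_path: str) -> list[Gene]:
    """Rebuild segmented tRNA genes from the region-table TSV.

    Rows named ``intron`` carry genomic intron intervals; the remaining
    rows give mature-coordinate structural regions in order.
    """
    import pandas as pd

    df = pd.read_csv(regions_path, sep="\t")
    genes = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        struct = grp[grp["region_name"] != "intron"]
        introns = grp[grp["region_name"] == "intron"]
        genes.append(
            Gene(
                gene_id=gene_id,
                chrom=struct["chrom"].iloc[0],
                start=int(grp["genomic_start"].min()),
                end=int(grp["genomic_end"].max()),
                strand=struct["strand"].iloc[0],
                gene_class="tRNA",
                introns=[
                    (int(r.genomic_start), int(r.genomic_end))
                    for r in introns.itertuples()
                ],
                regions=[
                    (r.region_name, int(r.mature_start), int(r.mature_end))
                    for r in struct.itertuples()
                ],
            )
        )
    return genes
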