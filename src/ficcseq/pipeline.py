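"""End-to-end pipeline orchestration.

Runs simulate -> demux -> align -> dedup -> crosslink extraction ->
permutation FDR calling -> peak refinement and replicate merging ->
counting/normalization/correlation -> consensus projection -> motif
recovery, writing one TSV report per stage plus a JSON manifest.  Outputs
are pure functions of (config, seed): re-running with the same config
reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import pandas as pd

from . import __version__
from .motif import discover_motif, extract_flanks, filter_anchor, pwm_consensus, write_pwm
from .peakcall import (
    RefineParams,
    annotate_peaks,
    call_peaks,
    correlate,
    count_clusters,
    merge_replicates,
    normalize_counts,
)
from .readproc import dedup, demultiplex_trim
from .sigcall import PermParams, call_significant, regions_from_genes
from .simdata import (
    ConfigError,
    SimConfig,
    align_synthetic,
    build_reference,
    simulate_reads,
    write_fastq,
    write_reference,
)
from .trna_consensus import build_consensus, infer_methylated_base, project_sites
from .xlink import extract_crosslinks, write_tracks

log = logging.getLogger("ficcseq")

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {f.name: None for f in dataclasses.fields(SimConfig)},
    "call": {"n_perm": 100, "alpha": 0.05},
    "peaks": {f.name: None for f in dataclasses.fields(RefineParams)},
    "motif": {"k": 7, "n_shuffles": 100, "flank": 50},
}


def validate_config(config: dict) -> None:
    """Reject unknown keys, naming the offender."""
    for key, val in config.items():
        if key not in DEFAULT_CONFIG:
            raise ConfigError(f"unknown config key: {key!r}")
        if isinstance(DEFAULT_CONFIG[key], dict):
            for sub in val or {}:
                if sub not in DEFAULT_CONFIG[key]:
                    raise ConfigError(f"unknown config key: {key}.{sub}")


def load_config(path: str) -> dict:
    import yaml

    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    validate_config(config)
    return config


def _build_params(config: dict):
    seed = int(config.get("seed", 0))
    sim_kwargs = {k: v for k, v in (config.get("simulate") or {}).items() if v is not None}
    sim_kwargs.setdefault("seed", seed)
    sim = SimConfig(**sim_kwargs)
    call_kwargs = {k: v for k, v in (config.get("call") or {}).items() if v is not None}
    call_kwargs.setdefault("seed", seed + 1)
    perm = PermParams(**call_kwargs)
    peak_kwargs = {k: v for k, v in (config.get("peaks") or {}).items() if v is not None}
    refine = RefineParams(**peak_kwargs)
    motif_kwargs = dict(DEFAULT_CONFIG["motif"])
    motif_kwargs.update(
        {k: v for k, v in (config.get("motif") or {}).items() if v is not None}
    )
    return seed, sim, perm, refine, motif_kwargs


def run_pipeline(config: dict, outdir: str) -> dict:
    """Execute every stage on a simulated dataset; return in-memory results.

    Each stage writes its report into ``outdir``; any stage failure raises
    with the stage name, leaving earlier outputs in place.
    """
    validate_config(config)
    seed, sim_cfg, perm, refine, motif_cfg = _build_params(config)
    perm.validate()
    refine.validate()
    os.makedirs(outdir, exist_ok=True)
    results: dict = {}

    def path(name: str) -> str:
        return os.path.join(outdir, name)

    stage = "simulate"
    try:
        ref = build_reference(sim_cfg)
        write_reference(ref, path("genome.fa"), path("genes.bed"), path("regions.tsv"))
        reads = simulate_reads(ref, sim_cfg)
        write_fastq(reads, path("reads.fastq"))
        reads.truth.to_csv(path("truth.tsv"), sep="\t", index=False)
        results.update(ref=ref, reads=reads, sim_cfg=sim_cfg)
        log.info("simulate: %d genes, %d FASTQ reads, %d unique cDNAs",
                 len(ref.genes), len(reads.fastq), len(reads.truth))

        stage = "demux"
        demux = demultiplex_trim(reads.fastq, sim_cfg.barcode_map, reads.layout)
        pd.Series(demux.counts).rename("n_reads").to_csv(path("demux_counts.tsv"), sep="\t")
        assigned = {
            tr.read_id
            for s, lst in demux.by_sample.items()
            if s in sim_cfg.barcode_map
            for tr in lst
        }
        results["demux"] = demux

        stage = "align"
        reads_assigned = dataclasses.replace(
            reads, placements=[p for p in reads.placements if p.read_id in assigned]
        )
        align_synthetic(reads_assigned, ref, path("aligned.sam"))

        stage = "dedup"
        cdnas = dedup(path("aligned.sam"))
        cdnas.to_csv(path("unique_cdnas.tsv"), sep="\t", index=False)
        results["cdnas"] = cdnas

        stage = "xlink"
        chrom_lengths = {c: len(s) for c, s in ref.genome.items()}
        sites, n_skipped = extract_crosslinks(cdnas, chrom_lengths)
        sites.to_csv(path("crosslink_sites.tsv"), sep="\t", index=False)
        write_tracks(sites, path("xlink"))
        results["sites"] = sites

        stage = "call"
        regions = regions_from_genes(ref.genes)
        called = call_significant(sites, regions, perm)
        called.to_csv(path("sites_fdr.tsv"), sep="\t", index=False)
        sig = called[called["significant"]]
        results["called"] = called

        stage = "peaks"
        rep_peaks = call_peaks(sig, refine)
        rep_peaks.to_csv(path("peaks_per_replicate.tsv"), sep="\t", index=False)
        final = merge_replicates(rep_peaks, refine.merge_tol)
        final.to_csv(path("final_clusters.tsv"), sep="\t", index=False)
        counts = count_clusters(final, cdnas)
        counts.to_csv(path("cluster_counts.tsv"), sep="\t")
        results.update(rep_peaks=rep_peaks, final=final, counts=counts)
        if counts.shape[1] >= 2 and not counts.empty:
            factors, norm = normalize_counts(counts, refine.min_total)
            factors.rename("size_factor").to_csv(path("size_factors.tsv"), sep="\t")
            norm.to_csv(path("normalized_counts.tsv"), sep="\t")
            corr = correlate(norm)
            corr.to_csv(path("correlation.tsv"), sep="\t")
            results.update(size_factors=factors, normalized=norm, correlation=corr)
        classes = annotate_peaks(final, ref.genes)
        classes.to_csv(path("peak_classes.tsv"), sep="\t", index=False)
        results["classes"] = classes

        stage = "consensus"
        model = build_consensus(ref.genes, ref.genome)
        pd.DataFrame(model.regions, columns=["region_name", "consensus_length"]).to_csv(
            path("consensus_regions.tsv"), sep="\t", index=False
        )
        prof_ann = project_sites(sig, ref.genes, model, mode="annotated_site")
        prof_ann.to_frame(model).to_csv(path("profile_annotated.tsv"), sep="\t", index=False)
        prof_meth = project_sites(sig, ref.genes, model, mode="inferred_methylation")
        prof_meth.to_frame(model).to_csv(path("profile_methylation.tsv"), sep="\t", index=False)
        results.update(model=model, profile_annotated=prof_ann, profile_methylation=prof_meth)

        stage = "motif"
        trna_peaks = final[final["final_id"].isin(
            annotate_with_class(final, ref.genes, "tRNA")
        )]
        motif_result = None
        if len(trna_peaks) >= 10:
            flanks = extract_flanks(trna_peaks, ref.genome, flank=motif_cfg["flank"])
            motif_result = discover_motif(
                flanks, k=motif_cfg["k"], n_shuffles=motif_cfg["n_shuffles"], seed=seed + 2
            )
            motif_result = filter_anchor(flanks, motif_result)
            with open(path("motif.tsv"), "w") as fh:
                fh.write("kmer\tshuffle_pvalue\tenrichment\tanchor_offset\tn_matches\tpwm_consensus\n")
                fh.write(
                    f"{motif_result.kmer}\t{motif_result.score}\t"
                    f"{motif_result.enrichment}\t{motif_result.anchor_offset}\t"
                    f"{motif_result.n_matches}\t"
                    f"{pwm_consensus(motif_result.pwm) if motif_result.pwm is not None else ''}\n"
                )
            if motif_result.pwm is not None:
                write_pwm(motif_result.pwm, path("motif_pwm.tsv"))
        results["motif"] = motif_result

        manifest = {
            "version": __version__,
            "seed": seed,
            "config": config,
            "stages": [
                "simulate", "demux", "align", "dedup", "xlink",
                "call", "peaks", "consensus", "motif",
            ],
        }
        with open(path("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage label
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results


def annotate_with_class(final: pd.DataFrame, genes, gene_class: str) -> set[str]:
    """IDs of final peaks whose representative position lies in a gene of the class."""
    out = set()
    for row in final.itertuples():
        for g in genes:
            if (
                g.gene_class == gene_class
                and g.chrom == row.chrom
                and g.strand == row.strand
                and g.start <= row.pos < g.end
            ):
                out.add(row.final_id)
                break
    return out


def major_sub_peaks(results: dict) -> pd.DataFrame:
    """Per-tRNA-gene major and sub-peak geometry from pipeline results.

    For each tRNA gene with at least two final peaks, reports the annotated
    consensus position of the major (highest-count) and secondary peaks,
    the inferred methylated base of the major peak (catalytic +1 rule) in
    consensus coordinates, and the consensus-coordinate distances.
    """
    ref = results["ref"]
    model = results["model"]
    final = results["final"]
    rows = []
    for gene in ref.genes:
        if gene.gene_class != "tRNA":
            continue
        sub = final[
            (final["chrom"] == gene.chrom)
            & (final["strand"] == gene.strand)
            & (final["pos"] >= gene.start)
            & (final["pos"] < gene.end)
        ].sort_values("total_count", ascending=False)
        if len(sub) < 2:
            continue
        major = sub.iloc[0]
        second = sub.iloc[1]

        def cons(gpos: int) -> int | None:
            m = gene.genomic_to_mature(gpos)
            if m is None:
                return None
            c = model.offset_map.get((gene.gene_id, m))
            return None if c is None else c + 1

        _g_meth, major_meth_cons = infer_methylated_base(
            int(major["pos"]), gene.strand, "catalytic", gene, model
        )
        major_ann = cons(int(major["pos"]))
        sub_ann = cons(int(second["pos"]))
        if None in (major_ann, sub_ann, major_meth_cons):
            continue
        rows.append(
            dict(
                gene_id=gene.gene_id,
                major_annotated_cons=major_ann,
                major_methylated_cons=major_meth_cons,
                sub_annotated_cons=sub_ann,
                dist_meth_to_sub=sub_ann - major_meth_cons,
                dist_annotated=sub_ann - major_ann,
            )
        )
    return pd.DataFrame(rows)
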