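"""Clustering, peak refinement, replicate merging, counting, normalization.

Significant crosslink sites are clustered by proximity, each cluster is
refined to its most over-represented positions (local maxima of the count
vector), per-replicate peaks are merged into a final cluster list, clusters
are counted from all overlapping unique cDNAs per replicate, and the count
matrix is size-factor normalized (median-of-ratios by default, total-count
ratios as the alternative) and compared via Pearson correlation of
log2(count+1) columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RefineParams",
    "cluster_sites",
    "refine_maxima",
    "call_peaks",
    "merge_replicates",
    "count_clusters",
    "normalize_counts",
    "correlate",
    "overlap_peaks",
    "annotate_peaks",
]


@dataclass
class RefineParams:
    max_gap: int = 15
    # 0.15 keeps the m1A-stall sub-peak (~0.19x the major peak under the
    # default 80/15 read-through/stall mix) above the eligibility floor
    rel_threshold: float = 0.15
    min_dist: int = 2
    merge_tol: int = 3
    min_count: int = 5  # minimum crosslink count for overlap comparisons
    min_total: int = 10  # pre-filter on summed cluster counts

    def validate(self) -> None:
        for name in ("max_gap", "min_dist", "merge_tol", "min_count", "min_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.rel_threshold <= 1:
            raise ValueError("rel_threshold must be in [0, 1]")


def cluster_sites(sites: pd.DataFrame, max_gap: int) -> pd.DataFrame:
    """Group same-strand sites within ``max_gap`` nt into clusters.

    Returns the input rows annotated with a ``cluster_id``; cluster
    intervals span the member sites.  Every site belongs to exactly one
    cluster (clustering is a partition).
    """
    if sites.empty:
        out = sites.copy()
        out["cluster_id"] = pd.Series(dtype=str)
        return out
    df = sites.sort_values(["chrom", "strand", "pos"]).reset_index(drop=True)
    ids = []
    n = 0
    prev = None
    for row in df.itertuples():
        key = (row.chrom, row.strand)
        if prev is None or key != prev[0] or row.pos - prev[1] > max_gap:
            n += 1
        ids.append(f"cl{n:05d}")
        prev = (key, row.pos)
    df["cluster_id"] = ids
    return df


def refine_maxima(
    positions: np.ndarray,
    counts: np.ndarray,
    rel_threshold: float,
    min_dist: int,
) -> list[int]:
    """Positions of local maxima of the cluster's count vector.

    Maxima are runs of equal counts higher than their flanks (leftmost
    position of a plateau reported), kept if their count is at least
    ``rel_threshold`` times the cluster maximum, then greedily selected in
    decreasing-count order (ties to the left) with at least ``min_dist`` nt
    separation.  The global maximum is always reported.  The result is
    invariant under uniform scaling of the counts.
    """
    positions = np.asarray(positions, dtype=int)
    counts = np.asarray(counts, dtype=float)
    if positions.size == 0:
        return []
    start, end = positions.min(), positions.max() + 1
    vec = np.zeros(end - start)
    vec[positions - start] = counts
    cmax = vec.max()
    if cmax <= 0:
        return []

    # candidate plateaus: value > neighbouring values on both sides
    cands = []
    i = 0
    L = len(vec)
    while i < L:
        j = i
        while j + 1 < L and vec[j + 1] == vec[i]:
            j += 1
        left_ok = i == 0 or vec[i - 1] < vec[i]
        right_ok = j == L - 1 or vec[j + 1] < vec[i]
        if vec[i] > 0 and left_ok and right_ok:
            cands.append((vec[i], i))
        i = j + 1

    cands = [c for c in cands if c[0] >= rel_threshold * cmax]
    cands.sort(key=lambda c: (-c[0], c[1]))
    chosen: list[int] = []
    for _val, idx in cands:
        if all(abs(idx - c) >= min_dist for c in chosen):
            chosen.append(idx)
    return sorted(start + i for i in chosen)


def call_peaks(sig_sites: pd.DataFrame, params: RefineParams) -> pd.DataFrame:
    """Cluster significant sites per sample and refine to peak positions.

    Returns one row per refined peak: sample, chrom, strand, pos, count
    (site count at the peak position), cluster_id and cluster interval.
    """
    params.validate()
    peaks = []
    if sig_sites.empty:
        return pd.DataFrame(
            columns=["sample", "chrom", "strand", "pos", "count", "cluster_id", "start", "end"]
        )
    for sample, sub in sig_sites.groupby("sample", sort=True):
        clustered = cluster_sites(sub, params.max_gap)
        for cid, grp in clustered.groupby("cluster_id", sort=True):
            pos = grp["pos"].to_numpy()
            cnt = grp["count"].to_numpy()
            maxima = refine_maxima(pos, cnt, params.rel_threshold, params.min_dist)
            lookup = dict(zip(pos.tolist(), cnt.tolist()))
            for m in maxima:
                peaks.append(
                    dict(
                        sample=sample,
                        chrom=grp["chrom"].iloc[0],
                        strand=grp["strand"].iloc[0],
                        pos=int(m),
                        count=int(lookup.get(m, 0)),
                        cluster_id=f"{sample}:{cid}",
                        start=int(pos.min()),
                        end=int(pos.max()) + 1,
                    )
                )
    return pd.DataFrame(peaks)


def _link_positions(positions: list[int], tol: int) -> list[list[int]]:
    """Single-linkage grouping of sorted positions with gap <= tol."""
    groups: list[list[int]] = []
    for p in sorted(positions):
        if groups and p - groups[-1][-1] <= tol:
            groups[-1].append(p)
        else:
            groups.append([p])
    return groups


def merge_replicates(peaks: pd.DataFrame, merge_tol: int) -> pd.DataFrame:
    """Merge per-replicate peaks into the final cluster list.

    Peaks within ``merge_tol`` nt on the same strand are unified; the
    representative position is the one with the largest count summed over
    replicates (ties to the left).  Provenance records which replicates
    contributed.  Commutative in replicate order.
    """
    if peaks.empty:
        return pd.DataFrame(
            columns=["final_id", "chrom", "strand", "start", "end", "pos", "replicates", "total_count"]
        )
    rows = []
    n = 0
    for (chrom, strand), sub in peaks.groupby(["chrom", "strand"], sort=True):
        for grp in _link_positions(sub["pos"].tolist(), merge_tol):
            members = sub[sub["pos"].isin(grp)]
            summed = members.groupby("pos")["count"].sum()
            rep_pos = int(summed[summed == summed.max()].index.min())
            n += 1
            rows.append(
                dict(
                    final_id=f"peak{n:05d}",
                    chrom=chrom,
                    strand=strand,
                    start=int(min(grp)),
                    end=int(max(grp)) + 1,
                    pos=rep_pos,
                    replicates=",".join(sorted(members["sample"].unique())),
                    total_count=int(members["count"].sum()),
                )
            )
    out = pd.DataFrame(rows).sort_values(["chrom", "strand", "start"]).reset_index(drop=True)
    out["final_id"] = [f"peak{i + 1:05d}" for i in range(len(out))]
    return out


def count_clusters(final: pd.DataFrame, cdnas: pd.DataFrame) -> pd.DataFrame:
    """Count, per replicate, unique cDNAs overlapping each final cluster.

    A cDNA counts for a cluster when its aligned interval [start, end)
    overlaps the cluster interval on the same strand (any overlap).
    Returns a cluster x replicate matrix.
    """
    samples = sorted(cdnas["sample"].unique()) if not cdnas.empty else []
    mat = pd.DataFrame(
        0, index=final["final_id"], columns=samples, dtype=int
    )
    if final.empty or cdnas.empty:
        return mat
    for (chrom, strand), sub in final.groupby(["chrom", "strand"], sort=True):
        reads = cdnas[(cdnas["chrom"] == chrom) & (cdnas["strand"] == strand)]
        if reads.empty:
            continue
        rs = reads["start"].to_numpy()
        re_ = reads["end"].to_numpy()
        rsample = reads["sample"].to_numpy()
        for row in sub.itertuples():
            hit = (rs < row.end) & (re_ > row.start)
            if hit.any():
                vals, cnts = np.unique(rsample[hit], return_counts=True)
                for s, c in zip(vals, cnts):
                    mat.loc[row.final_id, s] += int(c)
    return mat


def size_factors_median_of_ratios(matrix: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors.

    The pseudo-reference is the per-cluster geometric mean over samples,
    computed on clusters with all-positive counts; each sample's factor is
    the median ratio of its counts to the reference.
    """
    pos = matrix[(matrix > 0).all(axis=1)]
    if pos.empty:
        raise ValueError("no cluster with all-positive counts")
    arr = pos.to_numpy(dtype=float)
    gm = np.exp(np.log(arr).mean(axis=1, keepdims=True))
    factors = np.median(arr / gm, axis=0)
    return pd.Series(factors, index=matrix.columns)


def size_factors_total_count(matrix: pd.DataFrame) -> pd.Series:
    """Ratios of total reads per sample to the mean total."""
    totals = matrix.sum(axis=0).astype(float)
    return totals / totals.mean()


def normalize_counts(
    matrix: pd.DataFrame, min_total: int = 10, method: str = "median_of_ratios"
) -> tuple[pd.Series, pd.DataFrame]:
    """Pre-filter low-count clusters and size-factor normalize.

    Clusters whose summed count is below ``min_total`` are dropped before
    estimation.  ``method`` is ``median_of_ratios`` (default) or
    ``total_count``; if no cluster has all-positive counts the estimator
    falls back to total-count ratios with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("normalization needs >= 2 samples")
    kept = matrix[matrix.sum(axis=1) >= min_total]
    if method == "median_of_ratios":
        try:
            factors = size_factors_median_of_ratios(kept)
        except ValueError:
            import warnings

            warnings.warn(
                "no all-positive cluster; falling back to total-count size factors"
            )
            factors = size_factors_total_count(kept)
    elif method == "total_count":
        factors = size_factors_total_count(kept)
    else:
        raise ValueError(f"unknown size-factor method {method!r}")
    normalized = kept.div(factors, axis=1)
    return factors, normalized


def correlate(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of log2(count+1)-transformed columns.

    Zero-variance columns yield missing (NaN) correlations; the diagonal
    is 1 for well-defined columns.
    """
    if matrix.shape[1] < 2:
        raise ValueError("correlation needs >= 2 columns")
    log = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    cols = matrix.columns
    out = pd.DataFrame(np.nan, index=cols, columns=cols)
    sd = log.std(axis=0)
    for i in range(len(cols)):
        for j in range(len(cols)):
            if sd[i] == 0 or sd[j] == 0:
                continue
            out.iloc[i, j] = float(np.corrcoef(log[:, i], log[:, j])[0, 1])
    return out


def overlap_peaks(
    experiments: dict[str, pd.DataFrame],
    min_count: int = 5,
    merge_tol: int = 3,
    reference: str | None = None,
) -> tuple[dict[frozenset, int], float | None]:
    """Venn-style overlap of peak positions across experiments.

    Each experiment contributes peaks with count >= ``min_count``;
    positions on the same strand within ``merge_tol`` are matched.  Returns
    (subset counts keyed by the set of experiments sharing a matched
    position group, fraction of the reference experiment's peaks found in
    at least one other experiment).
    """
    if len(experiments) < 2:
        raise ValueError("overlap needs >= 2 experiments")
    pooled = []
    for name, df in experiments.items():
        count_col = "count" if "count" in df.columns else "total_count"
        sub = df[df[count_col] >= min_count]
        for row in sub.itertuples():
            pooled.append((row.chrom, row.strand, row.pos, name))
    venn: dict[frozenset, int] = {}
    ref_total = 0
    ref_shared = 0
    bykey: dict[tuple, list[tuple[int, str]]] = {}
    for chrom, strand, pos, name in pooled:
        bykey.setdefault((chrom, strand), []).append((pos, name))
    for items in bykey.values():
        items.sort()
        groups: list[list[tuple[int, str]]] = []
        for pos, name in items:
            if groups and pos - groups[-1][-1][0] <= merge_tol:
                groups[-1].append((pos, name))
            else:
                groups.append([(pos, name)])
        for grp in groups:
            present = frozenset(n for _, n in grp)
            venn[present] = venn.get(present, 0) + 1
            if reference is not None and reference in present:
                n_ref = sum(1 for _, n in grp if n == reference)
                ref_total += n_ref
                if len(present) > 1:
                    ref_shared += n_ref
    frac = (ref_shared / ref_total) if reference is not None and ref_total else (
        None if reference is None else 0.0
    )
    return venn, frac


def annotate_peaks(final: pd.DataFrame, genes) -> pd.DataFrame:
    """Per-class (tRNA / other) proportions of peaks and of their counts.

    Peaks outside every same-strand gene are classed "other".
    """
    classes = []
    for row in final.itertuples():
        cls = "other"
        for g in genes:
            if (
                g.chrom == row.chrom
                and g.strand == row.strand
                and g.start <= row.pos < g.end
            ):
                cls = g.gene_class
                break
        classes.append(cls)
    if final.empty:
        return pd.DataFrame(columns=["gene_class", "peak_fraction", "count_fraction"])
    df = final.copy()
    df["gene_class"] = classes
    total_peaks = len(df)
    total_counts = df["total_count"].sum()
    rows = []
    for cls, grp in df.groupby("gene_class"):
        rows.append(
            dict(
                gene_class=cls,
                peak_fraction=len(grp) / total_peaks,
                count_fraction=(
                    grp["total_count"].sum() / total_counts if total_counts else 0.0
                ),
            )
        )
    return pd.DataFrame(rows)
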