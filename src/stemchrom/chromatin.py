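"""Per-gene and metaprofile chromatin statistics from fragment intervals.

Coordinates are 0-based half-open genomic intervals; TSS-relative positions
are strand-oriented (upstream negative). A fragment contributes to a window
if the two intervals intersect by at least one base pair — the read-coverage
semantics of standard profiling tools — not by fragment midpoint, except in
the nucleosome-occupancy proxy where midpoints are the point of the method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

NUCLEOSOMAL_RANGE = (150, 250)


def add_tss(genes: pd.DataFrame) -> pd.DataFrame:
    """Annotate the strand-aware TSS (0-based position of the first
    transcribed base) on a gene table."""
    genes = genes.copy()
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    return genes


@dataclass
class TSSProfile:
    """Mean signal on a symmetric, strand-oriented grid around the TSS."""

    label: str
    positions: np.ndarray     # bp relative to TSS (bin centres), upstream negative
    values: np.ndarray

    def argmax_position(self) -> float:
        return float(self.positions[int(np.argmax(self.values))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "class": self.label,
                             "mean": self.values})


class _FragmentIndex:
    """Per-contig fragment intervals sorted by start, for overlap queries."""

    def __init__(self, fragments: pd.DataFrame):
        self.by_contig = {}
        for contig, sub in fragments.groupby("contig", sort=False):
            starts = sub["start"].to_numpy(np.int64)
            ends = sub["end"].to_numpy(np.int64)
            order = np.argsort(starts, kind="stable")
            self.by_contig[contig] = (starts[order], ends[order])
        self.n = len(fragments)

    def overlapping(self, contig, win_start, win_end):
        """Start/end arrays of fragments intersecting [win_start, win_end)."""
        if contig not in self.by_contig:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        starts, ends = self.by_contig[contig]
        hi = np.searchsorted(starts, win_end, side="left")
        s, e = starts[:hi], ends[:hi]
        keep = e > win_start
        return s[keep], e[keep]

    def count_overlaps(self, contig, win_starts, win_ends):
        """Number of fragments intersecting each window by >= 1 bp."""
        if contig not in self.by_contig:
            return np.zeros(len(win_starts), np.int64)
        starts, ends = self.by_contig[contig]
        ends_sorted = np.sort(ends)
        n_start_before_end = np.searchsorted(starts, win_ends, side="left")
        n_end_at_or_before_start = np.searchsorted(ends_sorted, win_starts, side="right")
        return n_start_before_end - n_end_at_or_before_start


def window_rpkm(fragments: pd.DataFrame, windows: pd.DataFrame,
                library_size: int) -> pd.Series:
    """Reads per kilobase per million for each window.

    RPKM = count * 1e9 / (window_bp * library_size); a fragment is counted
    if it overlaps the window by at least one base.
    """
    if library_size <= 0:
        raise ValueError("library size must be positive")
    index = _FragmentIndex(fragments)
    out = np.zeros(len(windows))
    widths = (windows["end"] - windows["start"]).to_numpy(float)
    for contig, sub in windows.groupby("contig", sort=False):
        counts = index.count_overlaps(contig, sub["start"].to_numpy(), sub["end"].to_numpy())
        out[windows.index.get_indexer(sub.index)] = counts
    values = out * 1e9 / (widths * library_size)
    name = windows["gene_id"] if "gene_id" in windows else windows.index
    return pd.Series(values, index=name, name="rpkm")


def tss_windows(genes: pd.DataFrame, upstream: int, downstream: int = 0) -> pd.DataFrame:
    """Strand-aware windows covering [TSS - upstream, TSS + downstream)."""
    genes = genes if "tss" in genes else add_tss(genes)
    plus = genes["strand"] == "+"
    start = np.where(plus, genes["tss"] - upstream, genes["tss"] - downstream + 1)
    end = np.where(plus, genes["tss"] + downstream, genes["tss"] + upstream + 1)
    return pd.DataFrame({"gene_id": genes["gene_id"], "contig": genes["contig"],
                         "start": np.clip(start, 0, None), "end": end})


def tss_metaprofile(fragments: pd.DataFrame, genes: pd.DataFrame,
                    half_width: int = 1000, bin: int = 10,
                    library_size: int | None = None,
                    label: str = "") -> TSSProfile:
    """Mean RPKM-scaled fragment coverage per bin over TSS +/- half_width.

    Minus-strand genes are flipped so upstream is negative for every gene.
    """
    genes = genes if "tss" in genes else add_tss(genes)
    lib = library_size if library_size is not None else len(fragments)
    if lib <= 0:
        raise ValueError("library size must be positive")
    index = _FragmentIndex(fragments)
    n_bins = (2 * half_width) // bin
    acc = np.zeros(n_bins)
    n_genes = 0
    for row in genes.itertuples(index=False):
        w0, w1 = row.tss - half_width, row.tss + half_width
        if w0 < 0:
            warnings.warn(f"window for {row.gene_id} truncated at contig edge")
        s, e = index.overlapping(row.contig, max(w0, 0), w1)
        diff = np.zeros(n_bins + 1)
        if s.size:
            b0 = np.clip((s - w0) // bin, 0, n_bins - 1)
            b1 = np.clip((e - 1 - w0) // bin, 0, n_bins - 1)
            np.add.at(diff, b0, 1.0)
            np.add.at(diff, b1 + 1, -1.0)
        cov = np.cumsum(diff[:-1])
        if row.strand == "-":
            cov = cov[::-1]
        acc += cov
        n_genes += 1
    if n_genes == 0:
        raise ValueError("no genes supplied")
    values = acc / n_genes * 1e9 / (bin * lib)
    positions = np.arange(n_bins) * bin - half_width + bin / 2.0
    return TSSProfile(label=label, positions=positions, values=values)


def per_gene_profile_argmax(fragments: pd.DataFrame, genes: pd.DataFrame,
                            half_width: int = 1000, bin: int = 10) -> pd.Series:
    """TSS-relative position of each gene's own coverage maximum.

    Same binning and strand handling as :func:`tss_metaprofile`, computed
    per gene (ties resolve to the most upstream bin via argmax).
    """
    genes = genes if "tss" in genes else add_tss(genes)
    index = _FragmentIndex(fragments)
    n_bins = (2 * half_width) // bin
    centres = np.arange(n_bins) * bin - half_width + bin / 2.0
    out = {}
    for row in genes.itertuples(index=False):
        w0, w1 = row.tss - half_width, row.tss + half_width
        s, e = index.overlapping(row.contig, max(w0, 0), w1)
        diff = np.zeros(n_bins + 1)
        if s.size:
            b0 = np.clip((s - w0) // bin, 0, n_bins - 1)
            b1 = np.clip((e - 1 - w0) // bin, 0, n_bins - 1)
            np.add.at(diff, b0, 1.0)
            np.add.at(diff, b1 + 1, -1.0)
        cov = np.cumsum(diff[:-1])
        if row.strand == "-":
            cov = cov[::-1]
        out[row.gene_id] = float(centres[int(np.argmax(cov))])
    return pd.Series(out, name="argmax_position")


def atac_h3k4_ratio(atac_rpkm: pd.Series, k4_rpkm: pd.Series,
                    pseudocount: float = 1.0) -> pd.Series:
    """Per-gene log2((ATAC + pc) / (H3K4me3 + pc)) on matched TSS windows."""
    if (atac_rpkm < 0).any() or (k4_rpkm < 0).any():
        raise ValueError("RPKM values must be non-negative")
    a, k = atac_rpkm.align(k4_rpkm, join="inner")
    return np.log2((a + pseudocount) / (k + pseudocount)).rename("log2_atac_h3k4")


def consensus_peaks(replicate_peaksets: list[pd.DataFrame], min_neg_log10_p: float = 4.0,
                    n_replicates: int = 3) -> pd.DataFrame:
    """Replicate-conserved peaks.

    Overlapping (>= 1 bp, single linkage) peaks are pooled; a pooled cluster
    becomes a consensus peak — spanning the union of its members — only if
    every replicate contributes at least one peak and every member has
    -log10(P) strictly greater than the cutoff.
    """
    if len(replicate_peaksets) != n_replicates:
        raise ValueError(f"expected {n_replicates} replicate peak sets")
    empty = pd.DataFrame(columns=["contig", "start", "end", "neg_log10_p"])
    if any(p.empty for p in replicate_peaksets):
        return empty  # a peak absent from any replicate cannot be conserved
    pooled = []
    for rep, peaks in enumerate(replicate_peaksets):
        p = peaks.copy()
        p["replicate"] = rep
        pooled.append(p)
    pooled = pd.concat(pooled, ignore_index=True)

    out = []
    for contig, sub in pooled.groupby("contig", sort=False):
        sub = sub.sort_values("start", kind="stable")
        cluster_end = -1
        members = []

        def flush(members):
            if not members:
                return
            m = pd.DataFrame(members)
            if (m["replicate"].nunique() == n_replicates
                    and (m["neg_log10_p"] > min_neg_log10_p).all()):
                out.append({"contig": contig, "start": int(m["start"].min()),
                            "end": int(m["end"].max()),
                            "neg_log10_p": float(m["neg_log10_p"].min())})

        for row in sub.itertuples(index=False):
            if members and row.start >= cluster_end:
                flush(members)
                members = []
            members.append({"start": row.start, "end": row.end,
                            "neg_log10_p": row.neg_log10_p, "replicate": row.replicate})
            cluster_end = max(cluster_end, row.end)
        flush(members)
    return pd.DataFrame(out, columns=["contig", "start", "end", "neg_log10_p"])


FEATURE_PRIORITY = ("promoter", "exon", "intron", "TE", "intergenic")


def assign_feature(peaks: pd.DataFrame, genes: pd.DataFrame, repeats: pd.DataFrame,
                   exons: pd.DataFrame | None = None, promoter_bp: int = 2000,
                   contig_sizes: dict | None = None) -> pd.Series:
    """Assign each peak summit to promoter > exon > intron > TE > intergenic.

    The promoter is the strand-aware [TSS - promoter_bp, TSS) window. With no
    exon table the whole gene span counts as exon (single-exon models).
    """
    genes = genes if "tss" in genes else add_tss(genes)
    summits = peaks["start"].to_numpy() + peaks["summit"].to_numpy()
    if contig_sizes is not None:
        sizes = peaks["contig"].map(contig_sizes).to_numpy()
        if (summits < 0).any() or (summits >= sizes).any():
            raise ValueError("peak summit outside contig bounds")

    prom = tss_windows(genes, upstream=promoter_bp, downstream=0)
    if exons is None:
        exons = genes[["contig", "start", "end"]]
    spans = genes[["contig", "start", "end"]]

    def member(intervals: pd.DataFrame) -> np.ndarray:
        hit = np.zeros(len(peaks), bool)
        for contig, sub in intervals.groupby("contig", sort=False):
            mask = peaks["contig"].to_numpy() == contig
            if not mask.any():
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], np.maximum.accumulate(ends[order])
            idx = np.searchsorted(starts, summits[mask], side="right") - 1
            ok = idx >= 0
            ok[ok] = summits[mask][ok] < ends[idx[ok]]
            hit[mask] = ok
        return hit

    in_prom = member(prom)
    in_exon = member(exons)
    in_gene = member(spans)
    in_te = member(repeats) if len(repeats) else np.zeros(len(peaks), bool)

    cat = np.full(len(peaks), "intergenic", dtype=object)
    cat[in_te] = "TE"
    cat[in_gene & ~in_exon] = "intron"
    cat[in_exon] = "exon"
    cat[in_prom] = "promoter"
    return pd.Series(cat, index=peaks.index, name="feature")


def max_signal_region(coverage_positions: np.ndarray, coverage_rpkm: np.ndarray,
                      min_rpkm: float = 10.0):
    """Argmax bin of RPKM-scaled coverage in the 2-kb promoter.

    ``coverage_positions`` are TSS-relative bin positions (upstream negative,
    restricted to [-2000, 0)); ties are broken toward the TSS. Returns
    (position, value) or None when the maximum does not exceed ``min_rpkm``.
    """
    pos = np.asarray(coverage_positions, float)
    val = np.asarray(coverage_rpkm, float)
    sel = (pos >= -2000) & (pos < 0)
    pos, val = pos[sel], val[sel]
    if not len(val):
        return None
    best = val.max()
    if best <= min_rpkm:
        return None
    candidates = pos[val == best]
    return float(candidates.max()), float(best)


def nucleosome_occupancy(fragments: pd.DataFrame, genes: pd.DataFrame,
                         half_width: int = 1000, smooth_sigma: float = 20.0,
                         flank: tuple = (800, 1000), label: str = "") -> TSSProfile:
    """Nucleosome-occupancy proxy from nucleosome-sized fragment midpoints.

    Midpoint density of fragments with length in [150, 250] is accumulated
    at 1-bp resolution around the TSS (strand-oriented), Gaussian-smoothed
    (sigma = 20 bp), and normalised to the mean over the |position| in
    [800, 1000] flanks.
    """
    genes = genes if "tss" in genes else add_tss(genes)
    lens = fragments["end"] - fragments["start"]
    nuc = fragments[(lens >= NUCLEOSOMAL_RANGE[0]) & (lens <= NUCLEOSOMAL_RANGE[1])]
    index = _FragmentIndex(nuc)
    n_pos = 2 * half_width + 1
    density = np.zeros(n_pos)
    for row in genes.itertuples(index=False):
        w0, w1 = row.tss - half_width - 300, row.tss + half_width + 300
        s, e = index.overlapping(row.contig, max(w0, 0), w1)
        mid = (s + e) // 2
        rel = mid - row.tss
        if row.strand == "-":
            rel = -rel
        rel = rel[(rel >= -half_width) & (rel <= half_width)]
        np.add.at(density, rel + half_width, 1.0)
    positions = np.arange(-half_width, half_width + 1, dtype=float)
    if density.sum() == 0:
        warnings.warn("no nucleosome-sized fragments; returning all-zero profile")
        return TSSProfile(label=label, positions=positions, values=density)
    smooth = gaussian_filter1d(density, smooth_sigma, mode="mirror")
    in_flank = (np.abs(positions) >= flank[0]) & (np.abs(positions) <= flank[1])
    norm = smooth[in_flank].mean()
    if norm == 0:
        warnings.warn("empty flanks; profile left unnormalised")
        norm = 1.0
    return TSSProfile(label=label, positions=positions, values=smooth / norm)


def profile_modes(profile: TSSProfile, sides=((-400, -20), (20, 400))) -> list[float]:
    """Positions of the maxima on each requested position range."""
    modes = []
    for lo, hi in sides:
        sel = (profile.positions >= lo) & (profile.positions <= hi)
        idx = np.argmax(profile.values[sel])
        modes.append(float(profile.positions[sel][idx]))
    return modes
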