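"""A/B compartment calling with white-strip correction.

The compartment signal is the leading eigenvector of the Pearson correlation
matrix of the observed/expected contact matrix, computed after removing
low-coverage rows/columns ("white strips") and balancing, then reallocated
to the original bin coordinates with NA at the dropped bins. Eigenvectors
are computed independently per contig, with the sign oriented so that the
positive (A) side has the higher chromatin accessibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts for one contig."""

    bin_size: int
    bins: pd.DataFrame        # contig, start (bp) per bin
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        if (m < 0).any():
            raise ValueError("contact counts must be non-negative")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def write(self, contacts_path, bins_path) -> None:
        from . import io as sio

        sio.write_contacts_coo(self.matrix, contacts_path)
        self.bins.to_csv(bins_path, sep="\t", index=False)


@dataclass
class CompartmentTrack:
    """Signed eigenvector values and A/B labels per original bin."""

    eigenvector: np.ndarray   # NaN at dropped bins
    labels: np.ndarray        # 'A' / 'B' / 'NA'
    bins: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_bedgraph(self, bin_size: int) -> pd.DataFrame:
        out = self.bins.copy()
        out["end"] = out["start"] + bin_size
        out["value"] = self.eigenvector
        return out[["contig", "start", "end", "value"]]


def kr_balance(matrix: np.ndarray, tol: float = 1e-6, max_iter: int = 3000):
    """Knight-Ruiz-style matrix balancing by symmetric diagonal scaling.

    Iterates d <- d / sqrt(rowsum(D M D)) until the coefficient of variation
    of the balanced row sums is below ``tol``. Returns (balanced, scaling).
    Zero rows must be removed beforehand (see :func:`drop_white_strips`).
    """
    m = np.asarray(matrix, float)
    if not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("matrix must be symmetric")
    rowsums = m.sum(axis=1)
    if (rowsums <= 0).any():
        raise ValueError("zero rows must be dropped before balancing")
    n = m.shape[0]
    d = 1.0 / np.sqrt(rowsums)
    for it in range(max_iter):
        r = d * (m @ d)               # row sums of diag(d) M diag(d)
        cv = r.std() / r.mean()
        if cv < tol:
            balanced = m * np.outer(d, d)
            # normalise so row sums average 1
            scale = np.sqrt(r.mean())
            return balanced / r.mean(), d / scale
        d = d / np.sqrt(r)
    raise RuntimeError(f"KR balancing did not converge in {max_iter} iterations")


def drop_white_strips(matrix: np.ndarray, min_coverage_frac: float = 0.05):
    """Remove low-coverage rows/columns.

    A bin is a white strip if its row sum is zero or below
    ``min_coverage_frac`` times the median nonzero row sum. Returns
    (reduced matrix, index map from reduced to original coordinates).
    """
    m = np.asarray(matrix, float)
    if not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("matrix must be symmetric")
    rowsums = m.sum(axis=1)
    nonzero = rowsums[rowsums > 0]
    if not len(nonzero):
        raise ValueError("all bins have zero coverage")
    threshold = min_coverage_frac * np.median(nonzero)
    keep = rowsums >= threshold
    keep &= rowsums > 0
    if not keep.any():
        raise ValueError("all bins dropped as white strips")
    index_map = np.nonzero(keep)[0]
    return m[np.ix_(index_map, index_map)], index_map


def observed_over_expected(balanced: np.ndarray,
                           distances: np.ndarray | None = None) -> np.ndarray:
    """Divide each entry by the mean of its distance diagonal.

    By default the distance is the matrix-index separation |i-j|; a genomic
    bin-distance matrix may be supplied instead (so the result does not
    depend on row order). Diagonals with zero mean are flagged and their
    entries set to 0.
    """
    m = np.asarray(balanced, float)
    n = m.shape[0]
    if distances is None:
        idx = np.arange(n)
        distances = np.abs(np.subtract.outer(idx, idx))
    oe = np.zeros_like(m)
    flagged = []
    for d in np.unique(distances):
        sel = distances == d
        mean = m[sel].mean()
        if mean == 0:
            flagged.append(d)
            continue
        oe[sel] = m[sel] / mean
    if flagged:
        warnings.warn(f"zero-mean diagonal(s) {flagged[:5]}... set to 0")
    return oe


def compartment_eigenvector(oe_reduced: np.ndarray, index_map: np.ndarray,
                            n_bins: int | None = None,
                            bins: pd.DataFrame | None = None) -> CompartmentTrack:
    """Leading eigenvector of the Pearson correlation matrix of O/E rows,
    reallocated to original bin coordinates (NaN / 'NA' at dropped bins)."""
    oe = np.asarray(oe_reduced, float)
    if np.any(oe.std(axis=1) == 0):
        raise ValueError("degenerate correlation matrix: constant O/E row(s)")
    corr = np.corrcoef(oe)
    if not np.all(np.isfinite(corr)):
        raise ValueError("degenerate correlation matrix")
    eigvals, eigvecs = np.linalg.eigh(corr)
    ev = eigvecs[:, -1]

    total = n_bins if n_bins is not None else (int(index_map.max()) + 1 if len(index_map) else 0)
    if bins is not None:
        total = len(bins)
    full = np.full(total, np.nan)
    full[index_map] = ev
    labels = np.where(np.isnan(full), "NA", np.where(full >= 0, "A", "B"))
    return CompartmentTrack(eigenvector=full, labels=labels,
                            bins=bins if bins is not None else pd.DataFrame(
                                {"contig": "na", "start": np.arange(total)}))


def call_compartments(contacts: ContactMatrix, min_coverage_frac: float = 0.05,
                      tol: float = 1e-6) -> tuple[CompartmentTrack, np.ndarray]:
    """White-strip removal -> KR balancing -> O/E -> correlation eigenvector,
    reallocated to the original bins. Returns (track, dropped bin indices)."""
    reduced, index_map = drop_white_strips(contacts.matrix, min_coverage_frac)
    balanced, _ = kr_balance(reduced, tol=tol)
    # genomic bin distance, so the call is equivariant under bin reordering
    starts = contacts.bins["start"].to_numpy()[index_map]
    dist = np.abs(np.subtract.outer(starts, starts)) // contacts.bin_size
    oe = observed_over_expected(balanced, distances=dist)
    track = compartment_eigenvector(oe, index_map, bins=contacts.bins)
    dropped = np.setdiff1d(np.arange(contacts.n_bins), index_map)
    return track, dropped


def orient_and_enrich(track: CompartmentTrack, accessibility: np.ndarray,
                      feature_bins: pd.DataFrame | None = None,
                      gene_bins: np.ndarray | None = None):
    """Fix the eigenvector sign so A (positive) is the more accessible side,
    then compute per-feature-family compartment enrichment.

    ``accessibility`` is a per-original-bin signal (NaN allowed at strips).
    ``feature_bins``: columns family, bin, bases — how many bases of each
    feature family fall in each bin. Enrichment of family f in compartment C
    is (fraction of f's bases in C) / (fraction of labeled bins in C), so a
    uniformly distributed family scores 1.0 in both compartments.
    """
    acc = np.asarray(accessibility, float)
    ev = track.eigenvector.copy()
    informative = ~np.isnan(ev)
    usable = informative & ~np.isnan(acc)
    if usable.sum() < 0.5 * informative.sum():
        if gene_bins is None:
            raise ValueError("accessibility missing for >50% of retained bins "
                             "and no gene density available as fallback")
        warnings.warn("orienting by gene density: accessibility too sparse")
        acc = np.asarray(gene_bins, float)
        usable = informative & ~np.isnan(acc)

    pos = usable & (ev >= 0)
    neg = usable & (ev < 0)
    if neg.any() and pos.any() and acc[neg].mean() > acc[pos].mean():
        ev = -ev
    labels = np.where(np.isnan(ev), "NA", np.where(ev >= 0, "A", "B"))
    oriented = CompartmentTrack(eigenvector=ev, labels=labels, bins=track.bins)

    enrichment = None
    if feature_bins is not None and len(feature_bins):
        lab = pd.Series(labels)
        share = {c: (lab == c).sum() / (lab != "NA").sum() for c in ("A", "B")}
        rows = []
        for family, sub in feature_bins.groupby("family", sort=True):
            bin_lab = lab.reindex(sub["bin"]).to_numpy()
            total = sub["bases"].sum()
            for c in ("A", "B"):
                frac = sub.loc[bin_lab == c, "bases"].sum() / total if total else np.nan
                rows.append({"family": family, "compartment": c,
                             "enrichment": frac / share[c] if share[c] else np.nan})
        enrichment = pd.DataFrame(rows)
    return oriented, enrichment
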