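"""Synthetic planarian-style datasets with planted ground truth.

Every generator in this module emulates one input of the analysis pipeline:
a genome with three promoter architectures, replicated expression counts,
ATAC / H3K4me3 fragment sets, checkerboard Hi-C contact matrices with
low-coverage "white strips", and calibrated image stacks of cell colonies.
The planted truth (gene classes, motif positions, compartment labels, colony
membership) is returned alongside so downstream recovery is checkable.

Promoter architectures
----------------------
* tissue-specific genes (brain / epidermis / intestine): a transcription
  factor motif planted in [-300, -100] relative to the TSS, AT/TA
  trinucleotide tandem repeats further upstream, and — in the fragment
  generator — a short-fragment accessibility peak around -200 bp present
  only in the matching cell isolation.
* stem-cell (neoblast) and constitutive genes: promoter [-250, 0) redrawn
  at high AT content with a T bias, at least two poly(dT) runs planted in
  [-200, 0), an Initiator-like motif at the TSS, mild TSS-centred
  accessibility, and nucleosome-sized fragments phased at -180 / +120 bp.
* unclassified genes: background sequence, background coverage, weak
  expression.

All randomness is drawn from ``numpy`` generators seeded from
``(plan.seed, stage tag)``, so an identical plan yields byte-identical
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio

CLASSES = ("brain", "epidermis", "intestine", "neoblast", "constitutive", "unclassified")
ISOLATIONS = ("brain", "epidermis", "intestine", "pharynx", "neoblast")
TISSUE_CLASSES = ("brain", "epidermis", "intestine")

TE_FAMILIES = ("Burro", "Gypsy", "Polinton", "Mariner", "hAT")

# planted fragment architecture (bp relative to TSS)
TISSUE_PEAK_CENTER = -200
NUCLEOSOME_MINUS1 = -180
NUCLEOSOME_PLUS1 = 120

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# consensus strings of the shipped PWM fixtures (data/core_motifs.meme)
TF_CONSENSUS = "CACGTGAC"
INR_CONSENSUS = "TCAGTCTT"

_UP_PAD = 2600       # promoter + composition window upstream of the TSS
_DOWN_PAD = 200
_GENES_PER_CONTIG = 40


@dataclass(frozen=True)
class SimulationPlan:
    """Study conditions for all generators.

    Defaults follow the emulation targets: ~70% genome AT content, >90% AT
    with T bias in constitutive/stem promoters, fourfold expression
    enrichment of class genes in their isolation, 50-kb Hi-C bins and
    20x-objective voxel calibration.
    """

    seed: int = 0
    n_genes_per_class: dict = field(default_factory=lambda: {
        "brain": 150, "epidermis": 150, "intestine": 150,
        "neoblast": 150, "constitutive": 200, "unclassified": 200,
    })
    genome_at_fraction: float = 0.70
    promoter_at_fraction_constitutive: float = 0.92
    tss_window_bp: int = 2000
    fragment_depth: int = 200_000
    nb_dispersion: float = 0.1
    fold_change: float = 4.0
    hic_bins: int = 100
    strip_fraction: float = 0.10
    image_voxel_um: tuple = (1.38, 1.38, 7.0)

    def validate(self) -> "SimulationPlan":
        for name in ("genome_at_fraction", "promoter_at_fraction_constitutive", "strip_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(n < 0 for n in self.n_genes_per_class.values()):
            raise ValueError("gene counts must be non-negative")
        if sum(self.n_genes_per_class.values()) <= 0:
            raise ValueError("at least one gene must be requested")
        unknown = set(self.n_genes_per_class) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")
        if self.nb_dispersion < 0 or self.fold_change <= 0:
            raise ValueError("nb_dispersion must be >= 0 and fold_change > 0")
        if self.fragment_depth < 0 or self.tss_window_bp <= 0:
            raise ValueError("fragment_depth must be >= 0 and tss_window_bp > 0")
        if any(v <= 0 for v in self.image_voxel_um):
            raise ValueError("voxel sizes must be positive")
        return self

    def with_seed(self, seed: int) -> "SimulationPlan":
        return replace(self, seed=int(seed))


@dataclass
class GroundTruth:
    """Planted truth; generators fill the fields they own."""

    gene_classes: pd.Series | None = None          # gene_id -> class
    gene_lengths: pd.Series | None = None          # gene_id -> body length (bp)
    motifs: pd.DataFrame | None = None             # planted motif/poly-dT positions
    bin_labels: pd.Series | None = None            # Hi-C bin -> 'A' / 'B'
    bin_accessibility: np.ndarray | None = None    # per-bin accessibility proxy
    strip_bins: np.ndarray | None = None           # indices of planted white strips
    colony_labels: np.ndarray | None = None        # planted object -> colony id


@dataclass
class GenomeBundle:
    sequences: dict
    genes: pd.DataFrame       # gene_id contig start end strand tss (0-based)
    repeats: pd.DataFrame     # contig start end family

    def contig_sizes(self) -> dict:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.write_fasta(self.sequences, outdir / "genome.fa")
        sio.write_gff3(self.genes, outdir / "genes.gff3")
        sio.write_bed(self.repeats, outdir / "repeats.bed",
                      columns=["contig", "start", "end", "family"])


def _rng(plan: SimulationPlan, tag: int) -> np.random.Generator:
    return np.random.default_rng([plan.seed, tag])


def _random_codes(rng, n, at_fraction, t_bias=0.5):
    """i.i.d. bases as uint8 codes; ``t_bias`` is T's share of the AT mass."""
    at = at_fraction
    p = np.array([at * (1 - t_bias), (1 - at) / 2, (1 - at) / 2, at * t_bias])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _str_to_codes(s: str) -> np.ndarray:
    return np.array([_CODE[c] for c in s], dtype=np.uint8)


_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def rel_to_genomic(tss: int, strand: str, rel_start: int, rel_end: int) -> tuple[int, int]:
    """Map a TSS-relative half-open interval to genomic coordinates.

    Relative coordinates are on the coding strand with the TSS base at 0;
    upstream positions are negative.
    """
    if strand == "+":
        return tss + rel_start, tss + rel_end
    return tss - rel_end + 1, tss - rel_start + 1


def generate_genome(plan: SimulationPlan) -> tuple[GenomeBundle, GroundTruth]:
    """Lay out genes sequentially (which guarantees non-overlap) and plant
    the class-specific promoter sequence features."""
    plan.validate()
    rng = _rng(plan, 1)

    labels = [c for c in CLASSES for _ in range(plan.n_genes_per_class.get(c, 0))]
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    n_genes = len(labels)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    at = plan.genome_at_fraction
    atp = plan.promoter_at_fraction_constitutive
    tri_units = ["AAT", "ATA", "TAA", "ATT", "TTA", "TAT"]
    tf = _str_to_codes(TF_CONSENSUS)
    inr = _str_to_codes(INR_CONSENSUS)

    sequences: dict[str, str] = {}
    gene_rows, repeat_rows, motif_rows = [], [], []

    contig_parts: list[np.ndarray] = []
    pos = 0
    contig_idx = 0

    def flush_contig():
        nonlocal contig_parts, pos, contig_idx
        if contig_parts:
            name = f"chr{contig_idx + 1}"
            sequences[name] = _codes_to_str(np.concatenate(contig_parts))
            contig_parts = []
            pos = 0
            contig_idx += 1

    for gi, (gid, cls) in enumerate(zip(gene_ids, labels)):
        contig = f"chr{contig_idx + 1}"
        # spacer, occasionally carrying a transposable-element copy
        spacer_len = int(rng.integers(400, 1200))
        spacer = _random_codes(rng, spacer_len, at)
        if rng.random() < 0.5 and spacer_len > 300:
            te_len = int(rng.integers(150, min(500, spacer_len - 50)))
            te_off = int(rng.integers(0, spacer_len - te_len))
            repeat_rows.append((contig, pos + te_off, pos + te_off + te_len,
                                str(rng.choice(TE_FAMILIES))))
        contig_parts.append(spacer)
        pos += spacer_len

        body = int(rng.integers(600, 3001))
        locus_len = _UP_PAD + body + _DOWN_PAD
        locus = _random_codes(rng, locus_len, at)
        strand = "+" if gi % 2 == 0 else "-"
        planted = []  # (motif name, rel_start, rel_end)

        def plant(codes, rel_start, name):
            locus[_UP_PAD + rel_start:_UP_PAD + rel_start + len(codes)] = codes
            planted.append((name, rel_start, rel_start + len(codes)))

        if cls in ("constitutive", "neoblast"):
            # AT-rich T-biased promoter with poly(dT) tracts and an Inr at the TSS
            locus[_UP_PAD - 250:_UP_PAD] = _random_codes(rng, 250, atp, t_bias=0.62)
            n_runs = int(rng.integers(2, 4))
            taken: list[tuple[int, int]] = []
            while len(taken) < n_runs:
                run = int(rng.integers(6, 10))
                start = int(rng.integers(-200, -10 - run))
                if all(start + run + 2 < s or start > e + 2 for s, e in taken):
                    plant(np.full(run, _CODE["T"], dtype=np.uint8), start, "polyT")
                    taken.append((start, start + run))
            plant(inr, -2, "INR")
        elif cls in TISSUE_CLASSES:
            tf_start = int(rng.integers(-300, -100 - len(tf) + 1))
            plant(tf, tf_start, "TF8")
            unit = _str_to_codes(str(rng.choice(tri_units)))
            n_units = int(rng.integers(4, 8))
            arr_start = int(rng.integers(-500, -330 - 3 * n_units))
            plant(np.tile(unit, n_units), arr_start, "AT_tandem")
            if rng.random() < 0.10:
                plant(inr, -2, "INR")

        if strand == "+":
            tss = pos + _UP_PAD
            g_start, g_end = tss, tss + body
            contig_parts.append(locus)
        else:
            tss = pos + locus_len - 1 - _UP_PAD
            g_start, g_end = pos + locus_len - _UP_PAD - body, pos + locus_len - _UP_PAD
            contig_parts.append(_revcomp_codes(locus))
        pos += locus_len

        gene_rows.append((gid, contig, g_start, g_end, strand, tss, body))
        for name, a, b in planted:
            ga, gb = rel_to_genomic(tss, strand, a, b)
            motif_rows.append((gid, name, a, contig, ga, gb, strand))

        if (gi + 1) % _GENES_PER_CONTIG == 0:
            contig_parts.append(_random_codes(rng, 500, at))
            flush_contig()
    if contig_parts:
        contig_parts.append(_random_codes(rng, 500, at))
        flush_contig()

    genes = pd.DataFrame(gene_rows, columns=["gene_id", "contig", "start", "end",
                                             "strand", "tss", "body_length"])
    repeats = pd.DataFrame(repeat_rows, columns=["contig", "start", "end", "family"])
    motifs = pd.DataFrame(motif_rows, columns=["gene_id", "motif", "rel_start",
                                               "contig", "start", "end", "strand"])
    truth = GroundTruth(
        gene_classes=pd.Series(labels, index=gene_ids, name="class"),
        gene_lengths=genes.set_index("gene_id")["body_length"],
        motifs=motifs,
    )
    return GenomeBundle(sequences, genes, repeats), truth


# ---------------------------------------------------------------------------
# Expression counts


def generate_counts(plan: SimulationPlan, truth: GroundTruth):
    """Negative-binomial counts, 3 replicates x 5 isolations.

    Class genes are ``plan.fold_change`` times higher in their own isolation;
    constitutive genes have equal means everywhere (high expression),
    unclassified genes have equal means everywhere (weak expression).
    """
    from .expression import CountMatrix

    plan.validate()
    if truth.gene_classes is None:
        raise ValueError("truth must carry gene class labels")
    rng = _rng(plan, 2)
    classes = truth.gene_classes
    gene_ids = classes.index.to_numpy()
    n = len(gene_ids)

    if truth.gene_lengths is not None:
        lengths = truth.gene_lengths.reindex(gene_ids).to_numpy()
    else:
        lengths = rng.integers(600, 3001, n)

    base = np.where(classes.to_numpy() == "constitutive", 150.0,
                    np.where(classes.to_numpy() == "unclassified", 0.3, 60.0))
    base = base * rng.lognormal(0.0, 0.4, n)

    samples = []
    cols = {}
    for iso in ISOLATIONS:
        mu = base * np.where(classes.to_numpy() == iso, plan.fold_change, 1.0)
        mu = mu * lengths / 1000.0
        for rep in range(1, 4):
            name = f"{iso}_r{rep}"
            cols[name] = _nb_draw(rng, mu, plan.nb_dispersion)
            samples.append((name, iso, rep))

    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    sample_sheet = pd.DataFrame(samples, columns=["sample", "isolation", "replicate"])
    return CountMatrix(counts=counts,
                       lengths=pd.Series(lengths, index=counts.index, name="length"),
                       samples=sample_sheet)


def _nb_draw(rng, mu, dispersion):
    if dispersion < 1e-12:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + np.asarray(mu, float)))


# ---------------------------------------------------------------------------
# Chromatin fragments


@dataclass
class FragmentSet:
    """0-based half-open fragment intervals with a sample (isolation) label."""

    fragments: pd.DataFrame   # contig start end sample
    assay: str

    def for_sample(self, sample: str) -> pd.DataFrame:
        return self.fragments[self.fragments["sample"] == sample]

    def library_sizes(self) -> pd.Series:
        return self.fragments.groupby("sample").size()

    def write(self, path) -> None:
        sio.write_fragments(self.fragments, path)


# per-promoter Poisson rates of the class templates (fragments per gene)
_ATAC_TISSUE_SHORT = 45.0
_ATAC_STEM_SHORT = 50.0
_ATAC_STEM_NUC = 20.0
_ATAC_BASELINE = 2.0
_K4_ACTIVE = 40.0
_K4_CONSTITUTIVE = 120.0
_K4_BASELINE = 3.0


def generate_fragments(plan: SimulationPlan, genome: GenomeBundle,
                       truth: GroundTruth, assay: str) -> FragmentSet:
    """BED3 fragments for all five isolations of one assay.

    ``plan.fragment_depth`` is the total fragment count per sample: promoter
    fragments are drawn Poisson around the class templates and the remainder
    is uniform genomic background (promoter rates are thinned if the depth
    cannot accommodate them).
    """
    if assay not in ("ATAC", "H3K4me3"):
        raise ValueError("assay must be 'ATAC' or 'H3K4me3'")
    plan.validate()
    rng = _rng(plan, 3 if assay == "ATAC" else 4)

    genes = genome.genes
    classes = truth.gene_classes.reindex(genes["gene_id"]).to_numpy()
    tss = genes["tss"].to_numpy()
    minus = (genes["strand"] == "-").to_numpy()
    contigs = genes["contig"].to_numpy()
    sizes = genome.contig_sizes()
    contig_names = list(sizes)
    contig_len = np.array([sizes[c] for c in contig_names])
    total_len = int(contig_len.sum())
    offsets = np.concatenate([[0], np.cumsum(contig_len)])

    rows = []
    for iso in ISOLATIONS:
        if plan.fragment_depth == 0:
            continue
        parts = []
        if assay == "ATAC":
            is_stem_here = (classes == "constitutive") | ((classes == "neoblast") & (iso == "neoblast"))
            is_tissue_here = np.isin(classes, TISSUE_CLASSES) & (classes == iso)
            lam_short = np.where(is_tissue_here, _ATAC_TISSUE_SHORT,
                                 np.where(is_stem_here, _ATAC_STEM_SHORT, _ATAC_BASELINE))
            lam_nuc = np.where(is_stem_here, _ATAC_STEM_NUC, _ATAC_BASELINE)
            expected = lam_short.sum() + lam_nuc.sum()
            thin = min(1.0, plan.fragment_depth / expected)
            # short (sub-nucleosomal) fragments
            n_short = rng.poisson(lam_short * thin)
            g = np.repeat(np.arange(len(genes)), n_short)
            kind = is_tissue_here[g]
            centers = np.where(kind,
                               rng.normal(TISSUE_PEAK_CENTER, 35, g.size),
                               np.where(is_stem_here[g],
                                        rng.normal(0, 45, g.size),
                                        rng.uniform(-900, 900, g.size)))
            lens = rng.integers(50, 101, g.size)
            parts.append(_place(g, centers, lens, tss, minus, contigs))
            # nucleosome-sized fragments, phased at -180/+120 for stem/constitutive
            n_nuc = rng.poisson(lam_nuc * thin)
            g = np.repeat(np.arange(len(genes)), n_nuc)
            phased = is_stem_here[g]
            side = rng.random(g.size) < 0.5
            centers = np.where(phased,
                               np.where(side,
                                        rng.normal(NUCLEOSOME_MINUS1, 15, g.size),
                                        rng.normal(NUCLEOSOME_PLUS1, 15, g.size)),
                               rng.uniform(-900, 900, g.size))
            lens = rng.integers(150, 251, g.size)
            parts.append(_place(g, centers, lens, tss, minus, contigs))
        else:
            active = (classes == iso) | np.isin(classes, ("constitutive",))
            lam = np.where(classes == "constitutive", _K4_CONSTITUTIVE,
                           np.where(active, _K4_ACTIVE, _K4_BASELINE))
            expected = lam.sum()
            thin = min(1.0, plan.fragment_depth / expected)
            n_k4 = rng.poisson(lam * thin)
            g = np.repeat(np.arange(len(genes)), n_k4)
            centers = rng.normal(300, 200, g.size)
            lens = rng.integers(150, 351, g.size)
            parts.append(_place(g, centers, lens, tss, minus, contigs))

        prom = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
            columns=["contig", "start", "end"])
        n_bg = max(plan.fragment_depth - len(prom), 0)
        if n_bg:
            flat = rng.integers(0, total_len, n_bg)
            ci = np.searchsorted(offsets, flat, side="right") - 1
            starts = flat - offsets[ci]
            lens = rng.integers(50, 251, n_bg) if assay == "ATAC" else rng.integers(150, 351, n_bg)
            bg = pd.DataFrame({"contig": np.array(contig_names, dtype=object)[ci],
                               "start": starts, "end": starts + lens})
            prom = pd.concat([prom, bg], ignore_index=True)
        prom["sample"] = iso
        rows.append(prom)

    frags = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["contig", "start", "end", "sample"]))
    if len(frags):
        # clip fragments extending past contig bounds
        clen = frags["contig"].map(sizes).to_numpy()
        frags["start"] = np.clip(frags["start"].to_numpy(), 0, None)
        frags["end"] = np.minimum(frags["end"].to_numpy(), clen)
        frags = frags[frags["start"] < frags["end"]].reset_index(drop=True)
        frags = frags.astype({"start": np.int64, "end": np.int64})
    return FragmentSet(fragments=frags, assay=assay)


def _place(gene_idx, rel_centers, lengths, tss, minus, contigs) -> pd.DataFrame:
    """Convert TSS-relative fragment centres to genomic intervals (strand-aware)."""
    rel = np.where(minus[gene_idx], -rel_centers, rel_centers)
    centers = tss[gene_idx] + np.rint(rel).astype(np.int64)
    half = lengths // 2
    return pd.DataFrame({"contig": contigs[gene_idx],
                         "start": centers - half,
                         "end": centers - half + lengths})


# ---------------------------------------------------------------------------
# Hi-C


def generate_hic(plan: SimulationPlan, boost: float = 2.0, decay_exponent: float = 1.0,
                 block_size: int = 10, scale: float = 200.0):
    """Symmetric Poisson counts with power-law distance decay, a two-
    compartment checkerboard boost, and planted near-zero coverage strips."""
    from .hic import ContactMatrix

    plan.validate()
    if plan.hic_bins < 20:
        raise ValueError("hic_bins must be >= 20")
    rng = _rng(plan, 5)
    n = plan.hic_bins
    labels = np.where((np.arange(n) // block_size) % 2 == 0, "A", "B")
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    expected = scale * (1.0 / (1.0 + d)) ** decay_exponent
    same = labels[:, None] == labels[None, :]
    expected = expected * np.where(same, boost, 1.0)

    n_strips = int(round(plan.strip_fraction * n))
    strips = rng.choice(n, size=n_strips, replace=False) if n_strips else np.array([], dtype=int)
    damp = np.ones(n)
    damp[strips] = 1e-3
    expected = expected * damp[:, None] * damp[None, :]

    upper = rng.poisson(np.triu(expected))
    counts = np.triu(upper) + np.triu(upper, 1).T

    bins = pd.DataFrame({"contig": "hic", "start": np.arange(n) * 50_000})
    acc = np.where(labels == "A", 2.0, 1.0) * rng.lognormal(0.0, 0.1, n)
    truth = GroundTruth(bin_labels=pd.Series(labels, name="compartment"),
                        bin_accessibility=acc, strip_bins=np.sort(strips))
    return ContactMatrix(bin_size=50_000, bins=bins, matrix=counts.astype(float)), truth


# ---------------------------------------------------------------------------
# Image stacks


@dataclass
class ImageStack:
    data: np.ndarray          # (z, y, x)
    voxel_um: tuple           # (x, y, z)
    channel: str = "signal"

    def write(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.data.astype(np.float32))


def generate_colony_stack(plan: SimulationPlan, centroids_um, radii_um,
                          shape=None, amplitude: float = 50.0, noise_sd: float = 5.0,
                          background: float = 100.0, colony_cutoff_um: float = 50.0):
    """Gaussian blobs at the given physical centroids plus Gaussian noise.

    Truth colony labels are the connected components of the planted centroid
    graph with edges at pairwise distance < ``colony_cutoff_um`` (computed
    here by direct O(N^2) transitive closure, independently of the detection
    module).
    """
    plan.validate()
    rng = _rng(plan, 6)
    vx, vy, vz = plan.image_voxel_um
    centroids = np.asarray(centroids_um, float).reshape(-1, 3)  # (x, y, z) um
    radii = np.broadcast_to(np.asarray(radii_um, float), (len(centroids),))
    if len(centroids) and (radii < min(vx, vy)).any():
        raise ValueError("blob radius below voxel size")

    if shape is None:
        if len(centroids):
            shape = (int(np.ceil(centroids[:, 2].max() / vz)) + 4,
                     int(np.ceil(centroids[:, 1].max() / vy)) + 20,
                     int(np.ceil(centroids[:, 0].max() / vx)) + 20)
        else:
            shape = (8, 64, 64)

    img = rng.normal(background, noise_sd, shape)
    zz = np.arange(shape[0])[:, None, None] * vz
    yy = np.arange(shape[1])[None, :, None] * vy
    xx = np.arange(shape[2])[None, None, :] * vx
    for (cx, cy, cz), r in zip(centroids, radii):
        sigma = r / 2.0
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
        img += amplitude * np.exp(-d2 / (2.0 * sigma ** 2))

    labels = _transitive_colonies(centroids, colony_cutoff_um)
    truth = GroundTruth(colony_labels=labels)
    return ImageStack(data=img.astype(np.float32), voxel_um=(vx, vy, vz)), truth


def _transitive_colonies(points: np.ndarray, cutoff: float) -> np.ndarray:
    """Brute-force union of all pairs at distance < cutoff."""
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) < cutoff:
                parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    remap = {r: k for k, r in enumerate(dict.fromkeys(roots))}
    return np.array([remap[r] for r in roots], dtype=int)
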