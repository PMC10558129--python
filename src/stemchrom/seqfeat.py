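"""Promoter sequence statistics: composition, poly(dT) tracts, k-mer and
tandem-repeat enrichment, PWM scanning and motif-centred accessibility.

Promoter sequences are always read 5'->3' on the coding strand (minus-strand
genes reverse-complemented), so the documented T-over-A bias of stem-cell and
constitutive promoters is preserved; promoter statistics therefore scan the
coding strand only. Genome-coordinate motif hits used for accessibility
profiles scan both strands.
"""

from __future__ import annotations

import importlib.resources
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .chromatin import TSSProfile, _FragmentIndex, add_tss

_COMP = str.maketrans("ACGTN", "TGCAN")
DEFAULT_BACKGROUND = {"A": 0.35, "C": 0.15, "G": 0.15, "T": 0.35}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class PromoterSeq:
    gene_id: str
    sequence: str
    window: tuple            # (upstream, downstream) bp around the TSS
    truncated: bool = False


@dataclass
class PWM:
    """Position probability matrix with background frequencies.

    ``matrix`` is (w, 4) over columns A, C, G, T; each row sums to 1.
    Zero cells are floored at 1e-3 before taking log-odds.
    """

    name: str
    matrix: np.ndarray
    background: dict = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.shape[0] < 4 or self.matrix.shape[1] != 4:
            raise ValueError("PWM must be (w >= 4, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        p = np.maximum(self.matrix, 1e-3)
        bg = np.array([max(self.background[b], 1e-3) for b in "ACGT"])
        return np.log2(p / bg)

    def reverse_complement(self) -> "PWM":
        bg = self.background
        rc_bg = {"A": bg["T"], "C": bg["G"], "G": bg["C"], "T": bg["A"]}
        return PWM(self.name + "_rc", self.matrix[::-1, ::-1].copy(), rc_bg)

    def score_threshold(self, p_value: float, granularity: float = 1e-3) -> float:
        """Smallest score whose background tail probability is <= p_value.

        Exact enumeration of the score distribution under the background
        model, by dynamic programming on a quantised score grid.
        """
        lo = self.log_odds()
        q = np.rint(lo / granularity).astype(np.int64)
        offset = q.min(axis=1)
        q = q - offset[:, None]
        bg = np.array([self.background[b] for b in "ACGT"])
        dist = np.array([1.0])
        for row, probs in zip(q, itertools.repeat(bg)):
            new = np.zeros(len(dist) + row.max())
            for val, pr in zip(row, probs):
                new[val:val + len(dist)] += pr * dist
            dist = new
        tail = np.cumsum(dist[::-1])[::-1]
        ok = np.nonzero(tail <= p_value)[0]
        if not len(ok):
            return float("inf")
        return float((ok[0] + offset.sum()) * granularity)


def load_core_motifs() -> dict[str, PWM]:
    """Initiator-like (INR), TATA-like (TATA) and planted tissue TF (TF8)
    matrices shipped as an editable minimal-MEME fixture. The INR and TATA
    matrices are placeholders with the field-standard consensus shapes, not
    experimentally derived planarian motifs."""
    from . import io as sio

    path = importlib.resources.files("stemchrom.data") / "core_motifs.meme"
    parsed = sio.read_meme(str(path))
    out = {}
    for name, m in parsed.items():
        mat = np.array([[m.pwm[b][i] for b in "ACGT"] for i in range(m.length)])
        bg = {b: float(m.background[b]) for b in "ACGT"}
        out[name] = PWM(name, mat, bg)
    return out


# ---------------------------------------------------------------------------
# Extraction and composition


def extract_promoters(sequences: dict, genes: pd.DataFrame, upstream: int,
                      downstream: int = 0) -> list[PromoterSeq]:
    """Strand-aware window [TSS - upstream, TSS + downstream) on the coding
    strand; position -1 abuts the TSS for every gene. Windows extending past
    a contig edge are truncated and flagged."""
    genes = genes if "tss" in genes else add_tss(genes)
    out = []
    for row in genes.itertuples(index=False):
        contig = sequences[row.contig]
        if row.strand == "+":
            a, b = row.tss - upstream, row.tss + downstream
        else:
            a, b = row.tss - downstream + 1, row.tss + upstream + 1
        truncated = a < 0 or b > len(contig)
        seq = contig[max(a, 0):min(b, len(contig))]
        if row.strand == "-":
            seq = revcomp(seq)
        out.append(PromoterSeq(row.gene_id, seq, (upstream, downstream), truncated))
    return out


def composition_profile(promoters: list[PromoterSeq]) -> pd.DataFrame:
    """Per-position A/T/C/G fractions over non-N bases, plus the AT fraction.

    Promoters must share a window; positions run upstream-negative with the
    TSS at 0.
    """
    if not promoters:
        raise ValueError("no promoter sequences supplied")
    up, down = promoters[0].window
    width = up + down
    counts = np.zeros((width, 5))
    code = {b: i for i, b in enumerate("ACGTN")}
    for p in promoters:
        if p.window != (up, down):
            raise ValueError("mixed promoter windows")
        pad = width - len(p.sequence)
        for i, base in enumerate(p.sequence):
            counts[i + pad, code.get(base, 4)] += 1
    informative = counts[:, :4].sum(axis=1)
    if (informative == 0).any():
        warnings.warn("all-N column(s) in composition profile")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts[:, :4] / informative[:, None]
    df = pd.DataFrame(frac, columns=list("ACGT"))
    df["position"] = np.arange(-up, down)
    df["AT"] = df["A"] + df["T"]
    return df


def at_fraction(promoters: list[PromoterSeq], rel_start: int, rel_end: int) -> float:
    """Aggregate AT fraction over a TSS-relative slice [rel_start, rel_end)."""
    at = total = 0
    for p in promoters:
        up, down = p.window
        offset = (up + down) - len(p.sequence)
        a = rel_start + up - offset
        b = rel_end + up - offset
        seg = p.sequence[max(a, 0):max(b, 0)]
        at += sum(c in "AT" for c in seg)
        total += sum(c != "N" for c in seg)
    return at / total if total else float("nan")


# ---------------------------------------------------------------------------
# T-stretches and tandem repeats


def t_runs(seq: str, min_len: int) -> list[int]:
    """Lengths of maximal T homopolymer runs of at least ``min_len``."""
    runs = []
    n = 0
    for c in seq + "$":
        if c == "T":
            n += 1
        else:
            if n >= min_len:
                runs.append(n)
            n = 0
    return runs


def t_stretch_stats(promoters: list[PromoterSeq], classes: pd.Series,
                    min_len: int = 5) -> tuple[pd.Series, pd.DataFrame]:
    """Per-gene counts of maximal T-runs >= min_len, and pairwise class
    comparisons by two-sided rank-sum test with Bonferroni correction."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    counts = pd.Series({p.gene_id: len(t_runs(p.sequence, min_len)) for p in promoters},
                       name="t_stretches")
    labels = classes.reindex(counts.index)
    groups = sorted(labels.dropna().unique())
    rows = []
    pairs = list(itertools.combinations(groups, 2))
    for a, b in pairs:
        xa = counts[labels == a]
        xb = counts[labels == b]
        if len(xa) and len(xb):
            stat, p = stats.ranksums(xa, xb)
        else:
            stat, p = np.nan, np.nan
        rows.append({"class_a": a, "class_b": b, "statistic": stat,
                     "p_value": p, "p_bonferroni": min(p * len(pairs), 1.0)})
    return counts, pd.DataFrame(rows)


def tandem_repeat_scan(promoters: list[PromoterSeq], unit_len: int = 3,
                       min_units: int = 3) -> pd.DataFrame:
    """Maximal perfect tandem arrays of ``unit_len``-mers with >= min_units
    full units; arrays whose unit contains only A/T are flagged."""
    if unit_len < 1:
        raise ValueError("unit_len must be >= 1")
    rows = []
    for p in promoters:
        for start, n_units, unit in _tandem_arrays(p.sequence, unit_len, min_units):
            rows.append({"gene_id": p.gene_id, "start": start, "n_units": n_units,
                         "unit": unit, "at_only": set(unit) <= {"A", "T"}})
    return pd.DataFrame(rows, columns=["gene_id", "start", "n_units", "unit", "at_only"])


def _tandem_arrays(seq: str, u: int, min_units: int):
    """Maximal runs of the period-u self-match; unit count uses full units."""
    n = len(seq)
    if n < 2 * u:
        return
    match = np.frombuffer(seq.encode(), np.uint8)
    m = match[:-u] == match[u:]
    i = 0
    while i < len(m):
        if m[i]:
            j = i
            while j < len(m) and m[j]:
                j += 1
            span = (j - i) + u
            n_units = span // u
            if n_units >= min_units:
                yield i, n_units, seq[i:i + u]
            i = j
        else:
            i += 1


# ---------------------------------------------------------------------------
# k-mer enrichment


def count_kmers(sequences: list[str], k: int) -> dict[str, int]:
    """Occurrences over all sequences, overlaps allowed, coding strand only.
    Windows containing N are skipped."""
    counts: dict[str, int] = {}
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def kmer_enrichment(promoters: list[PromoterSeq], background: list[PromoterSeq],
                    k: int = 9) -> pd.DataFrame:
    """k-mer enrichment of a promoter set against a background set.

    Expected counts come from background k-mer frequencies times the number
    of foreground positions; enrichment = log2((obs+0.5)/(exp+0.5)); the
    P value is a binomial upper tail (positions treated as independent),
    Benjamini-Hochberg corrected across k-mers.
    """
    fg = [p.sequence for p in promoters]
    bg = [p.sequence for p in background]
    if not bg:
        raise ValueError("empty background")
    if any(len(s) < k for s in fg + bg):
        raise ValueError("k exceeds the shortest sequence")
    obs = count_kmers(fg, k)
    bg_counts = count_kmers(bg, k)
    n_fg = sum(len(s) - k + 1 for s in fg)
    n_bg = sum(len(s) - k + 1 for s in bg)
    kmers = sorted(set(obs) | set(bg_counts))
    rows = []
    for kmer in kmers:
        o = obs.get(kmer, 0)
        p_bg = bg_counts.get(kmer, 0) / n_bg
        e = p_bg * n_fg
        enrich = np.log2((o + 0.5) / (e + 0.5))
        pval = stats.binom.sf(o - 1, n_fg, min(p_bg, 1.0)) if p_bg > 0 else (
            0.0 if o > 0 else 1.0)
        rows.append({"kmer": kmer, "observed": o, "expected": e,
                     "log2_enrichment": enrich, "p_value": pval})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["log2_enrichment", "kmer"],
                          ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# PWM scanning


def scan_sequence(seq: str, pwm: PWM, threshold: float) -> list[tuple[int, float]]:
    """(offset, score) of hits with log-odds score >= threshold."""
    lo = pwm.log_odds()
    w = pwm.width
    idx = {b: i for i, b in enumerate("ACGT")}
    hits = []
    for off in range(len(seq) - w + 1):
        window = seq[off:off + w]
        if "N" in window:
            continue
        score = sum(lo[j, idx[c]] for j, c in enumerate(window))
        if score >= threshold:
            hits.append((off, float(score)))
    return hits


def scan_pwm(promoters: list[PromoterSeq], pwm: PWM, score_threshold: float | None = None,
             p_value: float | None = None) -> pd.DataFrame:
    """Scan promoter sequences (coding strand) for PWM hits.

    Provide either a log-odds ``score_threshold`` or a ``p_value`` (converted
    to a score cutoff by exact enumeration of the background score
    distribution). Offsets are TSS-relative.
    """
    if score_threshold is None:
        if p_value is None:
            p_value = 1e-3
        score_threshold = pwm.score_threshold(p_value)
    rows = []
    for p in promoters:
        up, down = p.window
        offset0 = -up + ((up + down) - len(p.sequence))
        for off, score in scan_sequence(p.sequence, pwm, score_threshold):
            rows.append({"gene_id": p.gene_id, "offset": offset0 + off,
                         "strand": "+", "score": score, "motif": pwm.name})
    return pd.DataFrame(rows, columns=["gene_id", "offset", "strand", "score", "motif"])


def scan_genome(sequences: dict, pwm: PWM, score_threshold: float | None = None,
                p_value: float | None = None) -> pd.DataFrame:
    """Both-strand genome scan; returns genomic hit intervals with strand."""
    if score_threshold is None:
        score_threshold = pwm.score_threshold(p_value if p_value is not None else 1e-4)
    rows = []
    rc = pwm.reverse_complement()
    for contig, seq in sequences.items():
        for off, score in scan_sequence(seq, pwm, score_threshold):
            rows.append({"contig": contig, "start": off, "end": off + pwm.width,
                         "strand": "+", "score": score, "motif": pwm.name})
        for off, score in scan_sequence(seq, rc, score_threshold):
            rows.append({"contig": contig, "start": off, "end": off + pwm.width,
                         "strand": "-", "score": score, "motif": pwm.name})
    return pd.DataFrame(rows, columns=["contig", "start", "end", "strand", "score", "motif"])


def motif_class_frequency(hits: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    """Percent of genes in each class with >= 1 hit, per motif."""
    rows = []
    for motif, sub in hits.groupby("motif", sort=False) if len(hits) else ():
        with_hit = set(sub["gene_id"])
        for cls, members in classes.groupby(classes, sort=True):
            n = len(members)
            if n == 0:
                continue
            pct = 100.0 * sum(g in with_hit for g in members.index) / n
            rows.append({"motif": motif, "class": cls, "percent": pct, "n_genes": n})
    if not rows:  # no hits anywhere: report 0% for every class
        for cls, members in classes.groupby(classes, sort=True):
            rows.append({"motif": None, "class": cls, "percent": 0.0,
                         "n_genes": len(members)})
    return pd.DataFrame(rows)


def motif_accessibility_profile(hits: pd.DataFrame, fragments: pd.DataFrame,
                                half_width: int = 500, bin: int = 10,
                                library_size: int | None = None,
                                label: str = "") -> TSSProfile:
    """Mean RPKM-scaled coverage centred on genomic motif hits, oriented by
    motif strand."""
    if hits.empty:
        warnings.warn("no motif hits; returning empty profile")
        return TSSProfile(label=label, positions=np.array([]), values=np.array([]))
    lib = library_size if library_size is not None else len(fragments)
    index = _FragmentIndex(fragments)
    n_bins = (2 * half_width) // bin
    acc = np.zeros(n_bins)
    for row in hits.itertuples(index=False):
        center = (row.start + row.end) // 2
        w0, w1 = center - half_width, center + half_width
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
    values = acc / len(hits) * 1e9 / (bin * lib)
    positions = np.arange(n_bins) * bin - half_width + bin / 2.0
    return TSSProfile(label=label, positions=positions, values=values)
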