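"""TPM normalisation, pairwise differential contrasts, and gene classification.

Genes are labelled by the rule set used for the planarian cell isolations:
a gene is *stem-cell (neoblast) specific* if it is more than twofold higher
(log2FC > 1) with adjusted P < 0.05 against every other isolation; *tissue
specific* analogously for one tissue against all other isolations and the
neoblasts; *constitutive* if it is expressed (mean TPM > 10) in every
isolation with no significant pairwise difference anywhere; otherwise
*unclassified*.

The differential engine is pluggable:

* ``engine="welch"`` (default): two-sided Welch t-test on log2(TPM + pc)
  across replicates, Benjamini-Hochberg within each contrast. Lightweight
  and dependency-free, but with three replicates per group it has limited
  power at realistic overdispersion.
* ``engine="deseq2"``: Wald contrasts from a single pydeseq2 fit with a
  shared design (the negative-binomial GLM machinery used in the original
  analyses). Preferred when counts are available.
* precomputed per-contrast tables in the same schema may be passed straight
  to :func:`classify_genes`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONTRAST_COLUMNS = ["gene_id", "contrast", "log2FC", "p_adj"]


@dataclass
class CountMatrix:
    """Replicated gene x sample counts with isolation/replicate metadata."""

    counts: pd.DataFrame          # genes x samples, non-negative integers
    lengths: pd.Series            # effective gene length (bp), > 0
    samples: pd.DataFrame         # sample, isolation, replicate

    def __post_init__(self):
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        missing = set(self.samples["sample"]) - set(self.counts.columns)
        if missing:
            raise ValueError(f"samples missing from count matrix: {sorted(missing)}")

    @property
    def isolations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["isolation"]))

    def samples_of(self, isolation: str) -> list[str]:
        sel = self.samples[self.samples["isolation"] == isolation]
        return sel["sample"].tolist()

    def write(self, counts_path, sheet_path) -> None:
        from . import io as sio

        sio.write_counts(self.counts, self.lengths, counts_path)
        sio.write_sample_sheet(self.samples, sheet_path)

    @classmethod
    def read(cls, counts_path, sheet_path) -> "CountMatrix":
        from . import io as sio

        counts, lengths = sio.read_counts(counts_path)
        return cls(counts=counts, lengths=lengths, samples=sio.read_sample_sheet(sheet_path))


def compute_tpm(counts: CountMatrix) -> pd.DataFrame:
    """Transcripts per million: 1e6 * (count/length) / sum(count/length)."""
    rates = counts.counts.div(counts.lengths, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero total rate in sample(s): {', '.join(zero.index)}")
    return rates.div(totals, axis=1) * 1e6


def contrast_name(iso_a: str, iso_b: str) -> str:
    return f"{iso_a}_vs_{iso_b}"


def pairwise_contrasts(counts: CountMatrix, pseudocount: float = 1.0,
                       engine: str = "welch") -> pd.DataFrame:
    """Differential tests for every isolation pair (numerator = first isolation)."""
    isolations = counts.isolations
    if len(isolations) < 2:
        raise ValueError("need at least two isolations")
    for iso in isolations:
        if len(counts.samples_of(iso)) < 2:
            raise ValueError(f"isolation {iso} has fewer than two replicates")
    if engine == "welch":
        return _welch_contrasts(counts, pseudocount)
    if engine == "deseq2":
        return _deseq2_contrasts(counts)
    raise ValueError(f"unknown engine: {engine!r}")


def _welch_contrasts(counts: CountMatrix, pseudocount: float) -> pd.DataFrame:
    tpm = compute_tpm(counts)
    log_tpm = np.log2(tpm + pseudocount)
    out = []
    for iso_a, iso_b in itertools.combinations(counts.isolations, 2):
        xa = log_tpm[counts.samples_of(iso_a)].to_numpy()
        xb = log_tpm[counts.samples_of(iso_b)].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-variance groups yield nan
            _, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)  # zero variance both groups, equal means
        lfc = (np.log2(tpm[counts.samples_of(iso_a)].mean(axis=1) + pseudocount)
               - np.log2(tpm[counts.samples_of(iso_b)].mean(axis=1) + pseudocount))
        out.append(pd.DataFrame({
            "gene_id": tpm.index,
            "contrast": contrast_name(iso_a, iso_b),
            "log2FC": lfc.to_numpy(),
            "p_adj": multipletests(p, method="fdr_bh")[1],
        }))
    return pd.concat(out, ignore_index=True)


def _deseq2_contrasts(counts: CountMatrix) -> pd.DataFrame:
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    meta = counts.samples.set_index("sample")[["isolation"]]
    cdf = counts.counts.T.loc[meta.index].astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(counts=cdf, metadata=meta, design="~isolation", quiet=True)
        dds.deseq2()
    out = []
    for iso_a, iso_b in itertools.combinations(counts.isolations, 2):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = DeseqStats(dds, contrast=["isolation", iso_a, iso_b], quiet=True)
            ds.summary()
        res = ds.results_df
        out.append(pd.DataFrame({
            "gene_id": res.index,
            "contrast": contrast_name(iso_a, iso_b),
            "log2FC": res["log2FoldChange"].to_numpy(),
            "p_adj": np.nan_to_num(res["padj"].to_numpy(), nan=1.0),
        }))
    return pd.concat(out, ignore_index=True)


def classify_genes(contrasts: pd.DataFrame, tpm: pd.DataFrame, samples: pd.DataFrame,
                   stem_isolation: str = "neoblast",
                   tissue_isolations: tuple = ("brain", "epidermis", "intestine"),
                   log2fc_cutoff: float = 1.0, padj_cutoff: float = 0.05,
                   tpm_expressed: float = 10.0) -> pd.DataFrame:
    """Apply the classification rules to a contrast table.

    Inequalities are strict: a contrast with log2FC exactly at the cutoff
    does not count as differential.
    """
    isolations = list(dict.fromkeys(samples["isolation"]))
    gene_ids = tpm.index
    # signed log2FC lookup per (focal, other) ordered pair
    lfc: dict[tuple[str, str], pd.Series] = {}
    padj: dict[tuple[str, str], pd.Series] = {}
    for (a, b), sub in contrasts.groupby(
            contrasts["contrast"].str.split("_vs_").map(tuple), sort=False):
        sub = sub.set_index("gene_id")
        lfc[(a, b)] = sub["log2FC"]
        lfc[(b, a)] = -sub["log2FC"]
        padj[(a, b)] = padj[(b, a)] = sub["p_adj"]

    missing = [g for g in gene_ids
               if any(g not in lfc[pair].index for pair in lfc)]
    if missing:
        warnings.warn(f"{len(missing)} gene(s) absent from some contrast; left unclassified")

    def up_everywhere(focal: str) -> pd.Series:
        ok = pd.Series(True, index=gene_ids)
        for other in isolations:
            if other == focal:
                continue
            pair = (focal, other)
            if pair not in lfc:
                raise ValueError(f"missing contrast for isolations {pair}")
            l = lfc[pair].reindex(gene_ids)
            p = padj[pair].reindex(gene_ids)
            ok &= (l > log2fc_cutoff) & (p < padj_cutoff) & l.notna()
        return ok

    classes = pd.Series("unclassified", index=gene_ids, name="class")
    for focal in (stem_isolation, *tissue_isolations):
        hit = up_everywhere(focal) & (classes == "unclassified")
        classes[hit] = focal

    # constitutive: expressed everywhere, no significant pairwise difference
    mean_tpm = pd.DataFrame({
        iso: tpm[samples.loc[samples["isolation"] == iso, "sample"]].mean(axis=1)
        for iso in isolations})
    expressed_all = (mean_tpm > tpm_expressed).all(axis=1)
    any_sig = pd.Series(False, index=gene_ids)
    for _, tab in contrasts.groupby("contrast"):
        t = tab.set_index("gene_id").reindex(gene_ids)
        any_sig |= ((t["log2FC"].abs() > log2fc_cutoff)
                    & (t["p_adj"] < padj_cutoff)).fillna(False)
    const = expressed_all & ~any_sig & (classes == "unclassified")
    classes[const] = "constitutive"
    if missing:
        classes[missing] = "unclassified"

    table = classes.rename("class").to_frame()
    table["expression_bin"] = bin_expression(tpm, stem_isolation, samples)
    return table.reset_index(names="gene_id")


def bin_expression(tpm: pd.DataFrame, isolation: str, samples: pd.DataFrame) -> pd.Series:
    """Expression bins in one isolation: high (>30), expressed (>10 and <30,
    with boundary values 10 and 30 assigned to the middle bin), weak (<10)."""
    cols = samples.loc[samples["isolation"] == isolation, "sample"]
    if not len(cols):
        raise ValueError(f"no samples for isolation {isolation!r}")
    mean = tpm[cols].mean(axis=1)
    bins = pd.Series("weak", index=tpm.index, name="expression_bin")
    bins[mean >= 10] = "expressed"
    bins[mean > 30] = "high"
    return bins
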