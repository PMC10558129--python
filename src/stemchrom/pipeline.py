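"""Stage orchestration: simulate -> classify -> chromatin -> seqfeat ->
compartments -> colonies -> report.

A run is configured by a plain-text (YAML) config whose defaults are the
study's printed parameter values (2-kb promoter, +/-1-kb profiles, TSS+/-40
motif window, 50-kb Hi-C bins, 50-um colony cutoff, TPM bins at 10/30,
log2FC cutoff 1, adjusted P 0.05, replicate peak filter -log10 P > 4).
Unknown keys are rejected before any stage runs; the resolved config is
written beside the outputs; every source of randomness derives from the
single config seed, so a repeated run is byte-identical (the timestamped
log aside).
"""

from __future__ import annotations

import copy
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import chromatin, colonies, expression, hic, seqfeat
from . import io as sio
from . import simulate

STAGES = ("simulate", "classify", "chromatin", "seqfeat", "compartments", "colonies", "report")

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": list(STAGES),
    "simulate": {
        "n_genes_per_class": {"brain": 150, "epidermis": 150, "intestine": 150,
                              "neoblast": 150, "constitutive": 200, "unclassified": 200},
        "genome_at_fraction": 0.70,
        "promoter_at_fraction_constitutive": 0.92,
        "tss_window_bp": 2000,
        "fragment_depth": 200_000,
        "nb_dispersion": 0.1,
        "fold_change": 4.0,
        "hic_bins": 100,
        "strip_fraction": 0.10,
        "image_voxel_um": [1.38, 1.38, 7.0],
        "colony_sizes": [3, 5, 9],
        "blob_radius_um": 8.0,
    },
    "classify": {
        "engine": "deseq2",
        "pseudocount": 1.0,
        "log2fc_cutoff": 1.0,
        "padj_cutoff": 0.05,
        "tpm_expressed": 10.0,
    },
    "chromatin": {
        "promoter_bp": 2000,
        "profile_half_width": 1000,
        "profile_bin": 10,
        "min_neg_log10_p": 4.0,
    },
    "seqfeat": {
        "motif_window": 40,
        "upstream_bp": 500,
        "kmer_k": 9,
        "t_stretch_min_len": 5,
        "pwm_p_value": 1e-4,
    },
    "compartments": {
        "min_coverage_frac": 0.05,
    },
    "colonies": {
        "cutoff_um": 50.0,
        "n": 3,
        "f": 2.0,
        "mode": "3D",
        "min_size": 14,
    },
}


def resolve_config(user: dict | None) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    config = copy.deepcopy(DEFAULT_CONFIG)

    def merge(base, override, path=""):
        for key, value in override.items():
            if key not in base:
                raise KeyError(f"unknown config key: {path}{key}")
            if isinstance(base[key], dict) and key != "n_genes_per_class":
                if not isinstance(value, dict):
                    raise ValueError(f"config key {path}{key} must be a mapping")
                merge(base[key], value, path=f"{path}{key}.")
            else:
                base[key] = value

    if user:
        merge(config, user)
    unknown_stages = set(config["stages"]) - set(STAGES)
    if unknown_stages:
        raise KeyError(f"unknown stage(s): {sorted(unknown_stages)}")
    return config


def load_config(path) -> dict:
    return resolve_config(sio.read_keyvalue(path) or {})


def _plan_from_config(config: dict) -> simulate.SimulationPlan:
    sim = config["simulate"]
    return simulate.SimulationPlan(
        seed=config["seed"],
        n_genes_per_class=dict(sim["n_genes_per_class"]),
        genome_at_fraction=sim["genome_at_fraction"],
        promoter_at_fraction_constitutive=sim["promoter_at_fraction_constitutive"],
        tss_window_bp=sim["tss_window_bp"],
        fragment_depth=sim["fragment_depth"],
        nb_dispersion=sim["nb_dispersion"],
        fold_change=sim["fold_change"],
        hic_bins=sim["hic_bins"],
        strip_fraction=sim["strip_fraction"],
        image_voxel_um=tuple(sim["image_voxel_um"]),
    ).validate()


def planted_colony_layout(sizes, rng, inter_um=160.0, cell_spacing_um=30.0,
                          jitter_um=1.5):
    """Deterministic colony centroids for the synthetic stack.

    Colonies sit ``inter_um`` apart (every cross-colony cell pair well beyond
    the 50-um cutoff); within a colony, cells occupy a 3x3 in-plane grid
    (plus 14-um z layers beyond nine cells) with ``cell_spacing_um`` spacing,
    so neighbouring cells chain below the cutoff while every blob stays far
    enough from its neighbours to segment as a separate object.
    """
    pts = []
    for k, size in enumerate(sizes):
        cx = 80.0 + inter_um * k
        cy = 80.0
        cz = 14.0 + 7.0 * (k % 2)
        for i in range(size):
            gx = (i % 3 - 1) * cell_spacing_um
            gy = (i // 3 % 3 - 1) * cell_spacing_um
            gz = (i // 9) * 14.0
            jitter = rng.uniform(-jitter_um, jitter_um, 3) * np.array([1.0, 1.0, 0.1])
            pts.append(np.array([cx + gx, cy + gy, cz + gz]) + jitter)
    return np.array(pts) if pts else np.zeros((0, 3))


class PipelineError(RuntimeError):
    pass


def run(config: dict, outdir, stages=None) -> Path:
    """Execute the requested stages; returns the artifact directory."""
    config = resolve_config(config if config else {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages else list(config["stages"])
    for s in stages:
        if s not in STAGES:
            raise KeyError(f"unknown stage: {s}")
    sio.write_keyvalue(config, outdir / "resolved_config.yaml")
    log = open(outdir / "run.log", "a")

    def say(msg):
        log.write(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {msg}\n")
        log.flush()

    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            say(f"stage {stage} start")
            _STAGE_FUNCS[stage](config, outdir)
            say(f"stage {stage} done")
    except Exception as exc:
        say(f"FAILED: {exc}")
        raise
    finally:
        log.close()
    return outdir


def _require(outdir: Path, name: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise PipelineError(f"missing artifact: {name} (run the producing stage first)")
    return path


def _stage_simulate(config, outdir):
    plan = _plan_from_config(config)
    genome, truth = simulate.generate_genome(plan)
    genome.write(outdir)
    genome.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    truth.gene_classes.rename("class").to_frame().to_csv(outdir / "truth_classes.tsv", sep="\t")
    truth.motifs.to_csv(outdir / "truth_motifs.tsv", sep="\t", index=False)

    counts = simulate.generate_counts(plan, truth)
    counts.write(outdir / "counts.tsv", outdir / "samples.tsv")

    for assay, fname in (("ATAC", "atac_fragments.bed"), ("H3K4me3", "h3k4me3_fragments.bed")):
        frags = simulate.generate_fragments(plan, genome, truth, assay)
        frags.write(outdir / fname)

    contacts, hic_truth = simulate.generate_hic(plan)
    contacts.write(outdir / "hic_contacts.coo", outdir / "hic_bins.tsv")
    pd.DataFrame({"bin": np.arange(plan.hic_bins),
                  "compartment": hic_truth.bin_labels,
                  "accessibility": hic_truth.bin_accessibility,
                  }).to_csv(outdir / "truth_hic.tsv", sep="\t", index=False)

    rng = np.random.default_rng([plan.seed, 7])
    sizes = config["simulate"]["colony_sizes"]
    pts = planted_colony_layout(sizes, rng)
    stack, col_truth = simulate.generate_colony_stack(
        plan, pts, config["simulate"]["blob_radius_um"], shape=None)
    stack.write(outdir / "colony_stack.tif")
    pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1], "z_um": pts[:, 2],
                  "colony": col_truth.colony_labels,
                  }).to_csv(outdir / "truth_colonies.tsv", sep="\t", index=False)


def _stage_classify(config, outdir):
    cm = expression.CountMatrix.read(_require(outdir, "counts.tsv"),
                                     _require(outdir, "samples.tsv"))
    cc = config["classify"]
    tpm = expression.compute_tpm(cm)
    contrasts = expression.pairwise_contrasts(cm, pseudocount=cc["pseudocount"],
                                              engine=cc["engine"])
    table = expression.classify_genes(contrasts, tpm, cm.samples,
                                      log2fc_cutoff=cc["log2fc_cutoff"],
                                      padj_cutoff=cc["padj_cutoff"],
                                      tpm_expressed=cc["tpm_expressed"])
    contrasts.to_csv(outdir / "contrasts.tsv", sep="\t", index=False,
                     float_format="%.6g")
    table.to_csv(outdir / "classes.tsv", sep="\t", index=False)
    tpm.to_csv(outdir / "tpm.tsv", sep="\t", float_format="%.6g")


def _classes_for_profiles(outdir) -> pd.Series:
    path = outdir / "classes.tsv"
    if path.exists():
        table = pd.read_csv(path, sep="\t")
        return table.set_index("gene_id")["class"]
    return pd.read_csv(_require(outdir, "truth_classes.tsv"), sep="\t",
                       index_col=0)["class"]


def _stage_chromatin(config, outdir):
    cfg = config["chromatin"]
    genes = pd.read_csv(_require(outdir, "genes.tsv"), sep="\t")
    classes = _classes_for_profiles(outdir)
    atac = sio.read_fragments(_require(outdir, "atac_fragments.bed"))
    k4 = sio.read_fragments(_require(outdir, "h3k4me3_fragments.bed"))

    profiles, ratios, nuc_profiles = [], [], []
    iso_of = {"brain": "brain", "epidermis": "epidermis", "intestine": "intestine",
              "neoblast": "neoblast", "constitutive": "neoblast"}
    win = chromatin.tss_windows(genes, upstream=cfg["promoter_bp"] // 2,
                                downstream=cfg["promoter_bp"] // 2)
    for cls, iso in iso_of.items():
        members = genes[genes["gene_id"].isin(classes[classes == cls].index)]
        if members.empty:
            continue
        a = atac[atac["sample"] == iso]
        h = k4[k4["sample"] == iso]
        for frags, assay in ((a, "ATAC"), (h, "H3K4me3")):
            prof = chromatin.tss_metaprofile(frags, members,
                                             half_width=cfg["profile_half_width"],
                                             bin=cfg["profile_bin"],
                                             library_size=len(frags),
                                             label=f"{cls}:{assay}")
            profiles.append(prof.to_frame().assign(assay=assay, isolation=iso))
        wsub = win[win["gene_id"].isin(members["gene_id"])].reset_index(drop=True)
        ar = chromatin.window_rpkm(a, wsub, library_size=len(a))
        kr = chromatin.window_rpkm(h, wsub, library_size=len(h))
        ratio = chromatin.atac_h3k4_ratio(ar, kr)
        ratios.append(pd.DataFrame({"gene_id": ratio.index, "class": cls,
                                    "log2_atac_h3k4": ratio.to_numpy()}))
        nuc = chromatin.nucleosome_occupancy(a, members,
                                             half_width=cfg["profile_half_width"],
                                             label=cls)
        nuc_profiles.append(nuc.to_frame())

    pd.concat(profiles, ignore_index=True).to_csv(
        outdir / "tss_profiles.tsv", sep="\t", index=False, float_format="%.6g")
    pd.concat(ratios, ignore_index=True).to_csv(
        outdir / "atac_h3k4_ratio.tsv", sep="\t", index=False, float_format="%.6g")
    pd.concat(nuc_profiles, ignore_index=True).to_csv(
        outdir / "nucleosome_occupancy.tsv", sep="\t", index=False, float_format="%.6g")


def _stage_seqfeat(config, outdir):
    cfg = config["seqfeat"]
    genome = sio.read_fasta(_require(outdir, "genome.fa"))
    genes = pd.read_csv(_require(outdir, "genes.tsv"), sep="\t")
    classes = _classes_for_profiles(outdir)
    motifs = seqfeat.load_core_motifs()

    prom500 = seqfeat.extract_promoters(genome, genes, upstream=cfg["upstream_bp"])
    at_rows = []
    for cls in sorted(classes.unique()):
        members = [p for p in prom500 if classes.get(p.gene_id) == cls]
        if members:
            at_rows.append({"class": cls,
                            "at_fraction_minus200_0": seqfeat.at_fraction(members, -200, 0),
                            "n_genes": len(members)})
    pd.DataFrame(at_rows).to_csv(outdir / "promoter_at.tsv", sep="\t", index=False,
                                 float_format="%.6g")

    t_counts, t_tests = seqfeat.t_stretch_stats(prom500, classes,
                                                min_len=cfg["t_stretch_min_len"])
    t_counts.to_frame().to_csv(outdir / "t_stretch_counts.tsv", sep="\t")
    t_tests.to_csv(outdir / "t_stretch_tests.tsv", sep="\t", index=False,
                   float_format="%.6g")

    tissue = [p for p in prom500 if classes.get(p.gene_id) in simulate.TISSUE_CLASSES]
    stemlike = [p for p in prom500 if classes.get(p.gene_id) in ("constitutive", "neoblast")]
    if tissue and stemlike:
        enr = seqfeat.kmer_enrichment(tissue, stemlike, k=cfg["kmer_k"])
        enr.head(50).to_csv(outdir / "kmer_enrichment.tsv", sep="\t", index=False,
                            float_format="%.6g")

    w = cfg["motif_window"]
    prom_tss = seqfeat.extract_promoters(genome, genes, upstream=w, downstream=w + 1)
    hits = pd.concat([seqfeat.scan_pwm(prom_tss, motifs[m], p_value=cfg["pwm_p_value"])
                      for m in ("INR", "TATA")], ignore_index=True)
    freq = seqfeat.motif_class_frequency(hits, classes)
    freq.to_csv(outdir / "motif_frequencies.tsv", sep="\t", index=False,
                float_format="%.6g")


def _stage_compartments(config, outdir):
    cfg = config["compartments"]
    truth = pd.read_csv(_require(outdir, "truth_hic.tsv"), sep="\t")
    n = len(truth)
    matrix = sio.read_contacts_coo(_require(outdir, "hic_contacts.coo"), n)
    bins = pd.read_csv(_require(outdir, "hic_bins.tsv"), sep="\t")
    contacts = hic.ContactMatrix(bin_size=50_000, bins=bins, matrix=matrix)
    track, dropped = hic.call_compartments(contacts,
                                           min_coverage_frac=cfg["min_coverage_frac"])
    oriented, _ = hic.orient_and_enrich(track, truth["accessibility"].to_numpy())
    out = oriented.to_bedgraph(contacts.bin_size)
    out["label"] = oriented.labels
    out.to_csv(outdir / "compartments.tsv", sep="\t", index=False, float_format="%.6g")


def _stage_colonies(config, outdir):
    import tifffile

    cfg = config["colonies"]
    data = tifffile.imread(_require(outdir, "colony_stack.tif"))
    sim = config["simulate"]
    stack = simulate.ImageStack(data=data, voxel_um=tuple(sim["image_voxel_um"]))
    objects = colonies.detect_objects(stack, n=cfg["n"], f=cfg["f"], mode=cfg["mode"],
                                      min_size=cfg["min_size"])
    colset = colonies.assign_colonies(objects, cutoff=cfg["cutoff_um"])
    colset.objects.to_csv(outdir / "colony_objects.csv", index=False,
                          float_format="%.4f")
    colset.colony_sizes().to_frame().to_csv(outdir / "colony_sizes.csv")


def _stage_report(config, outdir):
    lines = ["stemchrom pipeline report", "=" * 40]
    lines.append(f"seed: {config['seed']}")

    def add_table(title, path, fmt=lambda df: df.to_string(index=False)):
        p = outdir / path
        if p.exists():
            df = pd.read_csv(p, sep="\t" if path.endswith(".tsv") else ",")
            lines.append("")
            lines.append(f"## {title}")
            lines.append(fmt(df))

    cpath = outdir / "classes.tsv"
    if cpath.exists():
        table = pd.read_csv(cpath, sep="\t")
        lines += ["", "## gene classes"]
        lines.append(table["class"].value_counts().sort_index().to_string())
        lines += ["", "## expression bins"]
        lines.append(table["expression_bin"].value_counts().sort_index().to_string())

    ppath = outdir / "tss_profiles.tsv"
    if ppath.exists():
        prof = pd.read_csv(ppath, sep="\t")
        lines += ["", "## ATAC TSS metaprofile argmax per class (bp rel. TSS)"]
        for cls, sub in prof[prof["assay"] == "ATAC"].groupby("class", sort=True):
            pos = sub.loc[sub["mean"].idxmax(), "position"]
            lines.append(f"{cls}: {pos:+.0f}")

    rpath = outdir / "atac_h3k4_ratio.tsv"
    if rpath.exists():
        rat = pd.read_csv(rpath, sep="\t")
        lines += ["", "## median log2(ATAC/H3K4me3) per class"]
        lines.append(rat.groupby("class")["log2_atac_h3k4"].median()
                     .round(3).to_string())

    add_table("promoter AT fraction [-200,0)", "promoter_at.tsv")
    add_table("motif frequencies (TSS +/- 40)", "motif_frequencies.tsv")

    kpath = outdir / "compartments.tsv"
    if kpath.exists():
        comp = pd.read_csv(kpath, sep="\t")
        lines += ["", "## compartments"]
        lines.append(comp["label"].value_counts().sort_index().to_string())

    spath = outdir / "colony_sizes.csv"
    if spath.exists():
        sizes = pd.read_csv(spath)
        lines += ["", "## colony sizes (cells per colony)"]
        lines.append(" ".join(str(s) for s in sorted(sizes["cells"])))

    (outdir / "report.txt").write_text("\n".join(lines) + "\n")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "chromatin": _stage_chromatin,
    "seqfeat": _stage_seqfeat,
    "compartments": _stage_compartments,
    "colonies": _stage_colonies,
    "report": _stage_report,
}
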