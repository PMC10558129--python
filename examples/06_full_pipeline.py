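"""Run the complete pipeline — simulate, classify, chromatin, seqfeat,
compartments, colonies, report — from one config, twice, and show that the
same seed reproduces every artifact byte for byte.
"""

import hashlib
from pathlib import Path
from tempfile import mkdtemp

from stemchrom import pipeline

config = {
    "seed": 7,
    "simulate": {
        "n_genes_per_class": {"brain": 30, "epidermis": 30, "intestine": 30,
                              "neoblast": 30, "constitutive": 40, "unclassified": 40},
        "fragment_depth": 60_000,
    },
}

digests = []
for run in ("first", "second"):
    outdir = Path(mkdtemp(prefix=f"stemchrom_{run}_"))
    pipeline.run(config, outdir)
    blob = b"".join(p.read_bytes() for p in sorted(outdir.iterdir())
                    if p.name != "run.log")
    digests.append(hashlib.sha256(blob).hexdigest())
    if run == "first":
        print((outdir / "report.txt").read_text())

print(f"run digests equal: {digests[0] == digests[1]}")
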