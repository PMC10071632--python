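#!/usr/bin/env python
"""FPKM/TE quantification, differential analysis and the nine-quadrant
classification of transcription vs translation changes.

Writes expression.tsv, diff_<layer>.tsv and quadrants.tsv; prints the
differential counts per layer and the quadrant occupancy.
"""

import logging
from pathlib import Path

import pandas as pd

from riboprof.pipeline import load_config, stage_quadrant, stage_te

RUN = Path(__file__).resolve().parent.parent / "results" / "run"

logging.basicConfig(level=logging.INFO)
cfg = load_config({"seed": 42})
stage_te(cfg, RUN)
stage_quadrant(cfg, RUN)

for layer in ("transcription", "translation", "te"):
    d = pd.read_csv(RUN / f"diff_{layer}.tsv", sep="\t")
    up = ((d["significant"]) & (d["log2fc"] > 0)).sum()
    dn = ((d["significant"]) & (d["log2fc"] < 0)).sum()
    print(f"{layer}: {up} up, {dn} down of {len(d)} genes")
quad = pd.read_csv(RUN / "quadrants.tsv", sep="\t")
occ = quad["label"].value_counts(normalize=True).mul(100).round(2)
print("quadrant occupancy (%):")
print(occ.to_string())
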