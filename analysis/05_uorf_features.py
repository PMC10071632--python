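#!/usr/bin/env python
"""Sequence and expression features of translated vs untranslated uORFs.

Writes uorf_lengths.tsv, distance_test.tsv, kozak_tests.tsv,
gc_profile.tsv and te_ecdf.tsv; prints the directional findings
(reinitiation distance, +4 G enrichment, TE repression).
"""

import json
import logging
from pathlib import Path

import pandas as pd

from riboprof.pipeline import load_config, stage_features

RUN = Path(__file__).resolve().parent.parent / "results" / "run"

logging.basicConfig(level=logging.INFO)
stage_features(load_config({"seed": 42}), RUN)

dist = pd.read_csv(RUN / "distance_test.tsv", sep="\t")
print("uORF-to-CDS distance:", dist.loc[0, "direction"],
      f"(p = {dist.loc[0, 'p_value']:.3g})")
kozak = pd.read_csv(RUN / "kozak_tests.tsv", sep="\t").set_index("position")
print(f"+4 position chi-squared p = {kozak.at[4, 'p_value']:.3g}")
te = json.loads((RUN / "te_test.json").read_text())
print(f"TE comparison: {te['direction']} (p = {te['p_value']:.3g}, "
      f"n = {te['n_translated']}/{te['n_untranslated']})")
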