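"""Transcription-factor / target co-expression network.

An edge is kept when the Pearson correlation of the two genes'
expression profiles across samples exceeds ``r_min`` (signed, r > 0.7
by default; ``absolute=True`` switches to |r|) and the two-sided
t-transform p-value (n-2 df) is below ``p_max``.  No multiple-testing
correction by default; a BH option exists.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

log = logging.getLogger(__name__)


class Edge(NamedTuple):
    tf_id: str
    target_id: str
    r: float
    p_value: float


def build_network(
    expr_matrix: pd.DataFrame,
    tf_ids,
    target_ids,
    r_min: float = 0.7,
    p_max: float = 0.05,
    absolute: bool = False,
    bh: bool = False,
) -> list[Edge]:
    """Correlate every TF against every target over samples and keep
    significant, highly correlated pairs.

    ``expr_matrix`` is genes x samples (>= 3 samples required).
    Zero-variance genes are skipped with a warning.  TF/target overlap
    is allowed but logged; self-pairs are never tested.
    """
    if expr_matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples for a correlation p-value")
    overlap = set(tf_ids) & set(target_ids)
    if overlap:
        log.info("%d genes appear as both TF and target", len(overlap))
    missing = (set(tf_ids) | set(target_ids)) - set(expr_matrix.index)
    if missing:
        raise KeyError(f"genes missing from matrix: {sorted(missing)[:5]}")
    candidates = []
    for tf in tf_ids:
        x = expr_matrix.loc[tf].to_numpy(dtype=float)
        if np.std(x) == 0:
            log.warning("TF %s has zero variance; skipped", tf)
            continue
        for tgt in target_ids:
            if tgt == tf:
                continue
            y = expr_matrix.loc[tgt].to_numpy(dtype=float)
            if np.std(y) == 0:
                log.warning("target %s has zero variance; skipped", tgt)
                continue
            res = sps.pearsonr(x, y)
            candidates.append(Edge(tf, tgt, float(res.statistic), float(res.pvalue)))
    if bh and candidates:
        adj = bh_adjust([e.p_value for e in candidates])
        candidates = [e._replace(p_value=float(q)) for e, q in zip(candidates, adj)]
    kept = [
        e for e in candidates
        if (abs(e.r) if absolute else e.r) > r_min and e.p_value < p_max
    ]
    return kept


def edges_frame(edges) -> pd.DataFrame:
    return pd.DataFrame(edges, columns=["tf_id", "target_id", "r", "p_value"])
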