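"""FPKM, translational efficiency, differential analysis and the
nine-quadrant multi-omics classification.

Differential testing uses a Welch t-test on log2-transformed values with
Benjamini-Hochberg correction across each layer.  A gene is "changed"
for the quadrant grid when FDR < alpha and |log2FC| >= 1 (boundary
inclusive); the DEG-list convention (fold-change >= 1.5) is a separate,
layer-scoped default.  The protein layer uses the raw p-value with a
fold-change >= 1.5 (or <= 0.67) cut, matching its source convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import CountTable, SampleSheet
from .stats import bh_adjust

log = logging.getLogger(__name__)

LAYERS = ("transcription", "translation", "te", "protein")

#: quadrant letters indexed by (transcription state, translation state),
#: states in {down, ns, up}; C=(up,up) and E=(ns,ns) are fixed by the
#: nine-quadrant convention, the rest is this package's declared grid.
QUADRANT_GRID = {
    ("down", "up"): "A", ("ns", "up"): "B", ("up", "up"): "C",
    ("down", "ns"): "D", ("ns", "ns"): "E", ("up", "ns"): "F",
    ("down", "down"): "G", ("ns", "down"): "H", ("up", "down"): "I",
}


def fpkm(count: float, feature_length_nt: float, library_size: float) -> float:
    """Fragments per kilobase of feature per million mapped fragments."""
    if feature_length_nt <= 0:
        raise ValueError("feature length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count / (feature_length_nt / 1e3 * library_size / 1e6)


def fpkm_table(
    counts: CountTable,
    feature_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM for every feature x sample in a count table.

    ``library_sizes`` overrides the table's own sizes, e.g. with
    :func:`median_ratio_library_sizes` for differential comparisons.
    """
    lengths = feature_lengths.reindex(counts.features)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise KeyError(f"no length for features {missing}")
    sizes = counts.library_sizes if library_sizes is None else library_sizes[counts.samples]
    denom = np.outer(lengths / 1e3, sizes / 1e6)
    return counts.counts / denom


def median_ratio_library_sizes(counts: CountTable) -> pd.Series:
    """Effective library sizes from median-of-ratios size factors.

    Raw column totals are distorted by a handful of strongly changed
    genes (compositional bias), which shifts the fold-change of every
    unchanged gene; the median ratio to the per-gene geometric mean is
    robust to that.  Sizes are scaled so their geometric mean matches
    the raw library sizes'.
    """
    mat = counts.counts.to_numpy(dtype=float)
    keep = (mat > 0).all(axis=1)
    if keep.sum() < 10:
        log.warning("too few all-positive genes for size factors; using raw sizes")
        return counts.library_sizes.astype(float)
    logs = np.log(mat[keep])
    ratios = logs - logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(ratios, axis=0))
    scale = np.exp(np.mean(np.log(counts.library_sizes.astype(float))))
    return pd.Series(sf * scale, index=counts.samples)


def translational_efficiency(rpf_fpkm, rna_fpkm):
    """TE = footprint FPKM / mRNA FPKM; undefined where rna_fpkm == 0."""
    if np.isscalar(rpf_fpkm):
        if rna_fpkm == 0:
            raise ValueError("TE undefined for rna_fpkm == 0")
        return rpf_fpkm / rna_fpkm
    rpf = pd.DataFrame(rpf_fpkm)
    rna = pd.DataFrame(rna_fpkm)
    te = rpf / rna.where(rna > 0)
    n_dropped = int(te.isna().all(axis=1).sum())
    if n_dropped:
        log.info("%d genes with zero RNA FPKM excluded from TE", n_dropped)
    return te


def te_table(
    rna_counts: CountTable,
    rpf_counts: CountTable,
    samples: SampleSheet,
    transcript_lengths: pd.Series,
    cds_lengths: pd.Series,
    rna_sizes: pd.Series | None = None,
    rpf_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene, per-replicate TE: CDS footprint FPKM over transcript
    RNA FPKM, pairing rna/ribo samples by condition and replicate."""
    rna_f = fpkm_table(rna_counts, transcript_lengths, library_sizes=rna_sizes)
    rpf_f = fpkm_table(rpf_counts, cds_lengths, library_sizes=rpf_sizes)
    cols = {}
    t = samples.table
    for (cond, rep), grp in t.groupby(["condition", "replicate"], sort=False):
        rna_ids = grp[grp["assay"] == "rna"]["sample_id"]
        ribo_ids = grp[grp["assay"] == "ribo"]["sample_id"]
        if len(rna_ids) != 1 or len(ribo_ids) != 1:
            continue
        rna_col = rna_f[rna_ids.iloc[0]]
        ribo_col = rpf_f[ribo_ids.iloc[0]]
        cols[f"{cond}_te_{rep}"] = ribo_col / rna_col.where(rna_col > 0)
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class DiffResult:
    gene_id: str
    layer: str
    log2fc: float
    p_value: float
    fdr: float
    significant: bool


def differential(
    values: pd.DataFrame,
    samples: SampleSheet,
    layer: str,
    alpha: float = 0.05,
    fc_min: float = 1.5,
    conditions: tuple[str, str] | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-gene differential analysis between the two conditions.

    ``values`` holds genes x samples abundances on the layer's natural
    scale (FPKM, TE or protein abundance); they are tested by Welch's
    t-test on log2(x+1) (or log2 x when ``log_transform`` is False, the
    TE convention).  Fold-change is condition2 over condition1.  The
    protein layer is judged on raw p-values, other layers on BH FDR.

    Returns a DataFrame (gene_id, layer, log2fc, p_value, fdr,
    significant), genes with no finite replicate values excluded.
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}")
    if conditions is None:
        conditions = tuple(samples.conditions[:2])
    c1, c2 = conditions
    col_cond = {}
    for col in values.columns:
        for _, row in samples.table.iterrows():
            if row["sample_id"] == col or col.startswith(f"{row['condition']}_"):
                col_cond[col] = row["condition"]
                break
    g1 = [c for c in values.columns if col_cond.get(c) == c1]
    g2 = [c for c in values.columns if col_cond.get(c) == c2]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 replicates per condition")
    x = values[g1].to_numpy(dtype=float)
    y = values[g2].to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.log2(x)
            y = np.log2(y)
        x[~np.isfinite(x)] = np.nan
        y[~np.isfinite(y)] = np.nan
    ok = (np.sum(np.isfinite(x), axis=1) >= 2) & (np.sum(np.isfinite(y), axis=1) >= 2)
    lfc = np.nanmean(y, axis=1) - np.nanmean(x, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = sps.ttest_ind(y, x, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(p, dtype=float)
    # zero variance in both groups: equal means -> p 1, unequal -> p 0
    degenerate = ~np.isfinite(p)
    p[degenerate & (np.abs(lfc) < 1e-12)] = 1.0
    p[degenerate & (np.abs(lfc) >= 1e-12)] = 0.0
    genes = values.index[ok]
    lfc, p = lfc[ok], p[ok]
    fdr = bh_adjust(p)
    crit = p < alpha if layer == "protein" else fdr < alpha
    significant = crit & (np.abs(lfc) >= np.log2(fc_min))
    return pd.DataFrame({
        "gene_id": genes,
        "layer": layer,
        "log2fc": lfc,
        "p_value": p,
        "fdr": fdr,
        "significant": significant,
    }).reset_index(drop=True)


def _state(log2fc: float, fdr: float, lfc_cut: float, alpha: float) -> str:
    if fdr < alpha and log2fc >= lfc_cut:
        return "up"
    if fdr < alpha and log2fc <= -lfc_cut:
        return "down"
    return "ns"


def quadrant_classify(
    diff_tx: pd.DataFrame,
    diff_tl: pd.DataFrame,
    lfc_cut: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Nine-quadrant joint classification of per-gene change states at
    two omic layers (boundary inclusive: |log2fc| == cut counts as
    changed; fdr == alpha does not)."""
    tx = diff_tx.set_index("gene_id")
    tl = diff_tl.set_index("gene_id")
    common = tx.index.intersection(tl.index)
    skipped = len(set(tx.index).symmetric_difference(tl.index))
    if skipped:
        log.info("%d genes missing one layer; excluded from quadrants", skipped)
    rows = []
    for gene in common:
        s_tx = _state(tx.at[gene, "log2fc"], tx.at[gene, "fdr"], lfc_cut, alpha)
        s_tl = _state(tl.at[gene, "log2fc"], tl.at[gene, "fdr"], lfc_cut, alpha)
        rows.append((gene, s_tx, s_tl, QUADRANT_GRID[(s_tx, s_tl)]))
    return pd.DataFrame(rows, columns=["gene_id", "tx_state", "tl_state", "label"])


def ddct(
    target_ct_treat: float,
    ref_ct_treat: float,
    target_ct_ctrl: float,
    ref_ct_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method."""
    ddct_val = (target_ct_treat - ref_ct_treat) - (target_ct_ctrl - ref_ct_ctrl)
    return float(2.0 ** -ddct_val)
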