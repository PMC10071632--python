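"""Feature comparisons between translated and untranslated uORFs:
length spectrum, reinitiation distance, Kozak-context base composition,
flanking GC content, and the cumulative TE curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import chi_squared, ecdf, rank_sum_test

log = logging.getLogger(__name__)

#: Kozak-style positions for an 11-nt -6..+5 flank (A of ATG = +1, no 0)
FLANK_POSITIONS = (-6, -5, -4, -3, -2, -1, 1, 2, 3, 4, 5)
ATG_POSITIONS = (1, 2, 3)


def length_summary(uorf_lengths, cutoff: int = 160) -> tuple[pd.DataFrame, float]:
    """Length histogram (30-nt bins) plus the fraction of uORFs strictly
    shorter than ``cutoff`` (the headline '80% shorter than 160 nt'
    style statistic)."""
    lengths = np.asarray(list(uorf_lengths), dtype=int)
    if lengths.size == 0:
        raise ValueError("no uORFs")
    edges = np.arange(0, lengths.max() + 30, 30)
    counts, _ = np.histogram(lengths, bins=edges)
    hist = pd.DataFrame({
        "bin_start": edges[:-1],
        "bin_end": edges[1:],
        "count": counts,
    })
    return hist, float((lengths < cutoff).mean())


@dataclass(frozen=True)
class FeatureComparison:
    feature: str
    n_translated: int
    n_untranslated: int
    statistic: float
    p_value: float
    direction: str  # which group has the larger values


def compare_distance(translated_distances, untranslated_distances) -> FeatureComparison:
    """Two-sided Wilcoxon rank-sum comparison of normalized uORF-to-CDS
    reinitiation distances between translated and untranslated uORFs."""
    x = np.asarray(list(translated_distances), dtype=float)
    y = np.asarray(list(untranslated_distances), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    u, p = rank_sum_test(x, y)
    direction = "translated larger" if np.median(x) > np.median(y) else "translated smaller"
    if np.median(x) == np.median(y):
        direction = "none"
    return FeatureComparison("normalized_distance", x.size, y.size, u, p, direction)


@dataclass(frozen=True)
class PositionTestResult:
    position: int
    counts_translated: dict
    counts_untranslated: dict
    chi2: float
    p_value: float


def _base_counts(flanks, idx: int) -> dict[str, int]:
    counts = {b: 0 for b in "ACGT"}
    for f in flanks:
        if idx < len(f) and f[idx] in counts:
            counts[f[idx]] += 1
    return counts


def kozak_position_test(translated_flanks, untranslated_flanks) -> list[PositionTestResult]:
    """Per-position chi-squared test (2 groups x 4 bases, no continuity
    correction) of base composition around the uORF start codon.

    Flanks are -6..+5 strings aligned on the ATG; the ATG positions
    (+1..+3) are skipped, N bases are excluded.
    """
    results = []
    for idx, pos in enumerate(FLANK_POSITIONS):
        if pos in ATG_POSITIONS:
            continue
        ct = _base_counts(translated_flanks, idx)
        cu = _base_counts(untranslated_flanks, idx)
        table = np.array([[ct[b] for b in "ACGT"], [cu[b] for b in "ACGT"]], dtype=float)
        if table.sum() == 0:
            log.warning("position %+d all-N; skipped", pos)
            continue
        stat, p = chi_squared(table)
        results.append(PositionTestResult(pos, ct, cu, stat, p))
    return results


def gc_flank_profile(flanks_by_group: dict[str, list[str]], window: int = 25) -> pd.DataFrame:
    """Per-position G+C fraction for each group over +-window nt around
    the start codon.  Flank strings must be centred: 2*window + 3 nt
    with the ATG in the middle; N positions are ignored."""
    positions = [p for p in range(-window, window + 4) if p != 0]
    rows = []
    for pos in positions:
        row = {"position": pos}
        for group, flanks in flanks_by_group.items():
            idx = pos + window if pos < 0 else pos + window - 1
            gc = tot = 0
            for f in flanks:
                if idx < len(f) and f[idx] in "ACGT":
                    tot += 1
                    gc += f[idx] in "GC"
            row[group] = gc / tot if tot else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def center_flank(sequence: str, atg_start: int, window: int = 25) -> str:
    """2*window+3 nt around an ATG, N-padded at the transcript ends."""
    out = []
    for i in range(atg_start - window, atg_start + 3 + window):
        out.append(sequence[i] if 0 <= i < len(sequence) else "N")
    return "".join(out)


@dataclass
class EcdfCurve:
    group: str
    values: np.ndarray
    cumulative: np.ndarray


def cumulative_te_curve(
    te_by_gene: pd.Series,
    translated_flag: pd.Series,
    te_min: float = 0.5,
) -> tuple[list[EcdfCurve], FeatureComparison]:
    """Cumulative TE distributions for genes with versus without a
    translated uORF, restricted to genes with TE > ``te_min``, plus the
    two-sided rank-sum comparison."""
    te = te_by_gene.dropna()
    te = te[te > te_min]
    flag = translated_flag.reindex(te.index).astype(bool)
    x = te[flag].to_numpy()
    y = te[~flag].to_numpy()
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty after the TE filter")
    u, p = rank_sum_test(x, y)
    direction = "translated lower" if np.median(x) < np.median(y) else "translated higher"
    if np.median(x) == np.median(y):
        direction = "none"
    curves = []
    for name, vals in (("translated", x), ("untranslated", y)):
        v, frac = ecdf(vals)
        curves.append(EcdfCurve(name, v, frac))
    comp = FeatureComparison("te", x.size, y.size, u, p, direction)
    return curves, comp
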