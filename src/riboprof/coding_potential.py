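"""Coding-potential statistics and translated-ORF calling.

Four statistics per candidate ORF:

* **ORFscore** — a signed log2-scaled chi-squared-like measure of how
  strongly P-sites favour the ORF's own reading frame: with
  ``M = (F0+F1+F2)/3``, ``score = log2(1 + sum_i (F_i - M)^2 / M)``,
  negated when frame 0 does not hold the unique plurality.
* **RRS (ribosome release score)** — footprint density inside the ORF
  versus downstream of its stop, normalised by the same RNA ratio:
  ``((rpf_in+1)/(rpf_down+1)) / ((rna_in+1)/(rna_down+1))``.
* **Fickett TESTCODE** — codon-position asymmetry and base composition
  mapped through the published probability tables and weights.
* **Hexamer score** — mean natural-log likelihood ratio of in-frame
  hexamer frequencies under a coding versus a noncoding model.

An ORF is called translated when every score strictly exceeds the 95th
percentile of that score on a null ORF set (rule configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import TranscriptModel, as_psite_frame
from .orf_discovery import OrfRecord
from .stats import threshold_percentile

log = logging.getLogger(__name__)

SCORE_NAMES = ("orfscore", "rrs", "fickett", "hexamer")


# ---------------------------------------------------------------------------
# ORFscore


def orfscore(frame_counts) -> float:
    """Signed ORFscore from the (F0, F1, F2) P-site frame counts."""
    f = np.asarray(frame_counts, dtype=float)
    if f.shape != (3,):
        raise ValueError("frame_counts must be a triple")
    if (f < 0).any():
        raise ValueError("negative frame counts")
    total = f.sum()
    if total == 0:
        return 0.0
    m = total / 3.0
    score = float(np.log2(1.0 + ((f - m) ** 2 / m).sum()))
    if not (f[0] > f[1] and f[0] > f[2]):
        score = -score
    return score


# ---------------------------------------------------------------------------
# Ribosome release score


def rrs(rpf_in_orf: float, rpf_downstream: float, rna_in_orf: float, rna_downstream: float) -> float:
    """Ratio-of-ratios release score with +1 pseudocounts."""
    if min(rpf_in_orf, rpf_downstream, rna_in_orf, rna_downstream) < 0:
        raise ValueError("negative counts")
    return ((rpf_in_orf + 1.0) / (rpf_downstream + 1.0)) / (
        (rna_in_orf + 1.0) / (rna_downstream + 1.0)
    )


# ---------------------------------------------------------------------------
# Fickett TESTCODE
#
# Published probability lookup tables and weights of the TESTCODE
# statistic (Fickett 1982): for each base, the position parameter
# max(c1,c2,c3)/(min(c1,c2,c3)+1) and the composition fraction are
# mapped to P(coding) values and combined with the published weights.

_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_EDGES = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_EDGES = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17]


def _lookup(value: float, edges, probs) -> float:
    for i, edge in enumerate(edges):
        if value >= edge:
            return probs[i]
    return probs[len(edges)]


def fickett_position_parameter(sequence: str, base: str) -> float:
    """max/(min+1) of the base's counts at the three codon positions."""
    counts = [sequence[i::3].count(base) for i in range(3)]
    return max(counts) / (min(counts) + 1.0)


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE statistic of a nucleotide sequence.

    Length-normalised (a sequence and its exact repetition score
    identically); sequences shorter than ~200 nt are accepted with a
    warning since small-ORF candidates are short by nature.  More than
    10% non-ACGT characters is an error.
    """
    seq = sequence.upper()
    if len(seq) == 0:
        raise ValueError("empty sequence")
    n_bad = sum(1 for ch in seq if ch not in "ACGT")
    if n_bad / len(seq) > 0.10:
        raise ValueError(f"{n_bad}/{len(seq)} non-ACGT characters")
    if len(seq) < 200:
        log.debug("Fickett score on short sequence (%d nt)", len(seq))
    score = 0.0
    for base in "ACGT":
        pos_param = fickett_position_parameter(seq, base)
        content = seq.count(base) / len(seq)
        score += _lookup(pos_param, _POSITION_EDGES, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        score += _lookup(content, _CONTENT_EDGES, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


# ---------------------------------------------------------------------------
# Hexamer usage score


def _hexamer_counts(seqs, pseudo: float = 1.0) -> pd.Series:
    from itertools import product

    idx = ["".join(p) for p in product("ACGT", repeat=6)]
    counts = dict.fromkeys(idx, pseudo)
    for s in seqs:
        s = s.upper()
        for i in range(0, len(s) - 5, 3):
            h = s[i : i + 6]
            if h in counts:
                counts[h] += 1.0
    return pd.Series(counts, dtype=float)


def train_hexamer(coding_seqs, noncoding_seqs) -> pd.DataFrame:
    """In-frame hexamer frequency table under coding and noncoding
    models, with additive (+1) smoothing over all 4096 hexamers."""
    if not coding_seqs or not noncoding_seqs:
        raise ValueError("both training sets must be non-empty")
    fc = _hexamer_counts(coding_seqs)
    fn = _hexamer_counts(noncoding_seqs)
    return pd.DataFrame({
        "f_coding": fc / fc.sum(),
        "f_noncoding": fn / fn.sum(),
    })


_LLR_CACHE: dict[int, dict[str, float]] = {}


def _llr_of(table: pd.DataFrame) -> dict[str, float]:
    key = id(table)
    if key not in _LLR_CACHE:
        _LLR_CACHE.clear()  # keep at most one table alive
        _LLR_CACHE[key] = dict(np.log(table["f_coding"] / table["f_noncoding"]))
    return _LLR_CACHE[key]


def hexamer_score(sequence: str, table: pd.DataFrame) -> float:
    """Mean ln(f_coding/f_noncoding) over the sequence's in-frame
    hexamers; 0 (with a warning) for sequences shorter than 6 nt."""
    seq = sequence.upper()
    if len(seq) < 6:
        log.warning("sequence shorter than 6 nt; hexamer score 0")
        return 0.0
    llr = _llr_of(table)
    vals = [
        llr[seq[i : i + 6]]
        for i in range(0, len(seq) - 5, 3)
        if seq[i : i + 6] in llr
    ]
    if not vals:
        return 0.0
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Scoring candidate ORFs


@dataclass(frozen=True)
class CodingScores:
    orf_id: str
    category: str
    orfscore: float
    rrs: float
    fickett: float
    hexamer: float
    rpf_in_orf: int
    low_coverage: bool


def _interval_counts(pos: np.ndarray, cnt: np.ndarray, lo: int, hi: int) -> float:
    if pos.size == 0 or lo >= hi:
        return 0.0
    keep = (pos >= lo) & (pos < hi)
    return float(cnt[keep].sum())


def _frame_counts(pos: np.ndarray, cnt: np.ndarray, start: int, stop_end: int) -> np.ndarray:
    out = np.zeros(3)
    keep = (pos >= start) & (pos < stop_end)
    for p, c in zip(pos[keep], cnt[keep]):
        out[(p - start) % 3] += c
    return out


def downstream_window(orf: OrfRecord, model: TranscriptModel) -> tuple[int, int]:
    """Length-matched release window after the stop codon, truncated at
    the end of the ORF's host region."""
    region_end = {
        "uORF": model.cds_start,
        "mORF": model.length,
        "dORF": model.length,
    }[orf.category]
    return orf.stop_end, min(orf.stop_end + orf.length, region_end)


def score_orfs(
    orfs,
    psites,
    rna_positions: pd.DataFrame,
    models,
    hexamer_table: pd.DataFrame | None = None,
    hexamer_seed: int = 0,
) -> list[CodingScores]:
    """Compute the four coding-potential statistics for each ORF.

    ``rna_positions`` is a positional RNA fragment table
    (transcript_id, position, count).  If no hexamer table is supplied,
    one is trained on the annotated CDSs versus their nucleotide
    shuffles (seeded, deterministic).
    """
    mm = {m.transcript_id: m for m in models}
    if hexamer_table is None:
        hexamer_table = default_hexamer_table(models, seed=hexamer_seed)
    ps = as_psite_frame(psites)
    ps_by_tid = {t: g for t, g in ps.groupby("transcript_id")}
    rna_by_tid = {t: g for t, g in rna_positions.groupby("transcript_id")} if len(rna_positions) else {}
    out: list[CodingScores] = []
    for orf in orfs:
        model = mm[orf.transcript_id]
        g = ps_by_tid.get(orf.transcript_id)
        pos = g["position"].to_numpy() if g is not None else np.array([], dtype=int)
        cnt = g["count"].to_numpy() if g is not None else np.array([], dtype=int)
        r = rna_by_tid.get(orf.transcript_id)
        rpos = r["position"].to_numpy() if r is not None else np.array([], dtype=int)
        rcnt = r["count"].to_numpy() if r is not None else np.array([], dtype=int)

        frames = _frame_counts(pos, cnt, orf.start, orf.stop_end)
        d_lo, d_hi = downstream_window(orf, model)
        seq = model.sequence[orf.start : orf.stop_end]
        rpf_in = frames.sum()
        score = CodingScores(
            orf_id=orf.orf_id,
            category=orf.category,
            orfscore=orfscore(frames),
            rrs=rrs(
                rpf_in,
                _interval_counts(pos, cnt, d_lo, d_hi),
                _interval_counts(rpos, rcnt, orf.start, orf.stop_end),
                _interval_counts(rpos, rcnt, d_lo, d_hi),
            ),
            fickett=fickett_score(seq),
            hexamer=hexamer_score(seq, hexamer_table),
            rpf_in_orf=int(rpf_in),
            low_coverage=rpf_in == 0,
        )
        out.append(score)
    return out


def default_hexamer_table(models, seed: int = 0) -> pd.DataFrame:
    """Hexamer table trained on annotated CDSs (coding) versus their
    per-sequence nucleotide shuffles (noncoding)."""
    rng = np.random.default_rng(seed)
    coding = [m.sequence[m.cds_start : m.cds_end] for m in models]
    noncoding = []
    for s in coding:
        arr = np.array(list(s))
        rng.shuffle(arr)
        noncoding.append("".join(arr))
    return train_hexamer(coding, noncoding)


def null_scores(
    orfs,
    scores: list[CodingScores],
    models,
    hexamer_table: pd.DataFrame,
    seed: int = 0,
    min_null: int = 20,
) -> pd.DataFrame:
    """Null score distributions for thresholding.

    ORFscore and RRS nulls come from 3'UTR ORFs (dORF candidates, which
    lack initiation under the generative model); Fickett and hexamer
    nulls from per-sequence nucleotide shuffles of the annotated CDSs —
    noncoding-composition sequences long enough for the two statistics
    to be stable (both are strongly length-noisy below ~20 codons).
    Columns may have different lengths (NaN padded).
    """
    rng = np.random.default_rng(seed)
    by_id = {s.orf_id: s for s in scores}
    d = [by_id[o.orf_id] for o in orfs if o.category == "dORF" and o.orf_id in by_id]
    if len(d) < min_null:
        raise ValueError(f"null set has {len(d)} ORFs; need >= {min_null}")
    shuffled_fickett = []
    shuffled_hexamer = []
    for m in models:
        seq = m.sequence[m.cds_start : m.cds_end]
        arr = np.array(list(seq))
        rng.shuffle(arr)
        sh = "".join(arr)
        shuffled_fickett.append(fickett_score(sh))
        shuffled_hexamer.append(hexamer_score(sh, hexamer_table))
    return pd.DataFrame({
        "orfscore": pd.Series([s.orfscore for s in d]),
        "rrs": pd.Series([s.rrs for s in d]),
        "fickett": pd.Series(shuffled_fickett),
        "hexamer": pd.Series(shuffled_hexamer),
    })


@dataclass(frozen=True)
class TranslationCall:
    orf_id: str
    translated: bool
    passing_scores: tuple[str, ...]


def call_translated(
    scores: list[CodingScores],
    null: pd.DataFrame,
    rule: str = "all",
    percentile: float = 95.0,
) -> tuple[list[TranslationCall], dict[str, float]]:
    """Threshold each score at the given percentile of its null
    distribution and call ORFs translated.

    rule "all": every score strictly exceeds its threshold (default);
    rule "any": at least one does.  Returns (calls, thresholds).
    """
    if rule not in ("all", "any"):
        raise ValueError(f"unknown rule {rule!r}")
    thresholds = {}
    for name in SCORE_NAMES:
        col = null[name].dropna()
        if len(col) < 20:
            raise ValueError(f"null set for {name} has {len(col)} values; need >= 20")
        thresholds[name] = threshold_percentile(col, percentile)
    calls = []
    for s in scores:
        passing = tuple(
            name for name in SCORE_NAMES if getattr(s, name) > thresholds[name]
        )
        ok = len(passing) == 4 if rule == "all" else len(passing) >= 1
        calls.append(TranslationCall(s.orf_id, ok, passing))
    return calls, thresholds
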