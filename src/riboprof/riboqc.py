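"""Footprint quality metrics: length spectrum, reading-frame fractions,
metagene profiles around start/stop codons, region partitioning, and
P-site offset inference from 5'-end records.

Periodicity is reported as the fraction of CDS-internal P-sites in the
annotated frame (frame 0), the same robustness measure the underlying
study design uses; no Fourier statistic is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import TranscriptModel, as_psite_frame

log = logging.getLogger(__name__)

OFFSET_SEARCH = (8, 20)  # nt upstream of the start codon scanned for 5'-end peaks
MIN_READS_PER_LENGTH = 50


def length_distribution(psites) -> pd.DataFrame:
    """Count-weighted footprint-length histogram with fractions.

    Returns a DataFrame (read_length, count, fraction); empty input
    yields an empty histogram with a warning.
    """
    df = as_psite_frame(psites)
    if df.empty:
        log.warning("no P-site records; empty length histogram")
        return pd.DataFrame(columns=["read_length", "count", "fraction"])
    hist = df.groupby("read_length")["count"].sum().reset_index()
    hist["fraction"] = hist["count"] / hist["count"].sum()
    return hist


def _model_map(models) -> dict[str, TranscriptModel]:
    return {m.transcript_id: m for m in models}


def _annotate(df: pd.DataFrame, models) -> pd.DataFrame:
    """Attach cds_start/cds_end/length columns to a P-site frame."""
    mm = _model_map(models)
    missing = set(df["transcript_id"]) - set(mm)
    if missing:
        raise KeyError(f"no transcript model for {sorted(missing)[:5]}")
    df = df.copy()
    df["cds_start"] = df["transcript_id"].map({k: m.cds_start for k, m in mm.items()})
    df["cds_end"] = df["transcript_id"].map({k: m.cds_end for k, m in mm.items()})
    df["tx_len"] = df["transcript_id"].map({k: m.length for k, m in mm.items()})
    return df


def frame_fractions(psites, models, region: str = "cds") -> tuple[float, float, float]:
    """Count-weighted fraction of P-sites in each reading frame
    ((position - cds_start) mod 3) over CDS-internal sites."""
    df = _annotate(as_psite_frame(psites), models)
    if region != "cds":
        raise ValueError("only CDS frame fractions are defined")
    df = df[(df["position"] >= df["cds_start"]) & (df["position"] < df["cds_end"])]
    if df.empty:
        log.warning("no CDS-internal P-sites; frame fractions undefined")
        return (float("nan"),) * 3
    frame = (df["position"] - df["cds_start"]) % 3
    totals = df.groupby(frame)["count"].sum()
    out = np.array([totals.get(f, 0) for f in range(3)], dtype=float)
    out /= out.sum()
    return tuple(out)


def metagene(psites, models, anchor: str = "start", window: tuple[int, int] = (-30, 60)) -> pd.DataFrame:
    """Counts binned by position relative to the start (or stop) codon
    and by frame (relative position mod 3).

    Returns a DataFrame indexed by relative position with columns
    frame0/frame1/frame2, covering the full window (zeros included).
    """
    if anchor not in ("start", "stop"):
        raise ValueError("anchor must be 'start' or 'stop'")
    df = _annotate(as_psite_frame(psites), models)
    lo, hi = window
    idx = np.arange(lo, hi + 1)
    out = pd.DataFrame(
        0, index=pd.Index(idx, name="rel_position"),
        columns=["frame0", "frame1", "frame2"],
    )
    if df.empty:
        return out
    anchor_pos = df["cds_start"] if anchor == "start" else df["cds_end"] - 3
    rel = df["position"] - anchor_pos
    keep = (rel >= lo) & (rel <= hi)
    rel, cnt = rel[keep], df["count"][keep]
    frame = rel % 3
    for f in range(3):
        sel = frame == f
        binned = pd.Series(cnt[sel].values, index=rel[sel].values).groupby(level=0).sum()
        out.loc[binned.index, f"frame{f}"] += binned.astype(int)
    return out


def region_fractions(psites, models) -> tuple[float, float, float]:
    """Fraction of P-site counts falling in the 5'UTR, CDS and 3'UTR."""
    df = _annotate(as_psite_frame(psites), models)
    if df.empty:
        return (float("nan"),) * 3
    in5 = df["position"] < df["cds_start"]
    incds = (~in5) & (df["position"] < df["cds_end"])
    totals = np.array([
        df["count"][in5].sum(),
        df["count"][incds].sum(),
        df["count"][~in5 & ~incds].sum(),
    ], dtype=float)
    return tuple(totals / totals.sum())


def region_counts_by_transcript(psites, models, region: str = "cds") -> pd.Series:
    """Per-transcript P-site count totals within one region; used to
    build the footprint count table for expression analysis."""
    df = _annotate(as_psite_frame(psites), models)
    if df.empty:
        return pd.Series(dtype=int)
    if region == "cds":
        keep = (df["position"] >= df["cds_start"]) & (df["position"] < df["cds_end"])
    elif region == "utr5":
        keep = df["position"] < df["cds_start"]
    elif region == "utr3":
        keep = df["position"] >= df["cds_end"]
    else:
        raise ValueError(f"unknown region {region!r}")
    return df[keep].groupby("transcript_id")["count"].sum()


@dataclass
class OffsetTable:
    """Per-read-length P-site offset (nt from the footprint 5' end)."""

    offsets: dict[int, int]

    def __getitem__(self, read_length: int) -> int:
        return self.offsets[read_length]


def infer_psite_offsets(five_prime_records, models) -> OffsetTable:
    """Infer the P-site offset for each read length from 5'-end records.

    For each length, the offset is the argmax over candidates 8..20 nt of
    the number of 5' ends lying exactly that far upstream of annotated
    start codons; ties break toward the smaller offset.  Lengths with
    fewer than 50 reads fall back to the global (all-length) offset.
    """
    df = _annotate(as_psite_frame(five_prime_records), models)
    lo, hi = OFFSET_SEARCH
    cands = np.arange(lo, hi + 1)

    def peak(sub: pd.DataFrame) -> np.ndarray:
        dist = sub["cds_start"] - sub["position"]
        scores = np.array([
            sub["count"][dist == o].sum() for o in cands
        ])
        return scores

    global_offset = int(cands[int(np.argmax(peak(df)))])
    offsets: dict[int, int] = {}
    for rl, sub in df.groupby("read_length"):
        if sub["count"].sum() < MIN_READS_PER_LENGTH:
            log.warning(
                "read length %d has %d reads (<%d); using global offset %d",
                rl, int(sub["count"].sum()), MIN_READS_PER_LENGTH, global_offset,
            )
            offsets[int(rl)] = global_offset
            continue
        offsets[int(rl)] = int(cands[int(np.argmax(peak(sub)))])
    return OffsetTable(offsets)


def apply_offsets(five_prime_records, table: OffsetTable) -> pd.DataFrame:
    """Convert 5'-end records to P-site records using an offset table."""
    df = as_psite_frame(five_prime_records).copy()
    df["position"] = df["position"] + df["read_length"].map(table.offsets).astype(int)
    return df
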