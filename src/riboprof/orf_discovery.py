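"""Enumeration of main, upstream and downstream open reading frames.

mORFs come straight from the annotation; uORF/dORF candidates are every
ATG in the 5'UTR / 3'UTR with an in-frame stop codon, mirroring an
ORFfinder-style scan of the untranslated regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_formats import TranscriptModel

log = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
DEFAULT_MIN_LEN = 9  # ATG + >=1 codon + stop


@dataclass(frozen=True)
class OrfRecord:
    """A candidate open reading frame in transcript coordinates.

    ``length`` runs from the A of the start codon through the stop codon
    inclusive; ``frame_vs_morf`` is the frame offset relative to the
    annotated start; ``normalized_distance`` (uORFs only) is the
    reinitiation distance from the uORF stop to the mORF ATG as a
    fraction of the 5'UTR, clipped to [0, 1].
    """

    orf_id: str
    transcript_id: str
    category: str  # mORF | uORF | dORF
    start: int
    stop_end: int
    length: int
    frame_vs_morf: int
    normalized_distance: float | None
    flank_sequence: str


def flank(sequence: str, atg_start: int, up: int = 6, down: int = 5) -> str:
    """Bases -up..+down around an ATG (Kozak numbering: A of ATG = +1),
    N-padded at transcript ends.  The default -6..+5 window is 11 nt with
    the ATG at offsets 6..8."""
    out = []
    for i in range(atg_start - up, atg_start + down):
        out.append(sequence[i] if 0 <= i < len(sequence) else "N")
    return "".join(out)


def _scan_region(seq: str, lo: int, hi_scan: int, start_codons) -> list[tuple[int, int]]:
    """Yield (start, stop_end) for every start codon in [lo, hi_scan)
    with an in-frame stop anywhere downstream in ``seq``."""
    hits = []
    for i in range(lo, hi_scan - 2):
        if seq[i : i + 3] not in start_codons:
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in STOP_CODONS:
                hits.append((i, j + 3))
                break
    return hits


def uorf_distance(stop_end: int, model: TranscriptModel) -> float:
    """Reinitiation distance from the uORF stop to the mORF ATG, as a
    fraction of the 5'UTR length, clipped to [0, 1] for uORFs whose stop
    extends past the annotated start."""
    if model.utr5_len == 0:
        raise ValueError(f"{model.transcript_id}: no 5'UTR, distance undefined")
    d = (model.cds_start - stop_end) / model.utr5_len
    return min(1.0, max(0.0, d))


def enumerate_orfs(
    model: TranscriptModel,
    min_len: int = DEFAULT_MIN_LEN,
    start_codons: frozenset[str] | set[str] = frozenset({"ATG"}),
    overlap_policy: str = "exclude",
) -> list[OrfRecord]:
    """All ORF records for one transcript: the annotated mORF, every
    qualifying uORF in the 5'UTR and every dORF in the 3'UTR.

    ``overlap_policy`` controls uORFs whose in-frame stop lies beyond
    the annotated start: "exclude" drops them (default, keeps uORF/mORF
    footprint assignment unambiguous), "clip" keeps them with
    normalized_distance 0.
    """
    if overlap_policy not in ("exclude", "clip"):
        raise ValueError(f"unknown overlap_policy {overlap_policy!r}")
    seq = model.sequence
    if len(seq) < model.cds_end:
        raise ValueError(f"{model.transcript_id}: sequence shorter than annotation")
    records: list[OrfRecord] = []

    def add(category: str, start: int, stop_end: int) -> None:
        length = stop_end - start
        dist = None
        if category == "uORF":
            dist = uorf_distance(stop_end, model)
        records.append(
            OrfRecord(
                orf_id=f"{model.transcript_id}:{category}:{start}",
                transcript_id=model.transcript_id,
                category=category,
                start=start,
                stop_end=stop_end,
                length=length,
                frame_vs_morf=(start - model.cds_start) % 3,
                normalized_distance=dist,
                flank_sequence=flank(seq, start),
            )
        )

    add("mORF", model.cds_start, model.cds_end)
    # uORFs: every start codon strictly upstream of the annotated ATG
    for start, stop_end in _scan_region(seq, 0, model.cds_start, start_codons):
        if stop_end - start < min_len:
            continue
        if stop_end > model.cds_start and overlap_policy == "exclude":
            continue
        add("uORF", start, stop_end)
    # dORFs: start at or beyond the stop of the annotated ORF
    for start, stop_end in _scan_region(seq, model.cds_end, model.length, start_codons):
        if stop_end - start < min_len:
            continue
        add("dORF", start, stop_end)
    return records


def enumerate_all(models, **kwargs) -> list[OrfRecord]:
    out: list[OrfRecord] = []
    for m in models:
        out.extend(enumerate_orfs(m, **kwargs))
    return out
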