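"""Readers, writers and core domain types.

Every downstream module works in *transcript space*: coordinates are
0-based, half-open, and already strand-resolved (the stored sequence is
the mature transcript read 5'->3').  The P-site position denotes the
first nucleotide of the decoded codon, so the reading frame of a P-site
relative to the annotated coding region is simply
``(position - cds_start) % 3``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

PSITE_COLUMNS = ["transcript_id", "position", "read_length", "count"]

#: bounds on plausible ribosome-footprint lengths (nt)
DEFAULT_READ_LENGTH_BOUNDS = (17, 40)


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript's 5'UTR / CDS / 3'UTR geometry in transcript coordinates.

    ``cds_start`` is the A of the annotated start codon (0-based);
    ``cds_end`` is one past the stop codon, so ``cds_end - cds_start`` is
    a multiple of 3 and includes the stop codon.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"outside transcript of length {len(self.sequence)}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length "
                f"{self.cds_end - self.cds_start} not a multiple of 3"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def utr5_len(self) -> int:
        return self.cds_start

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def utr3_len(self) -> int:
        return self.length - self.cds_end

    def region_of(self, position: int) -> str:
        """Assign a transcript position to 'utr5', 'cds' or 'utr3'."""
        if not 0 <= position < self.length:
            raise ValueError(f"position {position} outside {self.transcript_id}")
        if position < self.cds_start:
            return "utr5"
        if position < self.cds_end:
            return "cds"
        return "utr3"


class PsiteRecord(NamedTuple):
    """One ribosome P-site observation: the footprint's decoded-codon
    position on a transcript, the footprint length, and how many
    identical footprints were seen."""

    transcript_id: str
    position: int
    read_length: int
    count: int


def as_psite_frame(psites) -> pd.DataFrame:
    """Coerce a list of :class:`PsiteRecord` (or a matching DataFrame)
    to the canonical P-site DataFrame."""
    if isinstance(psites, pd.DataFrame):
        missing = [c for c in PSITE_COLUMNS if c not in psites.columns]
        if missing:
            raise ValueError(f"P-site frame missing columns {missing}")
        return psites[PSITE_COLUMNS].reset_index(drop=True)
    return pd.DataFrame(list(psites), columns=PSITE_COLUMNS)


@dataclass
class CountTable:
    """Feature x sample matrix of non-negative integer counts, plus
    per-sample library sizes (defaults to the column sums)."""

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative entries in count table")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        else:
            self.library_sizes = pd.Series(self.library_sizes)[self.counts.columns]
            short = self.library_sizes < self.counts.sum(axis=0)
            if short.any():
                bad = list(self.library_sizes.index[short])
                raise ValueError(f"library size below assigned counts for {bad}")

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        return cls(df)


@dataclass
class SampleSheet:
    """Sample metadata: condition label, assay layer and replicate index."""

    table: pd.DataFrame

    REQUIRED = ["sample_id", "condition", "assay", "replicate"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns {missing}")
        bad = set(self.table["assay"]) - {"rna", "ribo", "protein"}
        if bad:
            raise ValueError(f"unknown assay labels: {sorted(bad)}")

    def samples_for(self, assay: str, condition: str | None = None) -> list[str]:
        t = self.table[self.table["assay"] == assay]
        if condition is not None:
            t = t[t["condition"] == condition]
        return list(t["sample_id"])

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.table["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def to_tsv(self, path) -> None:
        self.table[self.REQUIRED].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# GFF3 + FASTA -> transcript models


def _spliced_sequence(exons, chrom_seq: str, strand: str) -> tuple[str, list[tuple[int, int]]]:
    """Concatenate exon slices into the mature transcript (5'->3').

    Returns the sequence and the exon intervals (genomic, 0-based
    half-open) in transcript order.
    """
    ivals = sorted(((e.start - 1, e.end) for e in exons))
    if strand == "-":
        ivals = ivals[::-1]
    parts = []
    for s, e in ivals:
        piece = chrom_seq[s:e]
        if strand == "-":
            piece = str(Seq(piece).reverse_complement())
        parts.append(piece)
    return "".join(parts), ivals


def _genomic_to_transcript(ivals, strand: str, gpos: int) -> int:
    """Map a genomic position (0-based) to transcript coordinates."""
    offset = 0
    for s, e in ivals:
        if s <= gpos < e:
            return offset + (gpos - s if strand == "+" else e - 1 - gpos)
        offset += e - s
    raise ValueError(f"genomic position {gpos} not exonic")


def read_transcript_models(gff3_path, fasta_path) -> list[TranscriptModel]:
    """Assemble strand-corrected transcript models from a GFF3 annotation
    and the genome FASTA.

    One transcript is kept per gene (the longest CDS wins, logged);
    transcripts whose CDS length is not a multiple of 3 are skipped with
    a warning.  A transcript on a contig missing from the FASTA is a
    hard error.
    """
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    try:
        db = gffutils.create_db(
            str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    models: list[TranscriptModel] = []
    for gene in db.features_of_type("gene"):
        candidates = []
        for mrna in db.children(gene, featuretype="mRNA"):
            if mrna.seqid not in genome:
                raise KeyError(
                    f"sequence {mrna.seqid!r} (transcript {mrna.id}) missing from FASTA"
                )
            exons = list(db.children(mrna, featuretype="exon"))
            if not exons:
                exons = [mrna]
            cds = list(db.children(mrna, featuretype="CDS"))
            if not cds:
                log.warning("transcript %s has no CDS; skipped", mrna.id)
                continue
            seq, ivals = _spliced_sequence(exons, genome[mrna.seqid], mrna.strand)
            g_lo = min(c.start - 1 for c in cds)
            g_hi = max(c.end for c in cds)
            if mrna.strand == "+":
                t_start = _genomic_to_transcript(ivals, "+", g_lo)
                t_end = _genomic_to_transcript(ivals, "+", g_hi - 1) + 1
            else:
                t_start = _genomic_to_transcript(ivals, "-", g_hi - 1)
                t_end = _genomic_to_transcript(ivals, "-", g_lo) + 1
            if (t_end - t_start) % 3 != 0:
                log.warning(
                    "transcript %s: CDS length %d not divisible by 3; skipped",
                    mrna.id, t_end - t_start,
                )
                continue
            candidates.append(
                TranscriptModel(mrna.id, gene.id, seq, t_start, t_end)
            )
        if not candidates:
            continue
        best = max(candidates, key=lambda m: m.cds_len)
        if len(candidates) > 1:
            log.info(
                "gene %s: %d isoforms, keeping %s (longest CDS)",
                gene.id, len(candidates), best.transcript_id,
            )
        models.append(best)
    return models


# ---------------------------------------------------------------------------
# P-site records


def read_psites(
    path,
    models: Sequence[TranscriptModel] | None = None,
    read_length_bounds: tuple[int, int] = DEFAULT_READ_LENGTH_BOUNDS,
) -> list[PsiteRecord]:
    """Read a 4-column BED-like TSV of P-site observations
    (transcript_id, position, read_length, count; header optional).

    If ``models`` is given, positions are validated against transcript
    lengths and out-of-bounds rows raise, naming the offending rows.
    Negative counts are a hard error.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=PSITE_COLUMNS, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if len(df) and not str(df.iloc[0]["position"]).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)  # header row
    if df.empty:
        return []
    for col in ("position", "read_length", "count"):
        df[col] = df[col].astype(int)
    if (df["count"] < 0).any():
        rows = list(df.index[df["count"] < 0] + 1)
        raise ValueError(f"negative counts at rows {rows}")
    lo, hi = read_length_bounds
    odd = df[(df["read_length"] < lo) | (df["read_length"] > hi)]
    if len(odd):
        log.warning("%d records outside read-length bounds [%d, %d]", len(odd), lo, hi)
    if models is not None:
        lengths = {m.transcript_id: m.length for m in models}
        bad_rows = [
            i + 1
            for i, r in df.iterrows()
            if r["transcript_id"] not in lengths
            or not 0 <= r["position"] < lengths[r["transcript_id"]]
        ]
        if bad_rows:
            raise ValueError(f"P-site positions outside transcripts at rows {bad_rows}")
    return [PsiteRecord(*row) for row in df[PSITE_COLUMNS].itertuples(index=False)]


def write_psites(psites, path) -> None:
    as_psite_frame(psites).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Generic result writer


def write_table(records, path) -> None:
    """Write result records (a DataFrame, or a list of dataclasses /
    NamedTuples) as a TSV with deterministic column order.  An empty
    record list with a known type still produces the header."""
    if isinstance(records, pd.DataFrame):
        records.to_csv(path, sep="\t", index=False)
        return
    records = list(records)
    if not records:
        pd.DataFrame().to_csv(path, sep="\t", index=False)
        return
    first = records[0]
    if hasattr(first, "_fields"):  # NamedTuple
        cols = list(first._fields)
        df = pd.DataFrame(records, columns=cols)
    elif hasattr(first, "__dataclass_fields__"):
        cols = list(first.__dataclass_fields__)
        df = pd.DataFrame([[getattr(r, c) for c in cols] for r in records], columns=cols)
    else:
        df = pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
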