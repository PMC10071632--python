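"""Synthetic translatome study with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: transcripts with 5'UTR/CDS/3'UTR geometry, a subset of 5'UTRs
carrying uORFs whose translation status depends on their Kozak context,
ribosome footprints with a 32-33 nt length mode, a configurable in-frame
P-site fraction and CDS enrichment, log-normal per-gene translational
efficiency (halved for genes with a translated uORF), and two conditions
with replicated Poisson counts and planted fold-changes.

Translated uORFs are written with the same position-biased codon model
as annotated coding regions, untranslated uORFs with uniform codons:
sequence-composition scores can only separate the two groups if
translated small ORFs actually look coding-like, which is the premise of
applying coding-potential statistics to them in the first place.

5'UTRs contain no ATG other than the planted uORF starts, so the truth
table is the complete list of upstream ORFs by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CountTable,
    PSITE_COLUMNS,
    SampleSheet,
    TranscriptModel,
)

log = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))
STOPS = ("TAA", "TAG", "TGA")

#: position-specific base frequencies of the coding model (order ACGT).
#: Strong codon-position asymmetry with a GC-rich third position, the
#: signature Fickett/hexamer statistics key on.
CODING_P1 = (0.28, 0.14, 0.50, 0.08)
CODING_P2 = (0.40, 0.20, 0.10, 0.30)
CODING_P3 = (0.12, 0.38, 0.32, 0.18)


def default_read_length_weights() -> dict[int, float]:
    """Footprint-length distribution peaked at 32-33 nt, the predominant
    plant ribosome-protected fragment size."""
    raw = {
        26: 1, 27: 2, 28: 4, 29: 6, 30: 9, 31: 14,
        32: 21, 33: 19, 34: 11, 35: 6, 36: 4, 37: 2, 38: 1,
    }
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


@dataclass
class SimConfig:
    """Study conditions for the synthetic translatome."""

    n_transcripts: int = 300
    utr5_range: tuple[int, int] = (90, 300)
    cds_codons_range: tuple[int, int] = (60, 400)
    utr3_range: tuple[int, int] = (60, 240)
    uorf_probability: float = 0.35
    p_second_uorf: float = 0.3
    p_translated_uorf: float = 0.5
    #: planted uORF length range (nt, stop included); most real plant
    #: uORFs fall in the 60-460 nt band, truncated here to fit the UTRs
    uorf_len_range: tuple[int, int] = (60, 150)
    #: normalized stop-to-CDS distance ranges (clipped to [0, 1]);
    #: translated uORFs sit closer to the main start by ~0.2
    uorf_dist_translated: tuple[float, float] = (0.10, 0.90)
    uorf_dist_untranslated: tuple[float, float] = (0.30, 1.10)
    read_length_weights: dict[int, float] = field(default_factory=default_read_length_weights)
    in_frame_fraction: float = 0.9
    cds_read_share: float = 0.87
    mean_depth: float = 500.0
    te_log2_sd: float = 1.0
    uorf_te_penalty: float = 0.5
    frac_diff_tx: float = 0.2
    frac_diff_te: float = 0.2
    effect_log2fc: float = 2.0
    kozak_strong_boost: float = 2.0
    uorf_read_share: float = 0.5
    init_peak_weight: float = 0.08
    n_replicates: int = 3
    conditions: tuple[str, str] = ("85DAF", "115DAF")
    seed: int = 42

    def validate(self) -> None:
        for name in (
            "uorf_probability", "p_second_uorf", "p_translated_uorf",
            "cds_read_share", "frac_diff_tx", "frac_diff_te",
            "uorf_read_share", "init_peak_weight",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} not in [0, 1]")
        if not 1 / 3 <= self.in_frame_fraction <= 1.0:
            raise ValueError("in_frame_fraction must be in [1/3, 1]")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        w = sum(self.read_length_weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"read_length_weights sum to {w}, not 1")
        if self.uorf_probability > 0 and self.utr5_range[0] < self.uorf_len_range[0] + 3:
            raise ValueError(
                "5'UTR range too short to host a uORF; raise utr5_range "
                "or set uorf_probability to 0"
            )
        if self.uorf_len_range[0] % 3 or self.uorf_len_range[0] < 9:
            raise ValueError("uorf_len_range[0] must be a multiple of 3 and >= 9")


@dataclass
class TruthTable:
    """Ground truth: per-transcript expression parameters and the
    complete list of planted uORFs."""

    transcripts: pd.DataFrame
    uorfs: pd.DataFrame

    def to_dir(self, outdir) -> None:
        outdir = Path(outdir)
        self.transcripts.to_csv(outdir / "truth_transcripts.tsv", sep="\t", index=False)
        self.uorfs.to_csv(outdir / "truth_uorfs.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, outdir) -> "TruthTable":
        outdir = Path(outdir)
        return cls(
            pd.read_csv(outdir / "truth_transcripts.tsv", sep="\t"),
            pd.read_csv(outdir / "truth_uorfs.tsv", sep="\t"),
        )


# ---------------------------------------------------------------------------
# sequence construction


def _random_seq(rng, n: int) -> np.ndarray:
    return rng.integers(0, 4, n)


def _coding_codons(rng, n: int, forbid_atg: bool = True) -> np.ndarray:
    """n codons (as base indices, shape (n, 3)) from the coding model,
    never a stop codon, optionally never ATG."""
    out = np.empty((n, 3), dtype=np.int64)
    need = np.arange(n)
    while need.size:
        c = np.column_stack([
            rng.choice(4, need.size, p=CODING_P1),
            rng.choice(4, need.size, p=CODING_P2),
            rng.choice(4, need.size, p=CODING_P3),
        ])
        out[need] = c
        tri = ["".join(BASES[row]) for row in out[need]]
        bad = [t in STOPS or (forbid_atg and t == "ATG") for t in tri]
        need = need[np.array(bad, dtype=bool)]
    return out


def _uniform_codons(rng, n: int) -> np.ndarray:
    out = np.empty((n, 3), dtype=np.int64)
    need = np.arange(n)
    while need.size:
        c = rng.integers(0, 4, (need.size, 3))
        out[need] = c
        tri = ["".join(BASES[row]) for row in out[need]]
        bad = [t in STOPS or t == "ATG" for t in tri]
        need = need[np.array(bad, dtype=bool)]
    return out


def _to_str(idx: np.ndarray) -> str:
    return "".join(BASES[idx.ravel()])


_B2I = {b: i for i, b in enumerate("ACGT")}


def _scrub_atg(seq: np.ndarray, protected_starts: set[int], protected_stops: set[int]) -> None:
    """Mutate every ATG in ``seq`` (base-index array) whose start is not
    protected.  The G is flipped to C, except when the G falls inside a
    planted stop codon, where the A is flipped instead; neither edit can
    create a stop codon or a new ATG."""
    a, t, g = _B2I["A"], _B2I["T"], _B2I["G"]
    c = _B2I["C"]
    stop_positions = set()
    for s in protected_stops:
        stop_positions.update((s, s + 1, s + 2))
    i = 0
    while i < len(seq) - 2:
        if seq[i] == a and seq[i + 1] == t and seq[i + 2] == g and i not in protected_starts:
            if i + 2 in stop_positions:
                seq[i] = c
            else:
                seq[i + 2] = c
            i += 1
        else:
            i += 1


# ---------------------------------------------------------------------------
# annotation generation


def simulate_annotation(config: SimConfig):
    """Build transcript models, a toy genome + GFF3, and the truth table.

    Returns (models, genome_dict, gff3_text, truth).  Deterministic
    under a fixed config seed.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    models: list[TranscriptModel] = []
    tx_rows = []
    uorf_rows = []

    for k in range(config.n_transcripts):
        tid = f"t{k + 1:04d}"
        gid = f"g{k + 1:04d}"
        utr5_len = int(rng.integers(config.utr5_range[0], config.utr5_range[1] + 1))
        n_codons = int(rng.integers(config.cds_codons_range[0], config.cds_codons_range[1] + 1))
        utr3_len = int(rng.integers(config.utr3_range[0], config.utr3_range[1] + 1))

        utr5 = _random_seq(rng, utr5_len)
        cds = np.concatenate([
            np.array([_B2I["A"], _B2I["T"], _B2I["G"]]),
            _coding_codons(rng, n_codons - 2, forbid_atg=False).ravel(),
            np.array([_B2I[x] for x in STOPS[rng.integers(0, 3)]]),
        ])
        utr3 = _random_seq(rng, utr3_len)

        # ---- plant uORFs
        planted: list[dict] = []
        if rng.random() < config.uorf_probability:
            n_uorfs = 1 + int(rng.random() < config.p_second_uorf)
            occupied: list[tuple[int, int]] = []
            for _ in range(n_uorfs):
                max_len = min(config.uorf_len_range[1], (utr5_len - 3) // 3 * 3)
                if max_len < config.uorf_len_range[0]:
                    continue
                n_cod = int(rng.integers(config.uorf_len_range[0] // 3, max_len // 3 + 1))
                length = 3 * n_cod
                # Kozak context decides translation before placement
                minus3 = int(rng.integers(0, 4))
                plus4 = int(rng.integers(0, 4))
                strong = BASES[minus3] in ("A", "G") and BASES[plus4] == "G"
                p_t = config.p_translated_uorf * (
                    config.kozak_strong_boost if strong else 1.0
                )
                translated = bool(rng.random() < min(0.95, p_t))
                d_lo, d_hi = (
                    config.uorf_dist_translated
                    if translated
                    else config.uorf_dist_untranslated
                )
                d = min(1.0, max(0.0, rng.uniform(d_lo, d_hi)))
                stop_end = utr5_len - int(round(d * utr5_len))
                start = stop_end - length
                if start < 0:
                    start, stop_end = 0, length
                if stop_end > utr5_len or any(
                    start < e and s < stop_end for s, e in occupied
                ):
                    continue
                occupied.append((start, stop_end))
                body = (
                    _coding_codons(rng, n_cod - 2)
                    if translated
                    else _uniform_codons(rng, n_cod - 2)
                )
                frag = np.concatenate([
                    np.array([_B2I["A"], _B2I["T"], _B2I["G"]]),
                    body.ravel(),
                    np.array([_B2I[x] for x in STOPS[rng.integers(0, 3)]]),
                ])
                utr5[start:stop_end] = frag
                # write the Kozak context bases; if forcing +4 turns the
                # second codon into a stop/ATG, resample its tail
                utr5[start + 3] = plus4
                cod = _to_str(utr5[start + 3 : start + 6])
                while cod in STOPS or cod == "ATG":
                    utr5[start + 4 : start + 6] = rng.integers(0, 4, 2)
                    cod = _to_str(utr5[start + 3 : start + 6])
                if start >= 3:
                    utr5[start - 3] = minus3
                occ = float(rng.gamma(3.0, 0.5)) * (
                    config.kozak_strong_boost if strong else 1.0
                )
                planted.append(dict(
                    transcript_id=tid,
                    start=start,
                    stop_end=stop_end,
                    length=length,
                    translated=translated,
                    occupancy=occ if translated else 0.0,
                ))

        _scrub_atg(
            utr5,
            protected_starts={u["start"] for u in planted},
            protected_stops={u["stop_end"] - 3 for u in planted},
        )
        seq = _to_str(np.concatenate([utr5, cds, utr3]))
        cds_start = utr5_len
        cds_end = utr5_len + 3 * n_codons
        model = TranscriptModel(tid, gid, seq, cds_start, cds_end)
        models.append(model)

        for u in planted:
            strong_final = (
                (u["start"] >= 3 and seq[u["start"] - 3] in "AG")
                and seq[u["start"] + 3] == "G"
            )
            uorf_rows.append(dict(
                transcript_id=tid,
                uorf_id=f"{tid}:uORF:{u['start']}",
                start=u["start"],
                stop_end=u["stop_end"],
                length=u["length"],
                translated=u["translated"],
                kozak_strong=strong_final,
                norm_distance=(cds_start - u["stop_end"]) / utr5_len,
                occupancy=u["occupancy"],
            ))

        abundance = float(2.0 ** rng.normal(0.0, 1.0))
        te = float(2.0 ** rng.normal(0.0, config.te_log2_sd))
        if any(u["translated"] for u in planted):
            te *= config.uorf_te_penalty
        tx_lfc = (
            float(rng.choice([-1.0, 1.0]) * config.effect_log2fc)
            if rng.random() < config.frac_diff_tx else 0.0
        )
        te_lfc = (
            float(rng.choice([-1.0, 1.0]) * config.effect_log2fc)
            if rng.random() < config.frac_diff_te else 0.0
        )
        tx_rows.append(dict(
            transcript_id=tid,
            gene_id=gid,
            length=model.length,
            cds_start=cds_start,
            cds_end=cds_end,
            abundance=abundance,
            true_te=te,
            tx_log2fc=tx_lfc,
            te_log2fc=te_lfc,
            n_uorfs=len(planted),
            n_translated_uorfs=sum(u["translated"] for u in planted),
        ))

    truth = TruthTable(
        pd.DataFrame(tx_rows),
        pd.DataFrame(uorf_rows, columns=[
            "transcript_id", "uorf_id", "start", "stop_end", "length",
            "translated", "kozak_strong", "norm_distance", "occupancy",
        ]),
    )
    genome, gff3 = _build_genome(models, rng)
    return models, genome, gff3, truth


def _build_genome(models, rng) -> tuple[dict[str, str], str]:
    """Lay transcripts onto chromosomes as 1-2 exon genes on random
    strands, separated by 20 nt spacers, and emit the matching GFF3."""
    from Bio.Seq import Seq

    per_chrom = 60
    chroms: dict[str, list[str]] = {}
    lines = ["##gff-version 3"]
    for k, m in enumerate(models):
        chrom = f"chr{k // per_chrom + 1}"
        parts = chroms.setdefault(chrom, [])
        offset = sum(len(p) for p in parts)
        strand = "+" if rng.random() < 0.5 else "-"
        two_exon = m.length > 60 and rng.random() < 0.5
        if two_exon:
            split = int(rng.integers(20, m.length - 20))
            t_ivals = [(0, split), (split, m.length)]
            intron = _to_str(_random_seq(rng, int(rng.integers(40, 80))))
        else:
            t_ivals = [(0, m.length)]
            intron = ""
        pieces = [m.sequence[a:b] for a, b in t_ivals]
        if strand == "-":
            pieces = [str(Seq(p).reverse_complement()) for p in reversed(pieces)]
            t_order = list(reversed(range(len(t_ivals))))
        else:
            t_order = list(range(len(t_ivals)))
        locus = (intron.join(pieces) if intron else "".join(pieces))
        g_exons: dict[int, tuple[int, int]] = {}
        pos = offset
        for j, t_i in enumerate(t_order):
            a, b = t_ivals[t_i]
            g_exons[t_i] = (pos, pos + (b - a))
            pos += (b - a) + (len(intron) if j == 0 and intron else 0)
        gene_lo = min(lo for lo, _ in g_exons.values())
        gene_hi = max(hi for _, hi in g_exons.values())

        def g_of(t: int) -> int:
            for t_i, (a, b) in enumerate(t_ivals):
                if a <= t < b:
                    lo, hi = g_exons[t_i]
                    return lo + (t - a) if strand == "+" else hi - 1 - (t - a)
            raise AssertionError

        def fields(ftype, lo, hi, attrs):
            return "\t".join([
                chrom, "riboprof_sim", ftype, str(lo + 1), str(hi),
                ".", strand, ".", attrs,
            ])

        lines.append(fields("gene", gene_lo, gene_hi, f"ID={m.gene_id}"))
        lines.append(fields(
            "mRNA", gene_lo, gene_hi, f"ID={m.transcript_id};Parent={m.gene_id}"
        ))
        for t_i, (lo, hi) in sorted(g_exons.items()):
            lines.append(fields(
                "exon", lo, hi,
                f"ID={m.transcript_id}.exon{t_i + 1};Parent={m.transcript_id}",
            ))
        # CDS segments: overlap of the CDS transcript interval with each exon
        for t_i, (a, b) in enumerate(t_ivals):
            lo_t, hi_t = max(a, m.cds_start), min(b, m.cds_end)
            if lo_t >= hi_t:
                continue
            g1, g2 = g_of(lo_t), g_of(hi_t - 1)
            lo_g, hi_g = min(g1, g2), max(g1, g2) + 1
            lines.append(fields(
                "CDS", lo_g, hi_g,
                f"ID={m.transcript_id}.cds{t_i + 1};Parent={m.transcript_id}",
            ))
        parts.append(locus)
        parts.append(_to_str(_random_seq(rng, 20)))
    genome = {c: "".join(ps) for c, ps in chroms.items()}
    return genome, "\n".join(lines) + "\n"


def generate_annotation(config: SimConfig, outdir) -> TruthTable:
    """Write genome.fa, annotation.gff3 and the truth tables to
    ``outdir``; returns the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models, genome, gff3, truth = simulate_annotation(config)
    with open(outdir / "genome.fa", "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    (outdir / "annotation.gff3").write_text(gff3)
    truth.to_dir(outdir)
    return truth


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SimReads:
    """Simulated observations: P-site records and positional RNA
    fragment counts per sample, gene-level count tables, sample sheet."""

    psites: dict[str, pd.DataFrame]
    rna_positions: dict[str, pd.DataFrame]
    rna_counts: CountTable
    rpf_counts: CountTable
    sample_sheet: SampleSheet

    def to_dir(self, outdir) -> None:
        outdir = Path(outdir)
        for sample, df in self.psites.items():
            df.to_csv(outdir / f"psites_{sample}.tsv", sep="\t", index=False)
        for sample, df in self.rna_positions.items():
            df.to_csv(outdir / f"rnapos_{sample}.tsv", sep="\t", index=False)
        self.rna_counts.to_tsv(outdir / "counts_rna.tsv")
        self.rpf_counts.to_tsv(outdir / "counts_rpf.tsv")
        self.sample_sheet.to_tsv(outdir / "samples.tsv")


def simulate_reads(truth: TruthTable, config: SimConfig) -> SimReads:
    """Simulate RNA-seq fragments and ribosome P-sites for every sample.

    RNA fragment starts are uniform over the transcript with Poisson
    totals; footprints split between CDS (``cds_read_share``) and UTRs,
    with the in-frame fraction on frame 0, an initiation peak on the
    start codon, and translated uORFs drawing a share of the UTR mass in
    their own frame.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    lengths = np.array(sorted(config.read_length_weights), dtype=np.int64)
    lweights = np.array([config.read_length_weights[x] for x in lengths])

    tx = truth.transcripts
    uorfs_by_tid: dict[str, pd.DataFrame] = {
        tid: grp for tid, grp in truth.uorfs.groupby("transcript_id")
    }
    sample_rows = []
    psites: dict[str, pd.DataFrame] = {}
    rna_positions: dict[str, pd.DataFrame] = {}
    rna_gene = {}
    rpf_gene = {}

    for cond_i, cond in enumerate(config.conditions):
        for rep in range(1, config.n_replicates + 1):
            rna_sample = f"{cond}_rna_{rep}"
            ribo_sample = f"{cond}_ribo_{rep}"
            sample_rows.append((rna_sample, cond, "rna", rep))
            sample_rows.append((ribo_sample, cond, "ribo", rep))
            rna_cols = []
            ps_cols = []
            rna_tot = {}
            rpf_tot = {}
            for row in tx.itertuples(index=False):
                L, cs, ce = int(row.length), int(row.cds_start), int(row.cds_end)
                fc_rna = 2.0 ** row.tx_log2fc if cond_i == 1 else 1.0
                fc_rpf = (
                    2.0 ** (row.tx_log2fc + row.te_log2fc) if cond_i == 1 else 1.0
                )
                # --- RNA fragments
                n_rna = int(rng.poisson(config.mean_depth * row.abundance * fc_rna))
                rna_tot[row.transcript_id] = n_rna
                if n_rna:
                    pos = rng.integers(0, L, n_rna)
                    cnt = np.bincount(pos, minlength=L)
                    nz = np.nonzero(cnt)[0]
                    rna_cols.append(pd.DataFrame({
                        "transcript_id": row.transcript_id,
                        "position": nz,
                        "count": cnt[nz],
                    }))
                # --- footprints
                n_rpf = int(rng.poisson(
                    config.mean_depth * row.abundance * row.true_te * fc_rpf
                ))
                if n_rpf == 0:
                    rpf_tot[row.transcript_id] = 0
                    continue
                n_cds = int(rng.binomial(n_rpf, config.cds_read_share))
                n_utr = n_rpf - n_cds
                rpf_tot[row.transcript_id] = n_cds
                positions = []
                n_codons = (ce - cs) // 3
                if n_cds:
                    n0 = int(rng.binomial(n_cds, config.in_frame_fraction))
                    n_peak = int(rng.binomial(n0, config.init_peak_weight))
                    codons0 = rng.integers(0, n_codons, n0 - n_peak)
                    positions.append(np.full(n_peak, cs))
                    positions.append(cs + 3 * codons0)
                    n1 = int(rng.binomial(n_cds - n0, 0.5))
                    n2 = n_cds - n0 - n1
                    positions.append(cs + 3 * rng.integers(0, n_codons, n1) + 1)
                    positions.append(cs + 3 * rng.integers(0, n_codons, n2) + 2)
                if n_utr:
                    u = uorfs_by_tid.get(row.transcript_id)
                    occ = (
                        u[u["translated"]] if u is not None else None
                    )
                    w_sum = float(occ["occupancy"].sum()) if occ is not None and len(occ) else 0.0
                    p_u = min(0.85, config.uorf_read_share * w_sum) if w_sum > 0 else 0.0
                    n_uorf = int(rng.binomial(n_utr, p_u))
                    n_bg = n_utr - n_uorf
                    if n_uorf:
                        w = occ["occupancy"].to_numpy()
                        alloc = rng.multinomial(n_uorf, w / w.sum())
                        for (ustart, ulen), n_here in zip(
                            zip(occ["start"], occ["length"]), alloc
                        ):
                            if n_here == 0:
                                continue
                            uc = int(ulen) // 3
                            nf0 = int(rng.binomial(n_here, config.in_frame_fraction))
                            positions.append(
                                int(ustart) + 3 * rng.integers(0, uc, nf0)
                            )
                            nf1 = int(rng.binomial(n_here - nf0, 0.5))
                            nf2 = n_here - nf0 - nf1
                            positions.append(
                                int(ustart) + 3 * rng.integers(0, uc, nf1) + 1
                            )
                            positions.append(
                                int(ustart) + 3 * rng.integers(0, uc, nf2) + 2
                            )
                    if n_bg:
                        utr_len = cs + (L - ce)
                        raw = rng.integers(0, utr_len, n_bg)
                        bg = np.where(raw < cs, raw, raw - cs + ce)
                        positions.append(bg)
                pos = np.concatenate([np.asarray(p, dtype=np.int64) for p in positions])
                rls = rng.choice(lengths, size=pos.size, p=lweights)
                ps_cols.append(pd.DataFrame({
                    "transcript_id": row.transcript_id,
                    "position": pos,
                    "read_length": rls,
                }))
            rna_positions[rna_sample] = (
                pd.concat(rna_cols, ignore_index=True)
                if rna_cols else pd.DataFrame(columns=["transcript_id", "position", "count"])
            )
            if ps_cols:
                ps = pd.concat(ps_cols, ignore_index=True)
                ps = (
                    ps.groupby(["transcript_id", "position", "read_length"], sort=True)
                    .size()
                    .reset_index(name="count")
                )
            else:
                ps = pd.DataFrame(columns=PSITE_COLUMNS)
            psites[ribo_sample] = ps[PSITE_COLUMNS] if len(ps) else ps
            rna_gene[rna_sample] = rna_tot
            rpf_gene[ribo_sample] = rpf_tot

    sheet = SampleSheet(pd.DataFrame(
        sample_rows, columns=["sample_id", "condition", "assay", "replicate"]
    ))
    rna_counts = CountTable(
        pd.DataFrame(rna_gene).reindex(tx["transcript_id"]).fillna(0).astype(int)
    )
    rpf_counts = CountTable(
        pd.DataFrame(rpf_gene).reindex(tx["transcript_id"]).fillna(0).astype(int)
    )
    return SimReads(psites, rna_positions, rna_counts, rpf_counts, sheet)


# ---------------------------------------------------------------------------
# helpers for planted-offset and co-expression experiments


def psites_to_five_prime(psite_frame: pd.DataFrame, offsets: dict[int, int]) -> pd.DataFrame:
    """Shift P-site positions back to the footprint 5' ends using a
    per-read-length offset table (position - offset, floored at 0)."""
    df = psite_frame.copy()
    off = df["read_length"].map(offsets)
    if off.isna().any():
        missing = sorted(df["read_length"][off.isna()].unique())
        raise KeyError(f"no offset for read lengths {missing}")
    df["position"] = np.maximum(0, df["position"] - off.astype(int))
    return df


def simulate_coexpression(
    n_samples: int = 6,
    n_linked_tfs: int = 10,
    n_null_tfs: int = 200,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Expression matrix where ``n_linked_tfs`` transcription factors are
    noisy copies of one target profile and the rest are independent.

    Returns (matrix genes x samples, tf_ids, target_ids).
    """
    rng = np.random.default_rng(seed)
    target = rng.normal(0.0, 1.0, n_samples)
    rows = {"target": target}
    tf_ids = []
    for i in range(n_linked_tfs):
        name = f"tf_linked_{i + 1}"
        rows[name] = target + rng.normal(0.0, noise_sd, n_samples)
        tf_ids.append(name)
    for i in range(n_null_tfs):
        name = f"tf_null_{i + 1}"
        rows[name] = rng.normal(0.0, 1.0, n_samples)
        tf_ids.append(name)
    mat = pd.DataFrame(rows).T
    mat.columns = [f"s{j + 1}" for j in range(n_samples)]
    return mat, tf_ids, ["target"]


def config_to_json(config: SimConfig) -> str:
    d = asdict(config)
    d["read_length_weights"] = {str(k): v for k, v in d["read_length_weights"].items()}
    return json.dumps(d, indent=2, sort_keys=True)
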