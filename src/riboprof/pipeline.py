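"""End-to-end orchestration: simulate -> qc -> orfs -> score -> te ->
quadrant -> features -> network, with one YAML config, one seed, and a
JSON manifest.  Every number in every stage TSV is produced by a library
operation; the pipeline only moves data between stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    CountTable,
    SampleSheet,
    read_psites,
    read_transcript_models,
    write_table,
    as_psite_frame,
)
from .synthetic_data import SimConfig, TruthTable, generate_annotation, simulate_reads
from . import riboqc, orf_discovery, coding_potential, expression_te, uorf_features
from .coexpress_network import build_network, edges_frame

log = logging.getLogger(__name__)

DEFAULTS: dict = {
    "seed": 42,
    "simulate": {"enabled": True},  # plus any SimConfig field
    "inputs": {
        "annotation": None,
        "genome": None,
        "sample_sheet": None,
    },
    "orfs": {"min_len": 9, "overlap_policy": "exclude"},
    "score": {"rule": "all", "percentile": 95.0},
    "diff": {"alpha": 0.05, "fc_min": 1.5},
    "quadrant": {"lfc_cut": 1.0, "alpha": 0.05},
    "features": {"te_min": 0.5, "length_cutoff": 160},
    "network": {
        "r_min": 0.7, "p_max": 0.05, "absolute": False,
        "n_tfs": 10, "n_targets": 3,
    },
}

SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}


def load_config(source) -> dict:
    """Merge a YAML file or dict over the defaults; unknown keys are
    rejected so typos fail fast."""
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        user = yaml.safe_load(Path(source).read_text()) or {}
    cfg = json.loads(json.dumps(DEFAULTS))  # deep copy
    for key, val in user.items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict):
            for k2, v2 in val.items():
                known = set(cfg[key]) | (SIM_FIELDS if key == "simulate" else set())
                if k2 not in known:
                    raise ValueError(f"unknown config key {key}.{k2}")
                cfg[key][k2] = v2
        else:
            cfg[key] = val
    return cfg


def _sim_config(cfg: dict) -> SimConfig:
    kwargs = {k: v for k, v in cfg["simulate"].items() if k != "enabled"}
    for tup in ("utr5_range", "cds_codons_range", "utr3_range", "conditions"):
        if tup in kwargs and isinstance(kwargs[tup], list):
            kwargs[tup] = tuple(kwargs[tup])
    if "read_length_weights" in kwargs:
        kwargs["read_length_weights"] = {
            int(k): float(v) for k, v in kwargs["read_length_weights"].items()
        }
    kwargs.setdefault("seed", cfg["seed"])
    return SimConfig(**kwargs)


def _load_models(rundir: Path):
    return read_transcript_models(rundir / "annotation.gff3", rundir / "genome.fa")


def _ribo_samples(sheet: SampleSheet) -> list[str]:
    return sheet.samples_for("ribo")


def _load_psites(rundir: Path, sample: str) -> pd.DataFrame:
    return as_psite_frame(read_psites(rundir / f"psites_{sample}.tsv"))


def _load_rna_positions(rundir: Path, sample: str) -> pd.DataFrame:
    return pd.read_csv(rundir / f"rnapos_{sample}.tsv", sep="\t")


def _pooled_psites(rundir: Path, sheet: SampleSheet) -> pd.DataFrame:
    frames = [_load_psites(rundir, s) for s in _ribo_samples(sheet)]
    frames = [f for f in frames if len(f)]
    return (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["transcript_id", "position", "read_length", "count"])
    )


def stage_simulate(cfg: dict, rundir: Path) -> None:
    sim = _sim_config(cfg)
    truth = generate_annotation(sim, rundir)
    reads = simulate_reads(truth, sim)
    reads.to_dir(rundir)


def stage_qc(cfg: dict, rundir: Path) -> None:
    models = _load_models(rundir)
    sheet = SampleSheet.from_tsv(rundir / "samples.tsv")
    pooled = _pooled_psites(rundir, sheet)
    hist = riboqc.length_distribution(pooled)
    write_table(hist, rundir / "length_hist.tsv")
    f0, f1, f2 = riboqc.frame_fractions(pooled, models)
    write_table(
        pd.DataFrame({"frame": [0, 1, 2], "fraction": [f0, f1, f2]}),
        rundir / "frame_fractions.tsv",
    )
    for anchor in ("start", "stop"):
        prof = riboqc.metagene(pooled, models, anchor=anchor)
        prof.reset_index().to_csv(rundir / f"metagene_{anchor}.tsv", sep="\t", index=False)
    r5, rc, r3 = riboqc.region_fractions(pooled, models)
    write_table(
        pd.DataFrame({"region": ["utr5", "cds", "utr3"], "fraction": [r5, rc, r3]}),
        rundir / "region_fractions.tsv",
    )


def stage_orfs(cfg: dict, rundir: Path) -> None:
    models = _load_models(rundir)
    orfs = orf_discovery.enumerate_all(
        models,
        min_len=cfg["orfs"]["min_len"],
        overlap_policy=cfg["orfs"]["overlap_policy"],
    )
    write_table(orfs, rundir / "orfs.tsv")


def _orfs_from_tsv(rundir: Path) -> list[orf_discovery.OrfRecord]:
    df = pd.read_csv(rundir / "orfs.tsv", sep="\t")
    df["normalized_distance"] = df["normalized_distance"].astype(object).where(
        df["normalized_distance"].notna(), None
    )
    return [orf_discovery.OrfRecord(**row) for row in df.to_dict("records")]


def stage_score(cfg: dict, rundir: Path) -> None:
    models = _load_models(rundir)
    sheet = SampleSheet.from_tsv(rundir / "samples.tsv")
    orfs = _orfs_from_tsv(rundir)
    pooled = _pooled_psites(rundir, sheet)
    rna = pd.concat(
        [_load_rna_positions(rundir, s) for s in sheet.samples_for("rna")],
        ignore_index=True,
    )
    table = coding_potential.default_hexamer_table(models, seed=cfg["seed"])
    scores = coding_potential.score_orfs(orfs, pooled, rna, models, hexamer_table=table)
    write_table(scores, rundir / "scores.tsv")
    null = coding_potential.null_scores(orfs, scores, models, table, seed=cfg["seed"])
    candidates = [s for s in scores if s.category != "mORF"]
    calls, thresholds = coding_potential.call_translated(
        candidates, null, rule=cfg["score"]["rule"], percentile=cfg["score"]["percentile"]
    )
    write_table(
        pd.DataFrame(
            {"score": list(thresholds), "threshold": list(thresholds.values())}
        ),
        rundir / "thresholds.tsv",
    )
    out = pd.DataFrame(
        [(c.orf_id, c.translated, ",".join(c.passing_scores)) for c in calls],
        columns=["orf_id", "translated", "passing_scores"],
    )
    write_table(out, rundir / "calls.tsv")


def _counts_and_lengths(rundir: Path, models, sheet: SampleSheet):
    tx_len = pd.Series({m.transcript_id: m.length for m in models})
    cds_len = pd.Series({m.transcript_id: m.cds_len for m in models})
    rna_cols = {}
    for s in sheet.samples_for("rna"):
        pos = _load_rna_positions(rundir, s)
        rna_cols[s] = pos.groupby("transcript_id")["count"].sum()
    rna_counts = CountTable(
        pd.DataFrame(rna_cols).reindex(tx_len.index).fillna(0).astype(int)
    )
    rpf_cols = {}
    for s in _ribo_samples(sheet):
        ps = _load_psites(rundir, s)
        rpf_cols[s] = riboqc.region_counts_by_transcript(ps, models, region="cds")
    rpf_counts = CountTable(
        pd.DataFrame(rpf_cols).reindex(tx_len.index).fillna(0).astype(int)
    )
    return rna_counts, rpf_counts, tx_len, cds_len


def stage_te(cfg: dict, rundir: Path) -> None:
    models = _load_models(rundir)
    sheet = SampleSheet.from_tsv(rundir / "samples.tsv")
    rna_counts, rpf_counts, tx_len, cds_len = _counts_and_lengths(rundir, models, sheet)
    # median-of-ratios sizes keep unchanged genes at log2fc ~ 0 when a
    # few strong effects skew the raw totals
    rna_sizes = expression_te.median_ratio_library_sizes(rna_counts)
    rpf_sizes = expression_te.median_ratio_library_sizes(rpf_counts)
    rna_f = expression_te.fpkm_table(rna_counts, tx_len, library_sizes=rna_sizes)
    rpf_f = expression_te.fpkm_table(rpf_counts, cds_len, library_sizes=rpf_sizes)
    te = expression_te.te_table(rna_counts, rpf_counts, sheet, tx_len, cds_len,
                                rna_sizes=rna_sizes, rpf_sizes=rpf_sizes)
    expr = pd.concat(
        {"rna_fpkm": rna_f, "rpf_fpkm": rpf_f, "te": te}, axis=1
    )
    expr.columns = [f"{a}:{b}" for a, b in expr.columns]
    expr.index.name = "gene_id"
    expr.reset_index().to_csv(rundir / "expression.tsv", sep="\t", index=False)
    a, fcm = cfg["diff"]["alpha"], cfg["diff"]["fc_min"]
    diff_tx = expression_te.differential(rna_f, sheet, "transcription", alpha=a, fc_min=fcm)
    diff_tl = expression_te.differential(rpf_f, sheet, "translation", alpha=a, fc_min=fcm)
    diff_te = expression_te.differential(
        te, sheet, "te", alpha=a, fc_min=fcm, log_transform=False
    )
    write_table(diff_tx, rundir / "diff_transcription.tsv")
    write_table(diff_tl, rundir / "diff_translation.tsv")
    write_table(diff_te, rundir / "diff_te.tsv")


def stage_quadrant(cfg: dict, rundir: Path) -> None:
    diff_tx = pd.read_csv(rundir / "diff_transcription.tsv", sep="\t")
    diff_tl = pd.read_csv(rundir / "diff_translation.tsv", sep="\t")
    quad = expression_te.quadrant_classify(
        diff_tx, diff_tl,
        lfc_cut=cfg["quadrant"]["lfc_cut"], alpha=cfg["quadrant"]["alpha"],
    )
    write_table(quad, rundir / "quadrants.tsv")


def stage_features(cfg: dict, rundir: Path) -> None:
    models = _load_models(rundir)
    sheet = SampleSheet.from_tsv(rundir / "samples.tsv")
    orfs = pd.read_csv(rundir / "orfs.tsv", sep="\t")
    calls = pd.read_csv(rundir / "calls.tsv", sep="\t")
    uorfs = orfs[orfs["category"] == "uORF"].merge(
        calls[["orf_id", "translated"]], on="orf_id", how="left"
    )
    uorfs["translated"] = uorfs["translated"].fillna(False).astype(bool)
    if uorfs.empty:
        log.warning("no uORFs; features stage writes empty tables")
    hist, frac = uorf_features.length_summary(
        uorfs["length"], cutoff=cfg["features"]["length_cutoff"]
    ) if len(uorfs) else (pd.DataFrame(), float("nan"))
    hist.to_csv(rundir / "uorf_lengths.tsv", sep="\t", index=False)
    tr = uorfs[uorfs["translated"]]
    un = uorfs[~uorfs["translated"]]
    if len(tr) and len(un):
        comp = uorf_features.compare_distance(
            tr["normalized_distance"], un["normalized_distance"]
        )
        write_table([comp], rundir / "distance_test.tsv")
        tests = uorf_features.kozak_position_test(
            list(tr["flank_sequence"]), list(un["flank_sequence"])
        )
        pd.DataFrame(
            [(t.position, t.chi2, t.p_value) for t in tests],
            columns=["position", "chi2", "p_value"],
        ).to_csv(rundir / "kozak_tests.tsv", sep="\t", index=False)
        mm = {m.transcript_id: m for m in models}
        flanks = {
            "translated": [
                uorf_features.center_flank(mm[t].sequence, s)
                for t, s in zip(tr["transcript_id"], tr["start"])
            ],
            "untranslated": [
                uorf_features.center_flank(mm[t].sequence, s)
                for t, s in zip(un["transcript_id"], un["start"])
            ],
        }
        uorf_features.gc_flank_profile(flanks).to_csv(
            rundir / "gc_profile.tsv", sep="\t", index=False
        )
    rna_counts, rpf_counts, tx_len, cds_len = _counts_and_lengths(rundir, models, sheet)
    te = expression_te.te_table(rna_counts, rpf_counts, sheet, tx_len, cds_len)
    te_mean = te.mean(axis=1)
    has_tr = pd.Series(False, index=te_mean.index)
    for t in tr["transcript_id"].unique():
        if t in has_tr.index:
            has_tr[t] = True
    carriers = set(uorfs["transcript_id"])
    keep = te_mean.index.isin(carriers)
    try:
        curves, comp = uorf_features.cumulative_te_curve(
            te_mean[keep], has_tr[keep], te_min=cfg["features"]["te_min"]
        )
        rows = []
        for c in curves:
            for v, f in zip(c.values, c.cumulative):
                rows.append((c.group, v, f))
        pd.DataFrame(rows, columns=["group", "te", "cumulative"]).to_csv(
            rundir / "te_ecdf.tsv", sep="\t", index=False
        )
        (rundir / "te_test.json").write_text(json.dumps({
            "p_value": comp.p_value, "direction": comp.direction,
            "n_translated": comp.n_translated, "n_untranslated": comp.n_untranslated,
        }, indent=2))
    except ValueError as err:
        log.warning("cumulative TE curve skipped: %s", err)


def stage_network(cfg: dict, rundir: Path) -> None:
    models = _load_models(rundir)
    sheet = SampleSheet.from_tsv(rundir / "samples.tsv")
    rna_counts, _, tx_len, _ = _counts_and_lengths(rundir, models, sheet)
    rna_f = expression_te.fpkm_table(rna_counts, tx_len)
    n_tfs, n_targets = cfg["network"]["n_tfs"], cfg["network"]["n_targets"]
    genes = list(rna_f.index)
    tf_ids, target_ids = genes[:n_tfs], genes[n_tfs : n_tfs + n_targets]
    edges = build_network(
        rna_f, tf_ids, target_ids,
        r_min=cfg["network"]["r_min"], p_max=cfg["network"]["p_max"],
        absolute=cfg["network"]["absolute"],
    )
    write_table(edges_frame(edges), rundir / "edges.tsv")


STAGES = [
    ("qc", stage_qc),
    ("orfs", stage_orfs),
    ("score", stage_score),
    ("te", stage_te),
    ("quadrant", stage_quadrant),
    ("features", stage_features),
    ("network", stage_network),
]


def run_all(config=None, out="run") -> Path:
    """Execute every stage into ``out``; returns the run directory.

    With simulation disabled, the inputs block must point at an existing
    annotation/genome/sample sheet (validated before any stage runs).
    Deterministic under a fixed config seed.
    """
    cfg = load_config(config)
    rundir = Path(out)
    rundir.mkdir(parents=True, exist_ok=True)
    if cfg["simulate"]["enabled"]:
        stage_simulate(cfg, rundir)
    else:
        for key in ("annotation", "genome", "sample_sheet"):
            path = cfg["inputs"].get(key)
            if not path or not Path(path).exists():
                raise ValueError(f"simulation disabled and inputs.{key} missing")
    for name, fn in STAGES:
        try:
            fn(cfg, rundir)
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
    manifest = {
        "version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
        "outputs": sorted(
            p.name for p in rundir.iterdir()
            if p.is_file() and p.name != "manifest.json"
        ),
    }
    (rundir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return rundir
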