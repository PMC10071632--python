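"""FPKM/TE arithmetic, differential testing, BH correction and the
nine-quadrant classification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riboprof import expression_te as et
from riboprof.io_formats import SampleSheet
from riboprof.stats import bh_adjust


def brute_bh(p):
    """Independent step-up oracle: q_i = min over j>=i of p_(j)*n/j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


class TestFpkm:
    @pytest.mark.parametrize("args, expected", [
        ((100, 1000, 1e6), 100.0),
        ((0, 777, 5e6), 0.0),
        ((50, 500, 2e6), 50.0),
    ])
    def test_hand_values(self, args, expected):
        assert et.fpkm(*args) == pytest.approx(expected)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            et.fpkm(10, 0, 1e6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.integers(0, 10**6),
        st.integers(1, 10**5),
        st.integers(1, 10**9),
        st.integers(2, 5),
    )
    def test_linear_in_count_inverse_in_normalizers(self, c, L, lib, k):
        base = et.fpkm(c, L, lib)
        assert et.fpkm(k * c, L, lib) == pytest.approx(k * base)
        assert et.fpkm(c, k * L, lib) == pytest.approx(base / k)
        assert et.fpkm(c, L, k * lib) == pytest.approx(base / k)


class TestTe:
    def test_scalar_cases(self):
        assert et.translational_efficiency(20.0, 10.0) == 2.0
        assert et.translational_efficiency(5.0, 5.0) == 1.0
        with pytest.raises(ValueError):
            et.translational_efficiency(5.0, 0.0)

    def test_zero_rna_gene_excluded(self):
        rpf = pd.DataFrame({"s1": [2.0, 4.0]}, index=["g1", "g2"])
        rna = pd.DataFrame({"s1": [1.0, 0.0]}, index=["g1", "g2"])
        te = et.translational_efficiency(rpf, rna)
        assert te.loc["g1", "s1"] == 2.0
        assert np.isnan(te.loc["g2", "s1"])


def two_condition_sheet(n_rep=3):
    rows = []
    for cond in ("85DAF", "115DAF"):
        for r in range(1, n_rep + 1):
            rows.append((f"{cond}_rna_{r}", cond, "rna", r))
    return SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "condition", "assay", "replicate"]
    ))


class TestDifferential:
    def test_identical_groups_not_significant(self):
        sheet = two_condition_sheet()
        vals = pd.DataFrame(
            {s: [10.0, 20.0] for s in sheet.table["sample_id"]}, index=["g1", "g2"]
        )
        out = et.differential(vals, sheet, "transcription")
        assert (out["log2fc"] == 0).all()
        assert not out["significant"].any()

    def test_bh_step_up_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_bh_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            p = rng.uniform(0, 1, rng.integers(1, 51))
            assert bh_adjust(p) == pytest.approx(brute_bh(p))

    def test_single_replicate_rejected(self):
        sheet = two_condition_sheet(n_rep=1)
        vals = pd.DataFrame({s: [1.0] for s in sheet.table["sample_id"]}, index=["g"])
        with pytest.raises(ValueError, match="replicates"):
            et.differential(vals, sheet, "transcription")

    def test_planted_fold_change_recovered(self, default_study):
        """Genes planted with log2fc 2 at depth 500 are flagged and the
        estimate lands near the truth (median error well under 0.3)."""
        models = default_study.models
        tx_len = pd.Series({m.transcript_id: m.length for m in models})
        rna_f = et.fpkm_table(
            default_study.reads.rna_counts, tx_len,
            library_sizes=et.median_ratio_library_sizes(default_study.reads.rna_counts),
        )
        out = et.differential(
            rna_f, default_study.reads.sample_sheet, "transcription"
        ).set_index("gene_id")
        truth = default_study.truth.transcripts.set_index("transcript_id")
        planted = truth[truth["tx_log2fc"] != 0]
        est = out["log2fc"].reindex(planted.index)
        err = (est - planted["tx_log2fc"]).abs()
        assert err.median() <= 0.3
        assert out["significant"].reindex(planted.index).mean() >= 0.95
        null_rate = out["significant"].reindex(
            truth[truth["tx_log2fc"] == 0].index
        ).mean()
        assert null_rate <= 0.05


class TestQuadrants:
    GRID = {
        ("down", "up"): "A", ("ns", "up"): "B", ("up", "up"): "C",
        ("down", "ns"): "D", ("ns", "ns"): "E", ("up", "ns"): "F",
        ("down", "down"): "G", ("ns", "down"): "H", ("up", "down"): "I",
    }
    STATE_VALUES = {"up": (2.0, 0.01), "down": (-2.0, 0.01), "ns": (0.0, 0.5)}

    def diff_frame(self, states):
        rows = []
        for gene, state in states.items():
            lfc, fdr = self.STATE_VALUES[state]
            rows.append((gene, lfc, fdr))
        return pd.DataFrame(rows, columns=["gene_id", "log2fc", "fdr"])

    def test_full_truth_table(self):
        """All 3x3 state combinations classify per the declared grid;
        C and E match the up/up and ns/ns definitions."""
        combos = list(self.GRID)
        genes = [f"g{i}" for i in range(len(combos))]
        tx = self.diff_frame({g: c[0] for g, c in zip(genes, combos)})
        tl = self.diff_frame({g: c[1] for g, c in zip(genes, combos)})
        out = et.quadrant_classify(tx, tl).set_index("gene_id")
        for g, combo in zip(genes, combos):
            assert out.at[g, "label"] == self.GRID[combo]
        assert out.at[genes[combos.index(("up", "up"))], "label"] == "C"
        assert out.at[genes[combos.index(("ns", "ns"))], "label"] == "E"

    def test_boundary_lfc_is_changed(self):
        tx = pd.DataFrame([("g", 1.0, 0.04)], columns=["gene_id", "log2fc", "fdr"])
        tl = pd.DataFrame([("g", -1.0, 0.04)], columns=["gene_id", "log2fc", "fdr"])
        out = et.quadrant_classify(tx, tl)
        assert out["label"].iloc[0] == "I"

    def test_boundary_fdr_is_not_changed(self):
        tx = pd.DataFrame([("g", 2.0, 0.05)], columns=["gene_id", "log2fc", "fdr"])
        tl = pd.DataFrame([("g", 2.0, 0.05)], columns=["gene_id", "log2fc", "fdr"])
        out = et.quadrant_classify(tx, tl)
        assert out["label"].iloc[0] == "E"

    def test_missing_layer_excluded(self):
        tx = self.diff_frame({"g1": "up", "g2": "up"})
        tl = self.diff_frame({"g1": "up"})
        out = et.quadrant_classify(tx, tl)
        assert list(out["gene_id"]) == ["g1"]

    def test_planted_up_up_genes_land_in_c(self, default_study):
        """Genes planted up at both layers are classified C in >= 90% of
        cases at depth 500."""
        models = default_study.models
        tx_len = pd.Series({m.transcript_id: m.length for m in models})
        cds_len = pd.Series({m.transcript_id: m.cds_len for m in models})
        reads = default_study.reads
        rna_f = et.fpkm_table(
            reads.rna_counts, tx_len,
            library_sizes=et.median_ratio_library_sizes(reads.rna_counts),
        )
        rpf_f = et.fpkm_table(
            reads.rpf_counts, cds_len,
            library_sizes=et.median_ratio_library_sizes(reads.rpf_counts),
        )
        sheet = reads.sample_sheet
        quad = et.quadrant_classify(
            et.differential(rna_f, sheet, "transcription"),
            et.differential(rpf_f, sheet, "translation"),
        ).set_index("gene_id")
        truth = default_study.truth.transcripts.set_index("transcript_id")
        upup = truth[(truth["tx_log2fc"] > 0) & (truth["tx_log2fc"] + truth["te_log2fc"] > 1)]
        labels = quad["label"].reindex(upup.index).dropna()
        assert len(labels) >= 5
        assert (labels == "C").mean() >= 0.9


class TestDdct:
    @pytest.mark.parametrize("args, expected", [
        ((20, 18, 22, 18), 4.0),
        ((20, 20, 20, 20), 1.0),
        ((21, 18, 21, 18), 1.0),
    ])
    def test_fold_changes(self, args, expected):
        assert et.ddct(*args) == pytest.approx(expected)
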