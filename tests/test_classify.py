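"""Subcluster assignment, NLS scanning and column conservation."""

import math
import random

import pytest

from shsp.classify import assign_cluster, scan_nls
from shsp.conservation import MAX_IC, column_stats, consensus_string
from shsp.detect import detect_acds, trim_core
from shsp.physchem import profile_protein
from shsp.seqio import ProteinRecord
from shsp.templates import CLUSTERS, build_template


def _classify(label, model, threshold):
    t = build_template(label)
    p = ProteinRecord(label, t.seq)
    hits, arch = detect_acds(p, model, threshold)
    core = trim_core(hits[0], p)
    prof = profile_protein(p.id, p.seq, core)
    return p, hits[0], prof


class TestAssignCluster:
    @pytest.mark.parametrize("label", CLUSTERS)
    def test_templates_recover_their_cluster(self, label, model, threshold):
        p, hit, prof = _classify(label, model, threshold)
        asg = assign_cluster(p, hit, prof)
        assert asg.label == label
        assert asg.fired_rules

    def test_a1_fires_on_size_charge_and_missing_b7_arginine(self, model, threshold):
        p, hit, prof = _classify("A1", model, threshold)
        asg = assign_cluster(p, hit, prof)
        fired = {name for name, _ in asg.fired_rules}
        assert "b7_R_absent" in fired

    def test_b1_fires_on_lysine_rich_motif_in_zone(self, model, threshold):
        p, hit, prof = _classify("B1", model, threshold)
        asg = assign_cluster(p, hit, prof)
        names = {name for name, _ in asg.fired_rules}
        assert "B1_Krich" in names or "B1_FxSES" in names
        # match coordinates fall inside the β5-L57 zone of the hit
        for name, span in asg.fired_rules:
            if name == "B1_Krich":
                z0 = hit.anchors["b5"][0]
                z1 = hit.anchors["L57"][1]
                assert z0 <= span[0] and span[1] <= z1

    def test_b2_is_residual_class(self, model, threshold):
        p, hit, prof = _classify("B2", model, threshold)
        asg = assign_cluster(p, hit, prof)
        assert asg.label == "B2"
        assert asg.fired_rules == [("acd_detected_no_signature", None)]

    def test_dimeric_rejected(self, model, threshold):
        t = build_template("dimeric")
        p = ProteinRecord("dim", t.seq)
        hits, _ = detect_acds(p, model, threshold)
        prof = profile_protein(p.id, p.seq)
        with pytest.raises(ValueError, match="monomeric classifier only"):
            assign_cluster(p, hits[0], prof)

    def test_batch_determinism_and_order_independence(self, model, threshold):
        inputs = [_classify(lab, model, threshold) for lab in CLUSTERS]
        forward = [assign_cluster(*x).label for x in inputs]
        backward = [assign_cluster(*x).label for x in reversed(inputs)]
        assert forward == list(reversed(backward))
        assert forward == [assign_cluster(*x).label for x in inputs]


class TestScanNls:
    def test_a1_has_vxp_candidate_in_b4_l45(self, model, threshold):
        p, hit, _ = _classify("A1", model, threshold)
        kinds = {n.kind for n in scan_nls(p, hit)}
        assert "VxP-type" in kinds

    def test_a2_has_basic_rich_candidate(self, model, threshold):
        p, hit, _ = _classify("A2", model, threshold)
        basics = [n for n in scan_nls(p, hit) if n.kind == "basic-rich"]
        assert basics and all(n.basic_count >= 4 for n in basics)

    def test_counting_rule(self):
        p = ProteinRecord("x", "AAAKVKKKAAAA")
        (n,) = scan_nls(p)
        assert n.kind == "basic-rich" and n.basic_count >= 4

    def test_all_ala_empty(self):
        assert scan_nls(ProteinRecord("x", "A" * 50)) == []

    def test_overlapping_windows_merged(self):
        p = ProteinRecord("x", "AAKKKKKKKKAA")
        hits = [n for n in scan_nls(p) if n.kind == "basic-rich"]
        assert len(hits) == 1
        assert hits[0].basic_count == 8


class TestColumnStats:
    def test_invariant_column_full_information(self):
        (s,) = column_stats(["A", "A", "A"])
        assert s.information == pytest.approx(MAX_IC)
        assert s.consensus == "A" and s.gap_fraction == 0.0

    def test_binary_split_loses_one_bit(self):
        (s,) = column_stats(["D"] * 10 + ["E"] * 10, t=0.5)
        assert s.information == pytest.approx(MAX_IC - 1.0)
        assert s.consensus == "x"

    def test_uniform_column_zero_information(self):
        (s,) = column_stats(list("ACDEFGHIKLMNPQRSTVWY"))
        assert s.information == pytest.approx(0.0, abs=1e-12)

    def test_all_gap_column(self):
        (s,) = column_stats(["-", "-"])
        assert s.information is None and s.consensus == "x"
        assert s.gap_fraction == 1.0

    def test_gap_fraction_separate_from_frequencies(self):
        (s,) = column_stats(["A", "A", "-", "-"])
        assert s.gap_fraction == 0.5
        assert s.information == pytest.approx(MAX_IC)  # gaps excluded

    def test_consensus_threshold(self):
        rows = ["A"] * 6 + ["V"] * 4
        (s5,) = column_stats(rows, t=0.5)
        (s7,) = column_stats(rows, t=0.7)
        assert s5.consensus == "A" and s7.consensus == "x"

    def test_information_decreases_under_progressive_randomization(self):
        rng = random.Random(21)
        rows = ["A"] * 40
        ics = []
        for _ in range(12):
            (s,) = column_stats(rows)
            ics.append(s.information)
            i = rng.randrange(len(rows))
            rows[i] = rng.choice("CDEFGHIKLMNPQRSTVWY")
        # monotone apart from replacements that hit an already-mutated row
        assert all(b <= a + 1e-9 for a, b in zip(ics, ics[1:]))

    def test_non_rectangular_rejected(self):
        with pytest.raises(ValueError, match="rectangular"):
            column_stats(["AA", "A"])

    def test_consensus_string_helper(self):
        stats = column_stats(["AC", "AC", "AG"], t=0.7)
        assert consensus_string(stats) == "Ax"
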