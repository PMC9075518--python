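"""The synthetic repertoire generator: determinism, boxes, noise model."""

import hashlib

import pytest

from shsp.detect import detect_acds, trim_core
from shsp.orf import translate_six_frames
from shsp.physchem import profile_protein
from shsp.seqio import ProteinRecord
from shsp.simulate import GeneratorConfig, generate_repertoire, make_template
from shsp.templates import ACD_BOXES, CLUSTERS, PROTEIN_BOXES
from shsp.motifs import B1_FXSES, B1_KRICH, scan_motif


class TestTemplates:
    @pytest.mark.parametrize("label", CLUSTERS)
    def test_template_inside_published_boxes(self, label):
        t = make_template(label)
        core = t.core_seqs[0]
        prof = profile_protein(label, t.seq, core)
        pb, ab = PROTEIN_BOXES[label], ACD_BOXES[label]
        assert pb["length_aa"][0] <= prof.length_aa <= pb["length_aa"][1]
        assert pb["mw_kda"][0] <= prof.mw_kda <= pb["mw_kda"][1]
        assert pb["pi"][0] <= prof.pi_protein <= pb["pi"][1]
        assert pb["gravy"][0] <= prof.gravy_protein <= pb["gravy"][1]
        assert ab["pi"][0] <= prof.pi_acd <= ab["pi"][1]
        assert ab["gravy"][0] <= prof.gravy_acd <= ab["gravy"][1]
        assert ab["core_len"][0] <= len(core) <= ab["core_len"][1]

    def test_b1_signature_motifs_in_their_zones(self):
        t = make_template("B1")
        segs = t.segments[0]
        z0, z1 = segs["b5"][0], segs["L57"][1]
        assert scan_motif(t.seq[z0:z1], B1_KRICH)
        l0, l1 = segs["L34"]
        assert scan_motif(t.seq[l0:l1], B1_FXSES)

    def test_dimeric_template_structure(self):
        t = make_template("dimeric")
        assert len(t.cores) == 2
        (s1, e1), (s2, e2) = t.cores
        linker = s2 - e1
        assert 15 <= linker <= 40
        up = t.seq[s1:e1]
        for lab in CLUSTERS:
            mono = make_template(lab).core_seqs[0]
            n = min(len(up), len(mono))
            diverged = sum(a != b for a, b in zip(up[:n], mono[:n])) / n
            assert diverged >= 0.30, f"upstream core too close to {lab}"

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            make_template("Z9")


class TestGeneratorConfig:
    def test_seed_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            GeneratorConfig()

    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            GeneratorConfig(seed=1, sub_rate_loop=1.5)

    def test_unknown_cluster_rejected(self):
        with pytest.raises(ValueError, match="unknown cluster"):
            GeneratorConfig(seed=1, n_per_cluster={"Q7": 1})


def _hash_outputs(rep, tmpdir):
    paths = rep.write(tmpdir)
    return {
        k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in paths.items()
    }


class TestGenerateRepertoire:
    def test_byte_identical_for_same_seed(self, tmp_path):
        cfg = dict(
            n_per_cluster={"A1": 2, "B1": 2, "dimeric": 2},
            sub_rate_strand=0.02, sub_rate_loop=0.05,
            n_random_decoys=3, n_near_miss_decoys=3, seed=42,
        )
        h1 = _hash_outputs(generate_repertoire(GeneratorConfig(**cfg)),
                           tmp_path / "a")
        h2 = _hash_outputs(generate_repertoire(GeneratorConfig(**cfg)),
                           tmp_path / "b")
        assert h1 == h2

    def test_truth_rows_cover_all_plants_and_decoys(self):
        cfg = GeneratorConfig(
            n_per_cluster={"A1": 2, "A2": 1, "dimeric": 2},
            n_random_decoys=4, n_near_miss_decoys=3, seed=8,
        )
        rep = generate_repertoire(cfg)
        assert len(rep.truth) == 2 + 1 + 2 + 4 + 3
        assert len(rep.transcripts) == len(rep.truth)

    def test_truth_coordinates_match_an_orf(self):
        cfg = GeneratorConfig(
            n_per_cluster={"B2": 2, "dimeric": 1}, seed=12,
            n_random_decoys=0, n_near_miss_decoys=0,
        )
        rep = generate_repertoire(cfg)
        proteins = {r.id: r for r in rep.proteins}
        for tr in rep.truth:
            tx = next(t for t in rep.transcripts if t.id == tr.transcript_id)
            orfs = translate_six_frames(tx, min_aa=50)
            planted = proteins[tr.protein_id].seq
            assert any(o.seq == planted for o in orfs), tr.protein_id
            for s, e in tr.acd_coords:
                hits, _ = detect_acds(ProteinRecord("x", planted))
                assert any(h.start == s or abs(h.start - s) <= 2 for h in hits)

    def test_truncated_fraction_yields_incomplete_orfs(self):
        cfg = GeneratorConfig(
            n_per_cluster={"B1": 6}, frac_truncated=1.0, seed=5,
            n_random_decoys=0, n_near_miss_decoys=0,
        )
        rep = generate_repertoire(cfg)
        assert all(not r.complete for r in rep.truth)
        for tx in rep.transcripts:
            orfs = translate_six_frames(tx, min_aa=50)
            longest = max(orfs, key=lambda o: len(o.seq))
            assert not longest.complete

    def test_zero_rate_perfect_recovery(self, model, threshold):
        from shsp.classify import assign_cluster

        cfg = GeneratorConfig(
            n_per_cluster={k: 5 for k in CLUSTERS},
            sub_rate_strand=0.0, sub_rate_loop=0.0, loop_indel_rate=0.0,
            n_random_decoys=0, n_near_miss_decoys=0, seed=20,
        )
        rep = generate_repertoire(cfg)
        truth = {r.protein_id: r.label for r in rep.truth}
        recovered = 0
        for p in rep.proteins:
            hits, arch = detect_acds(p, model, threshold)
            assert arch.label == "monomeric"
            core = trim_core(hits[0], p)
            prof = profile_protein(p.id, p.seq, core)
            if assign_cluster(p, hits[0], prof).label == truth[p.id]:
                recovered += 1
        assert recovered == 25

    def test_zero_rate_dimeric_all_detected(self, model, threshold):
        cfg = GeneratorConfig(
            n_per_cluster={"dimeric": 10},
            sub_rate_strand=0.0, sub_rate_loop=0.0, loop_indel_rate=0.0,
            n_random_decoys=0, n_near_miss_decoys=0, seed=21,
        )
        rep = generate_repertoire(cfg)
        for p in rep.proteins:
            _, arch = detect_acds(p, model, threshold)
            assert arch.label == "dimeric"

    def test_monotone_score_degradation(self, model, threshold):
        """Mean detection score never increases with the substitution rate."""
        means = []
        for rate in (0.0, 0.02, 0.05, 0.10):
            cfg = GeneratorConfig(
                n_per_cluster={k: 2 for k in CLUSTERS},
                sub_rate_strand=rate, sub_rate_loop=rate, loop_indel_rate=0.0,
                n_random_decoys=0, n_near_miss_decoys=0, seed=30,
            )
            rep = generate_repertoire(cfg)
            scores = []
            for p in rep.proteins:
                hits, _ = detect_acds(p, model, threshold)
                scores.extend(h.score for h in hits)
            means.append(sum(scores) / len(scores))
        assert all(b <= a + 1e-9 for a, b in zip(means, means[1:])), means
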