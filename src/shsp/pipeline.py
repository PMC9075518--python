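"""End-to-end orchestration: translate → scan → profile → classify → align → tree.

One reproducible run over a FASTA input (nucleotide transcripts or
proteins), driven by a RunConfig that is serialized into the output
directory next to the results.  Stage outputs use stable filenames and
contain no timestamps, so a rerun with identical config and inputs is
byte-identical.  Exact-duplicate translated proteins are collapsed before
analysis (the de-duplication criterion is exact sequence identity;
full-identity containment is flagged in the log but kept).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .align import UnalignableCoreError, align_cores
from .classify import DEFAULT_CUTOFFS, assign_cluster, scan_nls
from .conservation import column_stats
from .detect import detect_acds, trim_core
from .model import build_default_model, default_threshold
from .orf import translate_all
from .physchem import profile_protein, summarize_groups
from .seqio import ProteinRecord, read_fasta, write_fasta
from .tree import bootstrap_supports, p_distance_matrix

log = logging.getLogger("shsp")


@dataclass
class RunConfig:
    input_fasta: str
    outdir: str
    seed: int
    input_kind: str = "auto"  # nucleotide | protein | auto
    min_aa: int = 50
    genetic_code: int = 1
    threshold_bits: float | None = None  # None -> calibrated default
    pka_table: str = "sms"
    cutoffs: dict = field(default_factory=dict)
    bootstrap_reps: int = 100
    consensus_threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "input_fasta": self.input_fasta,
            "outdir": self.outdir,
            "seed": self.seed,
            "input_kind": self.input_kind,
            "min_aa": self.min_aa,
            "genetic_code": self.genetic_code,
            "threshold_bits": self.threshold_bits,
            "pka_table": self.pka_table,
            "cutoffs": self.cutoffs,
            "bootstrap_reps": self.bootstrap_reps,
            "consensus_threshold": self.consensus_threshold,
        }


@dataclass
class RunSummary:
    counts: dict
    provenance: dict

    def validate(self) -> None:
        c = self.counts
        assert (
            c["monomeric"] + c["dimeric"] + c["multi"] == c["proteins_with_acd"]
        ), "architecture counts do not add up"
        assert (
            sum(c["per_cluster"].values()) == c["monomeric"]
        ), "per-cluster counts do not sum to monomeric"


class StageError(RuntimeError):
    def __init__(self, stage: str, record_id: str | None, cause: Exception):
        self.stage = stage
        self.record_id = record_id
        super().__init__(
            f"stage {stage!r} failed"
            + (f" on record {record_id!r}" if record_id else "")
            + f": {cause}"
        )


def run_all(config: RunConfig) -> RunSummary:
    """Run the whole pipeline; writes all stage outputs under config.outdir."""
    # ---- input + translation (validated before any output is written) ---
    try:
        records = read_fasta(config.input_fasta, kind=config.input_kind)
    except Exception as e:
        raise StageError("read_input", None, e) from e

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    n_transcripts = 0
    if records and isinstance(records[0], ProteinRecord):
        proteins = records
    else:
        n_transcripts = len(records)
        try:
            proteins = translate_all(
                records, genetic_code=config.genetic_code, min_aa=config.min_aa
            )
        except Exception as e:
            raise StageError("translate", None, e) from e
    n_orfs = len(proteins)

    # de-duplicate exact sequences
    seen: dict[str, str] = {}
    unique: list[ProteinRecord] = []
    for p in proteins:
        if p.seq in seen:
            log.info("dedup: %s identical to %s, collapsed", p.id, seen[p.seq])
            continue
        seen[p.seq] = p.id
        unique.append(p)
    for p in unique:  # containment is only flagged, never dropped
        for q in unique:
            if p.id != q.id and p.seq != q.seq and p.seq in q.seq:
                log.info("containment: %s contained in %s (kept)", p.id, q.id)
    proteins = unique
    write_fasta(proteins, outdir / "proteins.faa")

    # ---- scan -----------------------------------------------------------
    model = build_default_model()
    threshold = (
        config.threshold_bits if config.threshold_bits is not None
        else default_threshold()
    )
    hits_rows = []
    arch_of = {}
    hits_of = {}
    for p in proteins:
        try:
            hits, arch = detect_acds(p, model, threshold)
        except Exception as e:
            raise StageError("scan", p.id, e) from e
        arch_of[p.id] = arch
        hits_of[p.id] = hits
        for h in hits:
            anchors = ";".join(
                f"{s}:{a}-{b}" for s, (a, b) in sorted(h.anchors.items())
            )
            hits_rows.append(
                f"{p.id}\t{h.start}\t{h.end}\t{h.score:.2f}\t{h.rank}\t{anchors}"
            )
    (outdir / "hits.tsv").write_text(
        "protein_id\tstart\tend\tscore_bits\trank\tanchors\n"
        + "".join(r + "\n" for r in hits_rows)
    )

    # ---- profile + classify + NLS --------------------------------------
    prof_rows, assign_rows, nls_rows = [], [], []
    labels = {}
    cores = []
    profiles = []
    for p in proteins:
        hits = hits_of[p.id]
        core = None
        if arch_of[p.id].label == "monomeric":
            core = trim_core(hits[0], p)
        try:
            prof = profile_protein(
                p.id, p.seq, core, complete=p.complete, pka_table=config.pka_table
            )
        except Exception as e:
            raise StageError("profile", p.id, e) from e
        profiles.append(prof)
        prof_rows.append(
            f"{p.id}\t{prof.length_aa}\t{prof.mw_kda:.3f}\t{prof.pi_protein:.2f}\t"
            f"{prof.gravy_protein:.3f}\t"
            + (f"{prof.pi_acd:.2f}" if prof.pi_acd is not None else "NA") + "\t"
            + (f"{prof.gravy_acd:.3f}" if prof.gravy_acd is not None else "NA")
            + f"\t{int(prof.complete)}"
        )
        if arch_of[p.id].label == "monomeric":
            try:
                asg = assign_cluster(p, hits[0], prof, cutoffs=config.cutoffs)
            except Exception as e:
                raise StageError("classify", p.id, e) from e
            labels[p.id] = asg.label
            fired = ";".join(name for name, _ in asg.fired_rules)
            assign_rows.append(
                f"{p.id}\t{asg.label}\t{asg.confidence:.2f}\t{fired}"
            )
            for nls in scan_nls(p, hits[0]):
                nls_rows.append(
                    f"{p.id}\t{nls.start}\t{nls.end}\t{nls.kind}\t{nls.basic_count}"
                )
            cores.append((p.id, core))
    (outdir / "profiles.tsv").write_text(
        "protein_id\tlength_aa\tmw_kda\tpi_protein\tgravy_protein\tpi_acd\t"
        "gravy_acd\tcomplete\n" + "".join(r + "\n" for r in prof_rows)
    )
    (outdir / "assignments.tsv").write_text(
        "protein_id\tlabel\tconfidence\tfired_rules\n"
        + "".join(r + "\n" for r in assign_rows)
    )
    (outdir / "nls.tsv").write_text(
        "protein_id\tstart\tend\tkind\tbasic_count\n"
        + "".join(r + "\n" for r in nls_rows)
    )

    # group summary over monomeric proteins
    mono_profiles = [pr for pr in profiles if pr.protein_id in labels]
    summaries = summarize_groups(mono_profiles, labels) if mono_profiles else []
    with open(outdir / "group_summary.tsv", "w") as fh:
        fh.write("group\tn\tmetric\tq1\tq3\n")
        for s in summaries:
            for metric, box in s.iqr.items():
                if box is None:
                    fh.write(f"{s.group}\t{s.n}\t{metric}\tNA\tNA\n")
                else:
                    fh.write(
                        f"{s.group}\t{s.n}\t{metric}\t{box[0]:.3f}\t{box[1]:.3f}\n"
                    )

    # ---- align + tree ---------------------------------------------------
    tree_newick = None
    if len(cores) >= 3:
        try:
            msa = align_cores(cores, model)
            with open(outdir / "cores.aln.faa", "w") as fh:
                for cid, row in zip(msa.ids, msa.rows):
                    fh.write(f">{cid}\n{row}\n")
            stats = column_stats(msa.rows, t=config.consensus_threshold)
            with open(outdir / "column_stats.tsv", "w") as fh:
                fh.write("column\tsegment\tinformation_bits\tgap_fraction\t"
                         "consensus\tcounts\n")
                for cs, seg in zip(stats, msa.column_labels):
                    ic = f"{cs.information:.3f}" if cs.information is not None else "NA"
                    counts = ",".join(
                        f"{a}:{c}" for a, c in sorted(cs.counts.items())
                    )
                    fh.write(
                        f"{cs.index}\t{seg}\t{ic}\t{cs.gap_fraction:.3f}\t"
                        f"{cs.consensus}\t{counts}\n"
                    )
            d = p_distance_matrix(msa)
            with open(outdir / "distances.tsv", "w") as fh:
                fh.write(f"{len(msa.ids)}\n")
                for i, cid in enumerate(msa.ids):
                    fh.write(cid + "\t" + "\t".join(f"{x:.6f}" for x in d[i]) + "\n")
            tree = bootstrap_supports(
                msa, n_reps=config.bootstrap_reps, seed=config.seed
            )
            tree_newick = tree.newick()
            (outdir / "tree.nwk").write_text(tree_newick + "\n")
        except UnalignableCoreError as e:
            log.warning("tree stage skipped: %s", e)

    # ---- summary --------------------------------------------------------
    arch_counts = {"monomeric": 0, "dimeric": 0, "multi": 0, "none": 0}
    for a in arch_of.values():
        arch_counts[a.label] += 1
    per_cluster: dict[str, int] = {}
    for lab in labels.values():
        per_cluster[lab] = per_cluster.get(lab, 0) + 1
    counts = {
        "transcripts": n_transcripts,
        "orfs": n_orfs,
        "proteins_unique": len(proteins),
        "proteins_with_acd": sum(
            v for k, v in arch_counts.items() if k != "none"
        ),
        "monomeric": arch_counts["monomeric"],
        "dimeric": arch_counts["dimeric"],
        "multi": arch_counts["multi"],
        "per_cluster": per_cluster,
    }
    # hash of the analysis parameters (output location excluded)
    hashed = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    config_hash = hashlib.sha256(yaml.safe_dump(hashed).encode()).hexdigest()[:12]
    summary = RunSummary(
        counts=counts,
        provenance={
            "version": __version__,
            "config_sha256": config_hash,
            "threshold_bits": round(float(threshold), 4),
            "pka_table": config.pka_table,
        },
    )
    summary.validate()
    (outdir / "summary.json").write_text(
        json.dumps({"counts": summary.counts, "provenance": summary.provenance},
                   indent=1)
    )
    return summary
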