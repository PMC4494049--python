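"""End-to-end annotation run: config, orchestration, persisted artifacts.

``run_annotate`` wires preprocessing, the iterative annotation driver,
dataset partitioning and per-dataset consensus building, persisting every
intermediate as a declared text format (FASTA / TSV / id lists) so each
stage is independently re-runnable, and writes a machine-readable JSON
manifest (config hash, seed, per-stage and per-category counts; the
category counts always sum to the number of annotated queries).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from saurannot import __version__
from saurannot.consensus import (
    build_consensus,
    consensus_to_record,
    coverage_stats,
)
from saurannot.homology import (
    AnnotationRecord,
    ReferenceDatabase,
    annotate_iterative,
    partition_datasets,
)
from saurannot.preprocess import cluster_redundant, filter_short
from saurannot.search import PROFILES, SearchParams, get_profile
from saurannot.seqio import SequenceRecord, read_fasta, write_fasta

__all__ = ["PipelineConfig", "StageConfig", "load_config", "run_annotate"]

logger = logging.getLogger("saurannot")

_ALLOWED_KINDS = ("mtDNA", "ncRNA", "cDNA", "unigene", "taxon_mRNA")


@dataclass
class StageConfig:
    kind: str
    label: str
    path: str
    profile: str | None = None


@dataclass
class PipelineConfig:
    stages: list[StageConfig]
    seed: int = 0
    max_excluded_len: int = 90
    cluster_identity: float = 0.95
    profiles: dict[str, dict] = field(default_factory=dict)
    raw: dict = field(default_factory=dict, repr=False)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def resolve_params(self, stage: StageConfig) -> SearchParams | None:
        if stage.profile is None:
            return None
        if stage.profile in self.profiles:
            return SearchParams(**self.profiles[stage.profile])
        return get_profile(stage.profile)


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "stages" not in raw or not raw["stages"]:
        raise ValueError(f"{path}: pipeline config must declare a non-empty 'stages' list")
    stages = []
    for i, s in enumerate(raw["stages"]):
        kind = s.get("kind")
        if kind not in _ALLOWED_KINDS:
            raise ValueError(f"{path}: stage {i}: kind {kind!r} not in {_ALLOWED_KINDS}")
        stage_path = (path.parent / s["path"]).resolve() if not Path(s["path"]).is_absolute() else Path(s["path"])
        if not stage_path.exists():
            raise FileNotFoundError(f"{path}: stage {i} ({s.get('label')}): no such file {stage_path}")
        stages.append(
            StageConfig(kind=kind, label=s.get("label", f"stage{i}"), path=str(stage_path),
                        profile=s.get("profile"))
        )
    cfg = PipelineConfig(
        stages=stages,
        seed=int(raw.get("seed", 0)),
        max_excluded_len=int(raw.get("max_excluded_len", 90)),
        cluster_identity=float(raw.get("cluster_identity", 0.95)),
        profiles=raw.get("profiles", {}) or {},
        raw=raw,
    )
    for name in (s.profile for s in stages if s.profile):
        if name not in cfg.profiles and name not in PROFILES:
            raise ValueError(f"{path}: unknown search profile {name!r}")
    return cfg


def write_annotations_tsv(records: Sequence[AnnotationRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tcategory\tstage\treference_label\tsubject_id\tevalue\tpident\tlength\trbbh\n")
        for r in records:
            h = r.best_hit
            fh.write(
                "\t".join(
                    [
                        r.query_id,
                        r.category,
                        str(r.stage_index),
                        r.reference_label,
                        r.subject_id or ".",
                        repr(h.e_value) if h else ".",
                        f"{h.percent_identity:.2f}" if h else ".",
                        str(h.alignment_length) if h else ".",
                        "1" if r.rbbh else "0",
                    ]
                )
                + "\n"
            )


def _write_consensus_outputs(
    records_in_set: list[AnnotationRecord],
    seq_by_id: Mapping[str, SequenceRecord],
    anchor_by_id: Mapping[str, SequenceRecord],
    outdir: Path,
) -> dict[str, Any]:
    outdir.mkdir(parents=True, exist_ok=True)
    groups: dict[str, list[AnnotationRecord]] = {}
    for r in records_in_set:
        groups.setdefault(r.subject_id, []).append(r)
    consensuses = []
    for anchor_id in sorted(groups):
        members = [seq_by_id[r.query_id] for r in groups[anchor_id]]
        hits = {r.query_id: r.best_hit for r in groups[anchor_id]}
        consensuses.append(build_consensus(members, anchor_by_id[anchor_id], hits))
    write_fasta(
        [consensus_to_record(c) for c in consensuses], outdir / "consensus.fasta"
    )
    with open(outdir / "members.tsv", "w") as fh:
        fh.write("anchor\tmember\tanchor_start\tanchor_end\tstrand\n")
        for c in consensuses:
            for m in c.members:
                fh.write(f"{c.name}\t{m.member_id}\t{m.anchor_start}\t{m.anchor_end}\t{m.strand}\n")
    with open(outdir / "stats.tsv", "w") as fh:
        fh.write("anchor\tkind\tn_members\tcoverage_fraction\tgap5\tgapMid\tgap3\n")
        for c in consensuses:
            st = coverage_stats(c)
            fh.write(
                f"{c.name}\t{c.kind}\t{len(c.members)}\t{st.coverage_fraction:.4f}\t"
                f"{st.gap5:.2f}\t{st.gap_mid:.2f}\t{st.gap3:.2f}\n"
            )
    n_many = sum(1 for c in consensuses if c.kind == "one_to_many")
    return {
        "n_consensuses": len(consensuses),
        "n_one_to_many": n_many,
        "mean_coverage_fraction": (
            sum(c.coverage_fraction for c in consensuses) / len(consensuses)
            if consensuses else 0.0
        ),
    }


def run_annotate(
    config: PipelineConfig | str | Path,
    queries_path: str | Path,
    outdir: str | Path,
) -> Path:
    """Run the full annotation pipeline and persist all artifacts.

    preprocess -> iterative annotation -> dataset partition -> consensus
    per data set -> statistics + manifest.  Reruns with identical config
    and inputs are byte-identical (the built-in engine is deterministic).
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    queries = read_fasta(queries_path)
    if not queries:
        raise ValueError(f"{queries_path}: empty query file")

    logger.info("preprocess: %d input sequences", len(queries))
    kept = filter_short(queries, config.max_excluded_len)
    reps, cmap = cluster_redundant(kept, identity_threshold=config.cluster_identity)
    write_fasta(reps, outdir / "preprocessed.fasta")
    with open(outdir / "clusters.tsv", "w") as fh:
        for rep, members in cmap.clusters.items():
            for m in members:
                fh.write(f"{rep}\t{m}\n")
    logger.info("preprocess: %d after length filter, %d representatives", len(kept), len(reps))

    stages = [
        ReferenceDatabase(
            label=s.label, db_kind=s.kind, records=read_fasta(s.path),
            params=config.resolve_params(s),
        )
        for s in config.stages
    ]
    records = annotate_iterative(reps, stages)
    write_annotations_tsv(records, outdir / "annotations.tsv")

    annotation_ids, phylogeny_ids = partition_datasets(records)
    (outdir / "annotation_set.txt").write_text("".join(i + "\n" for i in annotation_ids))
    (outdir / "phylogeny_set.txt").write_text("".join(i + "\n" for i in phylogeny_ids))

    seq_by_id = {r.id: r for r in reps}
    anchor_by_id: dict[str, SequenceRecord] = {}
    for db in stages:
        for rec in db.records:
            anchor_by_id.setdefault(rec.id, rec)
    rec_by_qid = {r.query_id: r for r in records}
    consensus_summary = {}
    for set_name, ids in (("annotation", annotation_ids), ("phylogeny", phylogeny_ids)):
        in_set = [rec_by_qid[i] for i in ids]
        consensus_summary[set_name] = _write_consensus_outputs(
            in_set, seq_by_id, anchor_by_id, outdir / set_name
        )

    category_counts: dict[str, int] = {}
    for r in records:
        category_counts[r.category] = category_counts.get(r.category, 0) + 1
    stage_counts: dict[str, int] = {}
    for r in records:
        key = f"{r.stage_index}:{r.reference_label or r.category}"
        stage_counts[key] = stage_counts.get(key, 0) + 1
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_input": len(queries),
        "n_after_length_filter": len(kept),
        "n_representatives": len(reps),
        "category_counts": category_counts,
        "stage_counts": stage_counts,
        "consensus": consensus_summary,
        "stages": [
            {"kind": s.kind, "label": s.label, "path": s.path, "profile": s.profile}
            for s in config.stages
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir
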