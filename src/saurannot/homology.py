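"""RBBH detection and the iterative multi-reference annotation driver.

The driver runs an ordered list of reference databases: a mitochondrial
genome and pooled ncRNA set first (nucleotide search), then per reference
species coding cDNA and EST-cluster (UniGene-style) databases with RBBH
identification (translated search, closest species first), then a taxon
mRNA collection (translated), then an optional cross-transcriptome
comparison and a pluggable repeat-masking hook.  A query annotated at one
stage is excluded from all later stages; queries exhausting every stage
are orphans (taxonomically restricted or unannotatable sequences).

Within the run of consecutive RBBH-capable stages (cDNA/UniGene), only an
RBBH finalizes a query early; a plain one-directional hit is kept as a
candidate and the query continues to the next reference species, its
final category being decided by the best-ranked candidate when the block
ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from saurannot.seqio import SearchHit, SequenceRecord
from saurannot.search import (
    BestMatch,
    SearchParams,
    best_match,
    best_matches_by_query,
    get_profile,
    search,
)

__all__ = [
    "ReferenceDatabase",
    "AnnotationRecord",
    "RBBHPair",
    "AnnotatedDataset",
    "CATEGORIES",
    "find_rbbh",
    "annotate_iterative",
    "cross_dataset_compare",
    "partition_datasets",
]

#: search mode fixed per database kind unless overridden
_MODE_BY_KIND = {
    "mtDNA": "nucleotide",
    "ncRNA": "nucleotide",
    "cDNA": "translated",
    "unigene": "translated",
    "taxon_mRNA": "translated",
}

#: database kinds whose stages participate in RBBH identification
_RBBH_KINDS = frozenset({"cDNA", "unigene"})

_CATEGORY_BY_KIND = {
    "mtDNA": "mtDNA",
    "ncRNA": "ncRNA",
    "taxon_mRNA": "taxon_mrna",
}

CATEGORIES = (
    "mtDNA",
    "ncRNA",
    "cdna_rbbh",
    "cdna_hit",
    "unigene_rbbh",
    "unigene_hit",
    "taxon_mrna",
    "cross_species",
    "repeat",
    "orphan",
)


@dataclass
class ReferenceDatabase:
    """One stage of the iterative annotation: a labelled reference FASTA.

    ``label`` names the reference species or collection; ``db_kind`` is one
    of mtDNA / ncRNA / cDNA / unigene / taxon_mRNA and fixes the search
    mode (nucleotide for mtDNA and ncRNA, translated otherwise) unless
    ``params`` overrides it.
    """

    label: str
    db_kind: str
    records: Sequence[SequenceRecord]
    params: SearchParams | None = None

    def __post_init__(self) -> None:
        if self.db_kind not in _MODE_BY_KIND:
            raise ValueError(
                f"unknown db_kind {self.db_kind!r}; expected one of {sorted(_MODE_BY_KIND)}"
            )
        if not self.records:
            raise ValueError(f"reference database {self.label!r} has no records")
        if self.params is None:
            self.params = get_profile(_MODE_BY_KIND[self.db_kind])
        expected = _MODE_BY_KIND[self.db_kind]
        if self.params.mode != expected:
            raise ValueError(
                f"stage {self.label!r} (kind {self.db_kind}) configured with "
                f"{self.params.mode} search; {expected} expected"
            )


@dataclass
class AnnotationRecord:
    """Final outcome of the iterative pipeline for one query."""

    query_id: str
    category: str
    stage_index: int = -1
    reference_label: str = ""
    subject_id: str | None = None
    best_hit: SearchHit | None = None
    rbbh: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "orphan" and self.subject_id is not None:
            raise ValueError("orphan records cannot carry a subject")
        if self.rbbh and self.category not in ("cdna_rbbh", "unigene_rbbh"):
            raise ValueError("rbbh flag is reserved for cdna_rbbh/unigene_rbbh")


@dataclass(frozen=True)
class RBBHPair:
    """A reciprocal best hit: q's best subject is s and s's best subject is q."""

    query_id: str
    subject_id: str
    forward: BestMatch
    reverse: BestMatch


def find_rbbh(
    forward_hits: Iterable[SearchHit], reverse_hits: Iterable[SearchHit]
) -> list[RBBHPair]:
    """Reciprocal best hits between two hit sets searched in both directions.

    ``forward_hits``: queries vs database; ``reverse_hits``: database
    sequences vs queries, under the same parameter profile.  (q, s) is a
    pair iff s is q's best match and q is s's best match, both under the
    ordered criteria.
    """
    fwd = best_matches_by_query(forward_hits)
    rev = best_matches_by_query(reverse_hits)
    pairs: list[RBBHPair] = []
    for qid, bm in fwd.items():
        sid = bm.subject_id
        back = rev.get(sid)
        if back is not None and back.subject_id == qid:
            pairs.append(RBBHPair(query_id=qid, subject_id=sid, forward=bm, reverse=back))
    return pairs


@dataclass
class _Candidate:
    stage_index: int
    db: ReferenceDatabase
    best: BestMatch


def _better(a: _Candidate, b: _Candidate) -> _Candidate:
    return a if a.best.hit.rank_key() <= b.best.hit.rank_key() else b


def annotate_iterative(
    queries: Sequence[SequenceRecord],
    stages: Sequence[ReferenceDatabase],
    masking_hook: Callable[[Sequence[SequenceRecord]], Mapping[str, float]] | None = None,
    masked_fraction_threshold: float = 0.5,
) -> list[AnnotationRecord]:
    """Run the ordered annotation stages over preprocessed queries.

    Every input query yields exactly one :class:`AnnotationRecord`.  A
    query annotated at stage k never reaches stage k+1; within a
    consecutive run of cDNA/UniGene stages only an RBBH finalizes early,
    while non-RBBH hits are carried as candidates and decided when the run
    ends.  ``masking_hook``, if given, receives the still-unannotated
    records and returns per-id masked fractions; ids at or above
    ``masked_fraction_threshold`` are labelled ``repeat``.  Everything
    left is an orphan.
    """
    if not stages:
        raise ValueError("annotate_iterative requires at least one stage")
    results: dict[str, AnnotationRecord] = {}
    remaining: list[SequenceRecord] = list(queries)
    pending: dict[str, _Candidate] = {}

    def finalize_pending() -> None:
        nonlocal remaining
        if not pending:
            return
        done: set[str] = set()
        for qid, cand in pending.items():
            category = "cdna_hit" if cand.db.db_kind == "cDNA" else "unigene_hit"
            results[qid] = AnnotationRecord(
                query_id=qid,
                category=category,
                stage_index=cand.stage_index,
                reference_label=cand.db.label,
                subject_id=cand.best.subject_id,
                best_hit=cand.best.hit,
                rbbh=False,
            )
            done.add(qid)
        pending.clear()
        remaining = [q for q in remaining if q.id not in done]

    for stage_index, db in enumerate(stages):
        if db.db_kind not in _RBBH_KINDS:
            finalize_pending()
        if not remaining:
            break
        forward = search(remaining, db.records, db.params)
        fwd_best = best_matches_by_query(forward)
        if db.db_kind in _RBBH_KINDS:
            reverse = search(db.records, remaining, db.params)
            rbbh_pairs = {p.query_id: p for p in find_rbbh(forward, reverse)}
            finalized: set[str] = set()
            for qid, bm in fwd_best.items():
                pair = rbbh_pairs.get(qid)
                if pair is not None:
                    category = "cdna_rbbh" if db.db_kind == "cDNA" else "unigene_rbbh"
                    results[qid] = AnnotationRecord(
                        query_id=qid,
                        category=category,
                        stage_index=stage_index,
                        reference_label=db.label,
                        subject_id=bm.subject_id,
                        best_hit=bm.hit,
                        rbbh=True,
                    )
                    finalized.add(qid)
                    pending.pop(qid, None)
                else:
                    cand = _Candidate(stage_index=stage_index, db=db, best=bm)
                    pending[qid] = _better(pending[qid], cand) if qid in pending else cand
            remaining = [q for q in remaining if q.id not in finalized]
        else:
            finalized = set()
            for qid, bm in fwd_best.items():
                results[qid] = AnnotationRecord(
                    query_id=qid,
                    category=_CATEGORY_BY_KIND[db.db_kind],
                    stage_index=stage_index,
                    reference_label=db.label,
                    subject_id=bm.subject_id,
                    best_hit=bm.hit,
                )
                finalized.add(qid)
            remaining = [q for q in remaining if q.id not in finalized]
    finalize_pending()

    if masking_hook is not None and remaining:
        masked = masking_hook(remaining)
        repeats = {
            qid for qid, frac in masked.items() if frac >= masked_fraction_threshold
        }
        for q in remaining:
            if q.id in repeats:
                results[q.id] = AnnotationRecord(
                    query_id=q.id, category="repeat", stage_index=len(stages)
                )
        remaining = [q for q in remaining if q.id not in repeats]

    for q in remaining:
        results[q.id] = AnnotationRecord(
            query_id=q.id, category="orphan", stage_index=len(stages)
        )
    return [results[q.id] for q in queries]


@dataclass
class AnnotatedDataset:
    """One species' annotation outcome: records plus the query sequences."""

    name: str
    records: list[AnnotationRecord]
    sequences: Mapping[str, SequenceRecord]

    def orphan_records(self) -> list[AnnotationRecord]:
        return [r for r in self.records if r.category == "orphan"]

    def annotated_ids(self) -> list[str]:
        ann, _ = partition_datasets(self.records)
        return ann


def cross_dataset_compare(
    datasets: Sequence[AnnotatedDataset],
    params: SearchParams | None = None,
) -> list[SearchHit]:
    """Compare each dataset's orphans with every other dataset (translated).

    Orphans of dataset A are searched against dataset B's annotation set
    and B's orphans, for all B != A.  An orphan with a hit is
    re-categorized ``cross_species`` (partner dataset recorded in
    ``reference_label``); when the matched partner sequence is itself an
    orphan, it is re-categorized symmetrically, so an a<->b match found
    once is recorded for both.  Records are updated in place; all passing
    hits are returned.  With fewer than two datasets this is the identity.
    """
    if len(datasets) < 2:
        return []
    params = params or get_profile("translated")
    by_name = {d.name: d for d in datasets}
    rec_index = {
        d.name: {r.query_id: r for r in d.records} for d in datasets
    }
    all_hits: list[SearchHit] = []
    matches: list[tuple[str, str, str, SearchHit]] = []  # (dataset, qid, partner, hit)
    for d in datasets:
        orphan_ids = [r.query_id for r in d.orphan_records()]
        orphan_seqs = [d.sequences[i] for i in orphan_ids if i in d.sequences]
        if not orphan_seqs:
            continue
        for other in datasets:
            if other.name == d.name:
                continue
            target_ids = other.annotated_ids() + [r.query_id for r in other.orphan_records()]
            target_seqs = [other.sequences[i] for i in target_ids if i in other.sequences]
            if not target_seqs:
                continue
            hits = search(orphan_seqs, target_seqs, params)
            all_hits.extend(hits)
            for qid, bm in best_matches_by_query(hits).items():
                matches.append((d.name, qid, other.name, bm.hit))
    # keep the best-ranked partner per orphan
    best_per_query: dict[tuple[str, str], tuple[str, SearchHit]] = {}
    for dname, qid, partner, hit in matches:
        key = (dname, qid)
        if key not in best_per_query or hit.rank_key() < best_per_query[key][1].rank_key():
            best_per_query[key] = (partner, hit)
    for (dname, qid), (partner, hit) in best_per_query.items():
        rec = rec_index[dname][qid]
        if rec.category != "orphan":
            continue
        rec.category = "cross_species"
        rec.reference_label = partner
        rec.subject_id = hit.subject_id
        rec.best_hit = hit
        # symmetric bookkeeping when the partner sequence is an orphan too
        partner_rec = rec_index[partner].get(hit.subject_id)
        if partner_rec is not None and partner_rec.category == "orphan":
            partner_rec.category = "cross_species"
            partner_rec.reference_label = dname
            partner_rec.subject_id = qid
            partner_rec.best_hit = hit
    return all_hits


def partition_datasets(records: Iterable[AnnotationRecord]) -> tuple[list[str], list[str]]:
    """Split annotation outcomes into the annotation and phylogeny id sets.

    The phylogeny set is the high-confidence RBBH subset (cDNA and
    UniGene RBBH); the annotation set adds the non-RBBH cDNA/UniGene
    matches and the taxon mRNA matches.  mtDNA, ncRNA, cross-species,
    repeat, and orphan records belong to neither set.
    """
    phylogeny = []
    annotation = []
    for r in records:
        if r.category in ("cdna_rbbh", "unigene_rbbh"):
            phylogeny.append(r.query_id)
            annotation.append(r.query_id)
        elif r.category in ("cdna_hit", "unigene_hit", "taxon_mrna"):
            annotation.append(r.query_id)
    return annotation, phylogeny
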