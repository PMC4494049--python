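"""Exon-projection genome annotation.

Annotates an unannotated genome from a related reference species: the
reference transcripts' exons, plus 1,000-base 5' and 3' flanks (to
capture UTRs), are extracted from the reference genome + GFF3, searched
against the target genome, and the matched target segments ("potential
exons", accepted at >= 80% alignment identity by default) are reassembled
into transcript consensuses by searching them against the reference cDNA
set with no minimum match length, so that even the shortest potential
exons can align.  A final filter restricts the result to a
phylogeny-grade set: consensuses longer than 90 bp, optionally named
after anchors with a required prefix (e.g., one reference species' gene
set).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

from saurannot.consensus import ConsensusSequence, build_consensus, group_by_anchor
from saurannot.search import SearchParams, best_matches_by_query, get_profile, search_nucleotide
from saurannot.seqio import SequenceRecord, reverse_complement

__all__ = [
    "ExonRecord",
    "PotentialExon",
    "extract_exons_flanks",
    "project_exons",
    "assemble_projected_transcripts",
    "filter_phylogeny_genome",
]


@dataclass(frozen=True)
class ExonRecord:
    """One reference exon or transcript flank, in transcript orientation."""

    source_transcript_id: str
    exon_index: int  # 0-based along the transcript; -1 for flanks
    role: str  # "exon" | "flank5" | "flank3"
    residues: str
    source_contig: str
    source_start: int  # 0-based half-open on the reference contig
    source_end: int
    strand: int

    @property
    def id(self) -> str:
        if self.role == "exon":
            return f"{self.source_transcript_id}|exon{self.exon_index}"
        return f"{self.source_transcript_id}|{self.role}"


@dataclass
class PotentialExon:
    """A target-genome segment matched by a reference exon or flank."""

    contig_id: str
    start: int  # 0-based half-open, forward strand of the target contig
    end: int
    strand: int
    residues: str
    provenance: list[ExonRecord]
    percent_identity: float

    @property
    def source_transcript_id(self) -> str:
        return self.provenance[0].source_transcript_id

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("potential exon requires end > start")


def _contig_map(genome: Sequence[SequenceRecord]) -> dict[str, SequenceRecord]:
    return {r.id: r for r in genome}


def extract_exons_flanks(
    reference_genome: Sequence[SequenceRecord],
    gff3_path: str | Path,
    flank_len: int = 1000,
) -> list[ExonRecord]:
    """Extract every transcript's exons plus its 5'/3' ``flank_len``-base flanks.

    Exons are returned in transcript orientation (minus-strand exons
    reverse-complemented, indexed 0.. along the transcript).  The 5' flank
    is the ``flank_len`` bases immediately upstream of the transcript span
    and the 3' flank immediately downstream, both truncated at contig
    edges.  Raises on exon coordinates outside their contig.
    """
    contigs = _contig_map(reference_genome)
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    by_transcript: dict[str, list] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent") or [exon.id]
        by_transcript.setdefault(parents[0], []).append(exon)

    out: list[ExonRecord] = []
    for tid, exons in by_transcript.items():
        exons.sort(key=lambda e: e.start)
        contig_id = exons[0].seqid
        contig = contigs.get(contig_id)
        if contig is None:
            raise ValueError(f"transcript {tid!r}: contig {contig_id!r} absent from genome")
        strand = -1 if exons[0].strand == "-" else 1
        span_start = exons[0].start - 1  # GFF3 is 1-based inclusive
        span_end = exons[-1].end
        ordered = exons if strand == 1 else list(reversed(exons))
        for idx, exon in enumerate(ordered):
            s, e = exon.start - 1, exon.end
            if s < 0 or e > len(contig):
                raise ValueError(
                    f"exon feature of transcript {tid!r} at {contig_id}:{exon.start}-{exon.end} "
                    f"outside contig of length {len(contig)}"
                )
            seq = contig.residues[s:e]
            if strand == -1:
                seq = reverse_complement(seq)
            out.append(
                ExonRecord(
                    source_transcript_id=tid,
                    exon_index=idx,
                    role="exon",
                    residues=seq,
                    source_contig=contig_id,
                    source_start=s,
                    source_end=e,
                    strand=strand,
                )
            )
        # flanks in transcript orientation; truncate at contig edges
        up = (max(0, span_start - flank_len), span_start)
        down = (span_end, min(len(contig), span_end + flank_len))
        five, three = (up, down) if strand == 1 else (down, up)
        for role, (s, e) in (("flank5", five), ("flank3", three)):
            if e <= s:
                continue
            seq = contig.residues[s:e]
            if strand == -1:
                seq = reverse_complement(seq)
            out.append(
                ExonRecord(
                    source_transcript_id=tid,
                    exon_index=-1,
                    role=role,
                    residues=seq,
                    source_contig=contig_id,
                    source_start=s,
                    source_end=e,
                    strand=strand,
                )
            )
    return out


def project_exons(
    exon_records: Sequence[ExonRecord],
    target_genome: Sequence[SequenceRecord],
    min_match_pct: float = 80.0,
    params: SearchParams | None = None,
) -> list[PotentialExon]:
    """Project reference exons/flanks onto the target genome.

    Each exon record is searched (nucleotide mode) against the target
    genome; the best hit with alignment identity >= ``min_match_pct``
    yields a potential exon covering the hit's subject interval.
    Overlapping projections of different records from the same source
    transcript are merged per contig and strand (interval union).
    Returns an empty list when nothing projects.
    """
    if params is None:
        params = get_profile("projection-reassembly")
    params = replace(params, min_percent_identity=min_match_pct)
    contigs = _contig_map(target_genome)
    queries = [SequenceRecord(id=er.id, residues=er.residues) for er in exon_records]
    by_id = {er.id: er for er in exon_records}
    hits = search_nucleotide(queries, target_genome, params)
    raw: list[PotentialExon] = []
    for qid, bm in best_matches_by_query(hits).items():
        h = bm.hit
        er = by_id[qid]
        contig = contigs[h.subject_id]
        raw.append(
            PotentialExon(
                contig_id=h.subject_id,
                start=h.subject_start,
                end=h.subject_end,
                strand=h.subject_frame,
                residues=contig.residues[h.subject_start:h.subject_end],
                provenance=[er],
                percent_identity=h.percent_identity,
            )
        )
    # merge overlapping projections per (transcript, contig, strand)
    groups: dict[tuple[str, str, int], list[PotentialExon]] = {}
    for pe in raw:
        groups.setdefault((pe.source_transcript_id, pe.contig_id, pe.strand), []).append(pe)
    merged: list[PotentialExon] = []
    for (tid, cid, strand), pes in groups.items():
        pes.sort(key=lambda p: p.start)
        cur = pes[0]
        for nxt in pes[1:]:
            if nxt.start <= cur.end:
                cur = PotentialExon(
                    contig_id=cid,
                    start=cur.start,
                    end=max(cur.end, nxt.end),
                    strand=strand,
                    residues=contigs[cid].residues[cur.start:max(cur.end, nxt.end)],
                    provenance=cur.provenance + nxt.provenance,
                    percent_identity=max(cur.percent_identity, nxt.percent_identity),
                )
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)
    merged.sort(key=lambda p: (p.contig_id, p.start, p.end))
    return merged


def assemble_projected_transcripts(
    potential_exons: Sequence[PotentialExon],
    cdna_db: Sequence[SequenceRecord],
    params: SearchParams | None = None,
) -> list[ConsensusSequence]:
    """Reassemble potential exons into transcript consensuses.

    Each potential exon is searched against the reference cDNA database
    with the minimum match length disabled; potential exons sharing a best
    cDNA anchor are assembled into a consensus named after that cDNA (via
    the anchored majority-rule builder).  The consensus is restricted to
    cDNA coordinates: member insertions relative to the cDNA are introns or
    flanking genomic sequence by construction and are excluded from the
    reassembled transcript.  Potential exons without a cDNA hit are
    dropped.  For dual-reference annotation, pass the
    concatenation of both cDNA sets.
    """
    if params is None:
        params = get_profile("projection-reassembly")
    if params.min_alignment_length is not None:
        raise ValueError(
            "transcript reassembly requires a profile with min_alignment_length disabled"
        )
    pe_records = [
        SequenceRecord(id=f"pe{k:06d}|{pe.contig_id}:{pe.start}-{pe.end}", residues=pe.residues)
        for k, pe in enumerate(potential_exons)
    ]
    hits = search_nucleotide(pe_records, cdna_db, params)
    best = best_matches_by_query(hits)
    groups = group_by_anchor(best)
    anchors = {r.id: r for r in cdna_db}
    rec_by_id = {r.id: r for r in pe_records}
    consensuses: list[ConsensusSequence] = []
    for anchor_id, member_ids in groups.items():
        members = [rec_by_id[m] for m in member_ids]
        member_hits = {m: best[m].hit for m in member_ids}
        consensuses.append(
            build_consensus(members, anchors[anchor_id], member_hits, keep_insertions=False)
        )
    consensuses.sort(key=lambda c: c.name)
    return consensuses


def filter_phylogeny_genome(
    consensuses: Iterable[ConsensusSequence],
    require_anchor_prefix: str | None = None,
    min_len_exclusive: int = 90,
) -> list[ConsensusSequence]:
    """Restrict genome-annotation consensuses to a phylogeny-grade set.

    Keeps consensuses whose non-gap length is strictly greater than
    ``min_len_exclusive`` (default: > 90 bp) and, when
    ``require_anchor_prefix`` is set, whose anchor name starts with that
    prefix (e.g., restricting crocodilian annotations to consensuses named
    after one reference species' transcripts).
    """
    out = []
    for c in consensuses:
        if c.nongap_length <= min_len_exclusive:
            continue
        if require_anchor_prefix is not None and not c.name.startswith(require_anchor_prefix):
            continue
        out.append(c)
    return out
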