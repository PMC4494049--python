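"""Anchored majority-rule consensus building and coverage statistics.

Input sequences whose best match is the same database sequence (the
*anchor*) are assembled into a consensus named after that anchor.  The
anchor only defines the coordinate frame: each member is placed on anchor
coordinates through its own pairwise alignment to the anchor, and per
anchor column the consensus emits the majority symbol among the covering
members — the anchor's residues never vote.  Anchor positions covered by
no member emit '-'.  A single matching input gives a "one-to-one"
consensus whose residues are the member's verbatim; two or more give a
"one-to-many" consensus.

Coverage statistics split the anchor into the 5' 30%, the middle 40% and
the 3' 30% and report the gap percentage of each region, to diagnose
end-biased transcript coverage.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from saurannot.search import BestMatch, SearchParams, make_aligner
from saurannot.seqio import SearchHit, SequenceRecord, reverse_complement

__all__ = [
    "ConsensusSequence",
    "MemberPlacement",
    "CoverageStats",
    "group_by_anchor",
    "build_consensus",
    "coverage_stats",
    "consensus_to_record",
]


@dataclass(frozen=True)
class MemberPlacement:
    """Where one member sits on the anchor (anchor coordinates, 0-based half-open)."""

    member_id: str
    anchor_start: int
    anchor_end: int
    strand: int  # +1 / -1 relative to the anchor


@dataclass
class ConsensusSequence:
    """A named consensus anchored on one database sequence.

    ``residues`` holds the consensus with majority-retained member
    insertions spliced in; for a one-to-one consensus it equals the sole
    member's residues verbatim.  ``anchor_residues`` is the consensus
    restricted to anchor coordinates (length ``anchor_length``, '-' at
    anchor positions covered by no member, insertions dropped), useful for
    column-wise comparison against the anchor.  ``anchor_covered`` marks,
    per anchor position, whether at least one member covers it.
    """

    name: str  # anchor id
    kind: str  # "one_to_one" | "one_to_many"
    members: list[MemberPlacement]
    residues: str
    anchor_length: int
    anchor_residues: str = field(repr=False, default="")
    anchor_covered: list[bool] = field(repr=False, default_factory=list)

    @property
    def coverage_fraction(self) -> float:
        return sum(self.anchor_covered) / self.anchor_length

    @property
    def nongap_length(self) -> int:
        return sum(1 for c in self.residues if c != "-")


def group_by_anchor(best_matches: Mapping[str, BestMatch] | Sequence[BestMatch]) -> dict[str, list[str]]:
    """Group query ids by the subject of their best match."""
    if isinstance(best_matches, Mapping):
        items = best_matches.values()
    else:
        items = best_matches
    groups: dict[str, list[str]] = {}
    for bm in items:
        groups.setdefault(bm.subject_id, []).append(bm.query_id)
    return groups


_PLACEMENT_PARAMS = SearchParams(e_value_max=float("inf"), min_alignment_length=None)
_PLACEMENT_ALIGNER = make_aligner(_PLACEMENT_PARAMS)


def _member_rank(hit: SearchHit) -> tuple:
    return hit.rank_key() + (hit.query_id,)


def build_consensus(
    member_records: Sequence[SequenceRecord],
    anchor_record: SequenceRecord,
    member_hits: Mapping[str, SearchHit],
    keep_insertions: bool = True,
    min_vote_segment: int = 11,
) -> ConsensusSequence:
    """Build the consensus of all members matching one anchor.

    ``member_hits`` maps each member id to its hit against the anchor (used
    for strand orientation and, through the ordered ranking criteria, for
    breaking voting ties in favour of the better-matching member).  A
    member without a hit to the anchor is a contract violation.

    Member insertions relative to the anchor are retained only when a
    strict majority of the members covering that junction carry an
    identical inserted sequence; otherwise they are dropped.  With
    ``keep_insertions`` False the consensus is restricted to anchor
    coordinates outright (used for transcripts reassembled from projected
    genome segments, whose insertions are introns by construction).

    Ungapped placement segments shorter than ``min_vote_segment`` columns
    cast no votes: a segment shorter than the seeding word size carries no
    seed support and is typically a chance pairing adjacent to an indel
    junction rather than genuine homology.
    """
    for m in member_records:
        if m.id not in member_hits:
            raise ValueError(f"member {m.id!r} has no hit against anchor {anchor_record.id!r}")
    L = len(anchor_record)

    # rank members by their hit under the ordered criteria (tie-break votes)
    ranked = sorted(member_records, key=lambda m: _member_rank(member_hits[m.id]))
    rank_of = {m.id: i for i, m in enumerate(ranked)}

    votes: list[list[tuple[str, int]]] = [[] for _ in range(L)]  # (symbol, member rank)
    # insertions[j] lists (inserted_seq, member rank) for insertions between
    # anchor positions j-1 and j
    insertions: dict[int, list[tuple[str, int]]] = {}
    placements: list[MemberPlacement] = []
    spans: dict[str, tuple[int, int]] = {}

    for m in member_records:
        hit = member_hits[m.id]
        strand = 1 if hit.subject_frame >= 0 else -1
        seq = m.residues if strand == 1 else reverse_complement(m.residues)
        aln = _PLACEMENT_ALIGNER.align(anchor_record.residues, seq)[0]
        coords = aln.coordinates  # row 0: anchor, row 1: member
        a_lo, a_hi = int(coords[0][0]), int(coords[0][-1])
        spans[m.id] = (a_lo, a_hi)
        placements.append(
            MemberPlacement(member_id=m.id, anchor_start=a_lo, anchor_end=a_hi, strand=strand)
        )
        r = rank_of[m.id]
        n_blocks = coords.shape[1] - 1
        for b in range(n_blocks):
            a0, a1 = int(coords[0][b]), int(coords[0][b + 1])
            m0, m1 = int(coords[1][b]), int(coords[1][b + 1])
            if a1 > a0 and m1 > m0:  # aligned block
                if a1 - a0 < min_vote_segment:
                    continue
                for off in range(a1 - a0):
                    votes[a0 + off].append((seq[m0 + off], r))
            elif a1 == a0 and m1 > m0:  # member insertion before anchor position a0
                insertions.setdefault(a0, []).append((seq[m0:m1], r))
            # a1 > a0 and m1 == m0: deletion in the member; no votes

    covered = [len(v) > 0 for v in votes]
    columns: list[str] = []
    for p in range(L):
        if not votes[p]:
            columns.append("-")
            continue
        counts = Counter(sym for sym, _ in votes[p])
        top = counts.most_common(1)[0][1]
        modal = [sym for sym, c in counts.items() if c == top]
        if len(modal) == 1:
            columns.append(modal[0])
        else:
            # tie: the symbol voted by the best-ranked member wins
            columns.append(
                min(modal, key=lambda sym: min(r for s, r in votes[p] if s == sym))
            )

    out: list[str] = []
    for p in range(L):
        ins = insertions.get(p)
        if ins:
            covering = sum(1 for s, e in spans.values() if s < p < e)
            counts = Counter(s for s, _ in ins)
            seq_, n = counts.most_common(1)[0]
            if covering > 0 and n > covering / 2:
                # among equally common insertion strings prefer the best-ranked voter
                best_seq = min(
                    (s for s, c in counts.items() if c == n),
                    key=lambda s: min(r for t, r in ins if t == s),
                )
                out.append(best_seq)
        out.append(columns[p])

    kind = "one_to_one" if len(member_records) == 1 else "one_to_many"
    if not keep_insertions:
        residues = "".join(columns)
    elif kind == "one_to_one":
        # one-to-one: the sole member's sequence verbatim takes the anchor's name
        residues = member_records[0].residues
    else:
        residues = "".join(out)
    return ConsensusSequence(
        name=anchor_record.id,
        kind=kind,
        members=placements,
        residues=residues,
        anchor_length=L,
        anchor_residues="".join(columns),
        anchor_covered=covered,
    )


@dataclass(frozen=True)
class CoverageStats:
    """Gap percentages of the 5' / middle / 3' anchor regions plus total coverage."""

    gap5: float
    gap_mid: float
    gap3: float
    coverage_fraction: float
    region_lengths: tuple[int, int, int]


def coverage_stats(consensus: ConsensusSequence) -> CoverageStats:
    """Per-region gap statistics on anchor coordinates.

    The anchor is partitioned into the 5' region (first ``round(0.3*L)``
    positions), the 3' region (last ``round(0.3*L)``) and the middle
    (remainder); the regions exhaust the anchor without overlap.  The gap
    percentage of a region is the fraction of its positions covered by no
    member.  Anchors shorter than 4 positions fall back to a single
    region with a warning.
    """
    L = consensus.anchor_length
    covered = consensus.anchor_covered
    if L < 4:
        warnings.warn(
            f"anchor {consensus.name!r} shorter than 4 positions: single-region statistics",
            stacklevel=2,
        )
        gap = 100.0 * (1 - sum(covered) / L)
        return CoverageStats(gap, gap, gap, consensus.coverage_fraction, (L, 0, 0))
    n_end = round(0.3 * L)
    n5, n3 = n_end, n_end
    nm = L - n5 - n3

    def gap_pct(lo: int, hi: int) -> float:
        n = hi - lo
        if n == 0:
            return 0.0
        return 100.0 * sum(1 for p in range(lo, hi) if not covered[p]) / n

    return CoverageStats(
        gap5=gap_pct(0, n5),
        gap_mid=gap_pct(n5, n5 + nm),
        gap3=gap_pct(n5 + nm, L),
        coverage_fraction=consensus.coverage_fraction,
        region_lengths=(n5, nm, n3),
    )


def consensus_to_record(
    consensus: ConsensusSequence, gaps_as: str = "N", strip_gaps: bool = False
) -> SequenceRecord:
    """Export a consensus as a sequence record for FASTA output.

    Uncovered anchor positions ('-') become runs of ``gaps_as`` (default
    'N'), or are stripped entirely with ``strip_gaps``.
    """
    residues = consensus.residues
    residues = residues.replace("-", "" if strip_gaps else gaps_as)
    return SequenceRecord(
        id=consensus.name,
        residues=residues,
        description=f"kind={consensus.kind} members={len(consensus.members)}",
    )
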