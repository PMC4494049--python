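"""Unit tests for consensus building rules not covered by the acceptance suite."""

from __future__ import annotations

import numpy as np
import pytest

from helpers import random_dna, rc
from saurannot.consensus import (
    build_consensus,
    consensus_to_record,
    coverage_stats,
    group_by_anchor,
)
from saurannot.search import BestMatch
from saurannot.seqio import SearchHit, SequenceRecord


def _hit(qid, sid, e=1e-20, length=100, pid=100.0, strand=1):
    return SearchHit(
        query_id=qid, subject_id=sid, percent_identity=pid, alignment_length=length,
        mismatches=0, gap_opens=0, query_start=0, query_end=length,
        subject_start=0, subject_end=length, e_value=e, bit_score=50.0,
        query_frame=1, subject_frame=strand,
    )


def test_group_by_anchor_mapping_and_sequence_inputs():
    bms = [
        BestMatch(query_id="q1", hit=_hit("q1", "a")),
        BestMatch(query_id="q2", hit=_hit("q2", "a")),
        BestMatch(query_id="q3", hit=_hit("q3", "b")),
    ]
    expected = {"a": ["q1", "q2"], "b": ["q3"]}
    assert group_by_anchor(bms) == expected
    assert group_by_anchor({bm.query_id: bm for bm in bms}) == expected


def test_insertion_majority_rule():
    rng = np.random.default_rng(0)
    anchor = SequenceRecord(id="anchor", residues=random_dna(rng, 240))
    ins = "GGTTAACCGGTTAACC"
    with_ins = anchor.residues[:120] + ins + anchor.residues[120:]

    def members(n_with, n_without):
        recs, hits = [], {}
        for i in range(n_with):
            recs.append(SequenceRecord(id=f"with{i}", residues=with_ins))
            hits[f"with{i}"] = _hit(f"with{i}", "anchor")
        for i in range(n_without):
            recs.append(SequenceRecord(id=f"plain{i}", residues=anchor.residues))
            hits[f"plain{i}"] = _hit(f"plain{i}", "anchor")
        return recs, hits

    # 2 of 3 covering members carry the identical insertion: retained
    recs, hits = members(2, 1)
    cons = build_consensus(recs, anchor, hits)
    assert ins in cons.residues
    assert cons.anchor_residues == anchor.residues  # columns unaffected
    assert len(cons.residues) == 240 + len(ins)

    # 1 of 3: dropped
    recs, hits = members(1, 2)
    cons = build_consensus(recs, anchor, hits)
    assert ins not in cons.residues
    assert cons.residues == anchor.residues

    # keep_insertions=False drops it even at 2 of 3
    recs, hits = members(2, 1)
    cons = build_consensus(recs, anchor, hits, keep_insertions=False)
    assert cons.residues == anchor.residues


def test_short_segments_cast_no_votes():
    # a member whose placement contains a sub-word ungapped segment: that
    # segment's columns stay uncovered unless min_vote_segment allows them
    rng = np.random.default_rng(2)
    anchor = SequenceRecord(id="anchor", residues=random_dna(rng, 300))
    # the gap boundaries must not slide: the bases flanking the deletion differ
    assert anchor.residues[9] != anchor.residues[15]
    assert anchor.residues[10] != anchor.residues[16]
    # member = 10 anchor bases, a 6-base deletion (cheap enough for the local
    # aligner to keep the prefix), then a long anchor block
    member = SequenceRecord(id="m", residues=anchor.residues[0:10] + anchor.residues[16:300])
    hits = {"m": _hit("m", "anchor")}
    cons = build_consensus([member], anchor, hits)
    assert not any(cons.anchor_covered[0:10])  # 10 < 11: no votes
    assert all(cons.anchor_covered[16:300])
    cons2 = build_consensus([member], anchor, hits, min_vote_segment=1)
    assert all(cons2.anchor_covered[0:10])
    assert not any(cons2.anchor_covered[10:16])  # deleted columns stay uncovered


def test_minus_strand_member_is_oriented_before_voting():
    rng = np.random.default_rng(2)
    anchor = SequenceRecord(id="anchor", residues=random_dna(rng, 200))
    member = SequenceRecord(id="m", residues=rc(anchor.residues[40:160]))
    cons = build_consensus([member], anchor, {"m": _hit("m", "anchor", strand=-1)})
    assert cons.anchor_residues[40:160] == anchor.residues[40:160]
    assert cons.members[0].strand == -1
    assert (cons.members[0].anchor_start, cons.members[0].anchor_end) == (40, 160)


def test_missing_hit_is_an_error():
    anchor = SequenceRecord(id="anchor", residues="ACGT" * 30)
    member = SequenceRecord(id="m", residues="ACGT" * 30)
    with pytest.raises(ValueError, match="no hit"):
        build_consensus([member], anchor, {})


def test_coverage_stats_short_anchor_warning():
    anchor = SequenceRecord(id="tiny", residues="ACG")
    cons = build_consensus(
        [SequenceRecord(id="m", residues="ACG")], anchor,
        {"m": _hit("m", "tiny", length=3)}, min_vote_segment=1,
    )
    with pytest.warns(UserWarning, match="shorter than 4"):
        stats = coverage_stats(cons)
    assert stats.region_lengths == (3, 0, 0)
    assert stats.gap5 == stats.gap_mid == stats.gap3 == 0.0
    assert stats.coverage_fraction == 1.0


def test_consensus_to_record_gap_handling():
    rng = np.random.default_rng(3)
    anchor = SequenceRecord(id="anchor", residues=random_dna(rng, 200))
    # two members leaving the middle uncovered
    m1 = SequenceRecord(id="m1", residues=anchor.residues[:60])
    m2 = SequenceRecord(id="m2", residues=anchor.residues[140:])
    cons = build_consensus(
        [m1, m2], anchor, {"m1": _hit("m1", "anchor"), "m2": _hit("m2", "anchor")}
    )
    assert cons.kind == "one_to_many"
    assert "-" in cons.residues
    as_n = consensus_to_record(cons)
    assert "-" not in as_n.residues and "N" * 80 in as_n.residues
    stripped = consensus_to_record(cons, strip_gaps=True)
    assert stripped.residues == anchor.residues[:60] + anchor.residues[140:]
    assert stripped.id == "anchor"
    assert "one_to_many" in stripped.description
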