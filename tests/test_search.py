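"""Unit tests for the search engine: statistics, coordinates, ranking."""

from __future__ import annotations

import math

import numpy as np
import pytest

from helpers import random_dna, rc
from saurannot.search import (
    SearchParams,
    best_match,
    best_matches_by_query,
    evalue,
    get_profile,
    raw_to_bit_score,
    search,
    search_nucleotide,
    search_translated,
)
from saurannot.seqio import SearchHit, SequenceRecord
from saurannot.synthdata import generate_reference_transcriptome


def test_karlin_altschul_formulas():
    p = SearchParams()  # lambda 0.625, K 0.41 for +2/-3, gap 5+2k
    assert evalue(100.0, 200, 50_000, p) == pytest.approx(
        0.41 * 200 * 50_000 * math.exp(-0.625 * 100.0)
    )
    assert raw_to_bit_score(100.0, p) == pytest.approx(
        (0.625 * 100.0 - math.log(0.41)) / math.log(2.0)
    )
    with pytest.raises(ValueError):
        evalue(10.0, 0, 100, p)


def test_search_params_validation_and_profiles():
    with pytest.raises(ValueError, match="mode"):
        SearchParams(mode="blastz")
    with pytest.raises(KeyError):
        get_profile("no-such-profile")
    assert SearchParams().word_size == 11
    assert SearchParams(mode="translated").word_size == 4
    # profiles are copies: mutating one does not change the registry
    p = get_profile("nucleotide")
    p.e_value_max = 1.0
    assert get_profile("nucleotide").e_value_max == 1e-3
    with pytest.raises(ValueError, match="nucleotide-mode"):
        search_nucleotide([], [], get_profile("translated"))
    with pytest.raises(ValueError, match="translated-mode"):
        search_translated([], [], get_profile("nucleotide"))


def test_planted_match_coordinates_forward_and_reverse():
    rng = np.random.default_rng(4)
    subject = SequenceRecord(id="s", residues=random_dna(rng, 800))
    lo, hi = 250, 400
    piece = subject.residues[lo:hi]
    for strand, qseq in ((1, piece), (-1, rc(piece))):
        (hit,) = search_nucleotide([SequenceRecord(id="q", residues=qseq)], [subject])
        assert hit.percent_identity == 100.0
        assert hit.alignment_length == hi - lo
        assert (hit.subject_start, hit.subject_end) == (lo, hi)
        assert (hit.query_start, hit.query_end) == (0, hi - lo)
        assert hit.subject_frame == strand
        assert hit.mismatches == 0 and hit.gap_opens == 0
        assert hit.e_value == pytest.approx(
            evalue(2.0 * (hi - lo), hi - lo, 800, get_profile("nucleotide"))
        )


def test_windowed_search_on_long_subject():
    # subjects longer than the windowing threshold take the seeded-window path
    rng = np.random.default_rng(5)
    backbone = random_dna(rng, 12_000)
    lo = 7_321
    query = backbone[lo:lo + 120]
    subject = SequenceRecord(id="g", residues=backbone)
    (hit,) = search_nucleotide([SequenceRecord(id="q", residues=query)], [subject])
    assert (hit.subject_start, hit.subject_end) == (lo, lo + 120)
    assert hit.percent_identity == 100.0


def test_translated_self_match_reports_frame_and_nt_coordinates():
    (gene,) = generate_reference_transcriptome(1, seed=3)
    (hit,) = search_translated([gene], [gene])
    assert (hit.query_frame, hit.subject_frame) == (1, 1)
    assert hit.percent_identity == 100.0
    assert hit.alignment_length == len(gene) // 3  # amino acids
    assert (hit.query_start, hit.query_end) == (0, len(gene))
    assert (hit.subject_start, hit.subject_end) == (0, len(gene))


def test_thresholds_filter_hits():
    rng = np.random.default_rng(6)
    subject = SequenceRecord(id="s", residues=random_dna(rng, 500))
    query = SequenceRecord(id="q", residues=subject.residues[100:200])
    assert search_nucleotide([query], [subject], SearchParams(min_alignment_length=101)) == []
    assert search_nucleotide([query], [subject], SearchParams(e_value_max=1e-300)) == []
    # a mismatch every 15 positions (identical runs of 14 still seed at word 11)
    diverged = list(subject.residues[100:300])
    for i in range(0, 200, 15):
        diverged[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[diverged[i]]
    q2 = SequenceRecord(id="q2", residues="".join(diverged))
    assert search_nucleotide([q2], [subject], SearchParams(min_percent_identity=96.0)) == []
    assert len(search_nucleotide([q2], [subject], SearchParams(min_percent_identity=85.0))) == 1


def test_best_match_ordered_criteria():
    base = dict(percent_identity=90.0, alignment_length=100, mismatches=0, gap_opens=0,
                query_start=0, query_end=100, subject_start=0, subject_end=100,
                e_value=1e-10, bit_score=50.0)
    hits = [
        SearchHit(query_id="q", subject_id="s1", **base),
        SearchHit(query_id="q", subject_id="s2", **{**base, "e_value": 1e-20}),
        SearchHit(query_id="q", subject_id="s3", **{**base, "e_value": 1e-20,
                                                    "alignment_length": 150}),
        SearchHit(query_id="q", subject_id="s4", **{**base, "e_value": 1e-20,
                                                    "alignment_length": 150,
                                                    "percent_identity": 95.0}),
        SearchHit(query_id="q", subject_id="s0", **{**base, "e_value": 1e-20,
                                                    "alignment_length": 150,
                                                    "percent_identity": 95.0}),
    ]
    bm = best_match(hits)
    assert bm.subject_id == "s0"  # full tie resolved by ascending subject id
    assert bm.criteria == (1e-20, 150, 95.0)
    assert best_match([]) is None
    with pytest.raises(ValueError, match="multiple queries"):
        best_match([hits[0], SearchHit(query_id="other", subject_id="s", **base)])
    grouped = best_matches_by_query(hits)
    assert set(grouped) == {"q"} and grouped["q"].subject_id == "s0"


def test_search_dispatcher():
    rng = np.random.default_rng(7)
    s = SequenceRecord(id="s", residues=random_dna(rng, 400))
    q = SequenceRecord(id="q", residues=s.residues[50:250])
    nt = search([q], [s], get_profile("nucleotide"))
    tr = search([q], [s], get_profile("translated"))
    assert nt and nt[0].subject_frame == 1
    assert tr and abs(tr[0].subject_frame) in (1, 2, 3)
    assert search([q], [], get_profile("nucleotide")) == []
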