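"""Unit tests for sequence I/O, adaptor trimming, translation, tabular hits."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from helpers import random_dna, rc
from saurannot.seqio import (
    SearchHit,
    SequenceRecord,
    read_fasta,
    read_hits_tabular,
    reverse_complement,
    six_frame_translate,
    trim_adaptors,
    write_fasta,
    write_hits_tabular,
)


def test_sequence_record_validation():
    with pytest.raises(ValueError):
        SequenceRecord(id="", residues="ACGT")
    with pytest.raises(ValueError):
        SequenceRecord(id="x", residues="")
    assert len(SequenceRecord(id="x", residues="ACGT")) == 4


def test_reverse_complement_matches_biopython():
    rng = np.random.default_rng(0)
    for _ in range(20):
        s = random_dna(rng, int(rng.integers(1, 200)))
        assert reverse_complement(s) == str(Seq(s).reverse_complement())
    assert reverse_complement("ACGTN") == "NACGT"


def test_fasta_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    records = [
        SequenceRecord(id=f"s{i}", residues=random_dna(rng, int(rng.integers(10, 300))),
                       description=f"desc {i}")
        for i in range(5)
    ]
    path = tmp_path / "x.fasta"
    write_fasta(records, path)
    assert read_fasta(path) == records


def test_fasta_uppercases_and_maps_u_to_t(tmp_path):
    path = tmp_path / "x.fasta"
    path.write_text(">r1 a record\nacgu\nACGU\n")
    (rec,) = read_fasta(path)
    assert rec.residues == "ACGTACGT"
    assert rec.description == "a record"


def test_fasta_errors(tmp_path):
    bad = tmp_path / "bad.fasta"
    bad.write_text("ACGT\n>r1\nACGT\n")
    with pytest.raises(ValueError, match="line 1"):
        read_fasta(bad)
    dup = tmp_path / "dup.fasta"
    dup.write_text(">r1\nACGT\n>r1\nTTTT\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_fasta(dup)
    empty = tmp_path / "empty.fasta"
    empty.write_text("")
    assert read_fasta(empty) == []


def test_trim_adaptors_terminal_internal_and_reverse():
    rng = np.random.default_rng(2)
    adaptor = "ACCGGTTACCGGTT"
    left = random_dna(rng, 120)
    right = random_dna(rng, 150)

    # terminal occurrence shortens, id kept
    rec = SequenceRecord(id="t", residues=adaptor + left)
    (out,) = trim_adaptors(rec, [adaptor], min_retained_len=91)
    assert (out.id, out.residues) == ("t", left)

    # internal occurrence splits with _1/_2 names; reverse-complement matches too
    for planted in (adaptor, rc(adaptor)):
        rec = SequenceRecord(id="t", residues=left + planted + right)
        a, b = trim_adaptors(rec, [adaptor], min_retained_len=91)
        assert (a.id, a.residues) == ("t_1", left)
        assert (b.id, b.residues) == ("t_2", right)

    # fragments below the retention length are dropped; empty result is legal
    rec = SequenceRecord(id="t", residues=random_dna(rng, 50) + adaptor + random_dna(rng, 60))
    assert trim_adaptors(rec, [adaptor], min_retained_len=91) == []

    # no occurrence: the record itself
    rec = SequenceRecord(id="t", residues=left)
    assert trim_adaptors(rec, [adaptor]) == [rec]

    with pytest.raises(ValueError, match="shorter than 8"):
        trim_adaptors(rec, ["ACGT"])


def test_six_frame_translate_against_biopython():
    rng = np.random.default_rng(3)
    for _ in range(10):
        nt = random_dna(rng, int(rng.integers(3, 100)))
        frames = six_frame_translate(nt)
        rcs = rc(nt)
        for f in (1, 2, 3):
            for seq, key in ((nt, f), (rcs, -f)):
                s = seq[f - 1:]
                s = s[: len(s) - len(s) % 3]
                expected = str(Seq(s).translate(table=1, stop_symbol="*")) if s else ""
                assert frames[key] == expected
    # stop codons do not truncate; N codons give X; short input gives empties
    assert six_frame_translate("ATGTAAATG")[1] == "M*M"
    assert six_frame_translate("ATGNNNATG")[1] == "MXM"
    assert all(v == "" for v in six_frame_translate("AC").values())


def test_hits_tabular_round_trip(tmp_path):
    hits = [
        SearchHit(query_id="q1", subject_id="s1", percent_identity=98.7654321,
                  alignment_length=123, mismatches=2, gap_opens=1,
                  query_start=4, query_end=127, subject_start=10, subject_end=133,
                  e_value=3.21e-42, bit_score=217.123456789,
                  query_frame=1, subject_frame=1),
        SearchHit(query_id="q1", subject_id="s2", percent_identity=91.0,
                  alignment_length=60, mismatches=5, gap_opens=0,
                  query_start=0, query_end=60, subject_start=200, subject_end=260,
                  e_value=1e-9, bit_score=88.8, query_frame=2, subject_frame=-3),
    ]
    path = tmp_path / "hits.tsv"
    write_hits_tabular(hits, path)
    assert read_hits_tabular(path) == hits  # score is excluded from equality


def test_hits_tabular_twelve_column_strand_inference(tmp_path):
    path = tmp_path / "ext.tsv"
    path.write_text(
        "# comment line\n"
        "q\ts\t95.5\t100\t4\t1\t1\t100\t250\t151\t1e-20\t180.0\n"
    )
    (h,) = read_hits_tabular(path)
    assert (h.subject_start, h.subject_end, h.subject_frame) == (150, 250, -1)
    assert (h.query_start, h.query_end, h.query_frame) == (0, 100, 1)

    bad = tmp_path / "bad.tsv"
    bad.write_text("q\ts\t95.5\n")
    with pytest.raises(ValueError, match="line 1"):
        read_hits_tabular(bad)


def test_search_hit_rank_key_order():
    base = dict(percent_identity=90.0, alignment_length=100, mismatches=0, gap_opens=0,
                query_start=0, query_end=100, subject_start=0, subject_end=100,
                e_value=1e-10, bit_score=50.0)
    a = SearchHit(query_id="q", subject_id="s1", **base)
    better_e = SearchHit(query_id="q", subject_id="s2", **{**base, "e_value": 1e-20})
    longer = SearchHit(query_id="q", subject_id="s3", **{**base, "alignment_length": 150})
    higher_pid = SearchHit(query_id="q", subject_id="s4", **{**base, "percent_identity": 99.0})
    assert better_e.rank_key() < a.rank_key()
    assert longer.rank_key() < a.rank_key()
    assert higher_pid.rank_key() < a.rank_key()
    assert a.rank_key() < SearchHit(query_id="q", subject_id="s9", **base).rank_key()
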