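"""Unit tests for the iterative annotation driver and cross-dataset logic."""

from __future__ import annotations

import numpy as np
import pytest

from helpers import random_dna
from saurannot.homology import (
    AnnotatedDataset,
    AnnotationRecord,
    ReferenceDatabase,
    annotate_iterative,
    cross_dataset_compare,
    partition_datasets,
)
from saurannot.seqio import SearchHit, SequenceRecord
from saurannot.synthdata import generate_reference_transcriptome, mutate_and_fragment


def test_reference_database_validation():
    rec = SequenceRecord(id="r", residues="ACGT" * 30)
    with pytest.raises(ValueError, match="db_kind"):
        ReferenceDatabase(label="x", db_kind="swissprot", records=[rec])
    with pytest.raises(ValueError, match="no records"):
        ReferenceDatabase(label="x", db_kind="cDNA", records=[])
    assert ReferenceDatabase(label="x", db_kind="mtDNA", records=[rec]).params.mode == "nucleotide"
    assert ReferenceDatabase(label="x", db_kind="cDNA", records=[rec]).params.mode == "translated"
    from saurannot.search import get_profile
    with pytest.raises(ValueError, match="translated expected"):
        ReferenceDatabase(label="x", db_kind="cDNA", records=[rec],
                          params=get_profile("nucleotide"))


def test_annotation_record_validation():
    with pytest.raises(ValueError, match="category"):
        AnnotationRecord(query_id="q", category="banana")
    with pytest.raises(ValueError, match="orphan"):
        AnnotationRecord(query_id="q", category="orphan", subject_id="s")
    with pytest.raises(ValueError, match="rbbh"):
        AnnotationRecord(query_id="q", category="cdna_hit", subject_id="s", rbbh=True)


def test_stage_order_earlier_stage_wins():
    # a query matching the mtDNA stage never reaches the cDNA stage, even
    # though the same sequence is present there too
    rng = np.random.default_rng(0)
    mt = SequenceRecord(id="mt_genome", residues=random_dna(rng, 2_000))
    genes = generate_reference_transcriptome(3, seed=1)
    q_mt = SequenceRecord(id="q_mt", residues=mt.residues[300:600])
    q_cdna = SequenceRecord(id="q_cdna", residues=genes[0].residues[:300])
    q_orphan = SequenceRecord(id="q_orphan", residues=random_dna(rng, 300))
    stages = [
        ReferenceDatabase(label="mito", db_kind="mtDNA", records=[mt]),
        ReferenceDatabase(label="spA", db_kind="cDNA",
                          records=genes + [SequenceRecord(id="mt_copy", residues=mt.residues)]),
    ]
    records = annotate_iterative([q_mt, q_cdna, q_orphan], stages)
    by_id = {r.query_id: r for r in records}
    assert by_id["q_mt"].category == "mtDNA" and by_id["q_mt"].stage_index == 0
    assert by_id["q_cdna"].category in ("cdna_rbbh", "cdna_hit")
    assert by_id["q_cdna"].subject_id == genes[0].id
    assert by_id["q_orphan"].category == "orphan"
    assert [r.query_id for r in records] == ["q_mt", "q_cdna", "q_orphan"]
    with pytest.raises(ValueError, match="at least one stage"):
        annotate_iterative([q_mt], [])


def test_rbbh_block_keeps_non_reciprocal_hits_pending():
    # two fragments of the same gene: only one can be the gene's reciprocal
    # best; the other must be finalized as a plain hit when the block ends
    genes = generate_reference_transcriptome(4, seed=2)
    g = genes[0]
    strong = SequenceRecord(id="strong", residues=g.residues)
    weak = SequenceRecord(id="weak", residues=g.residues[: len(g) // 2])
    stages = [ReferenceDatabase(label="spA", db_kind="cDNA", records=genes)]
    by_id = {r.query_id: r for r in annotate_iterative([strong, weak], stages)}
    assert by_id["strong"].category == "cdna_rbbh" and by_id["strong"].rbbh
    assert by_id["weak"].category == "cdna_hit" and not by_id["weak"].rbbh
    assert by_id["weak"].subject_id == g.id


def test_masking_hook_labels_repeats():
    rng = np.random.default_rng(3)
    genes = generate_reference_transcriptome(2, seed=4)
    q1 = SequenceRecord(id="rep", residues="ACGGT" * 60)
    q2 = SequenceRecord(id="plain", residues=random_dna(rng, 300))

    def hook(records):
        return {r.id: (0.9 if r.id == "rep" else 0.1) for r in records}

    stages = [ReferenceDatabase(label="spA", db_kind="cDNA", records=genes)]
    by_id = {r.query_id: r for r in annotate_iterative([q1, q2], stages, masking_hook=hook)}
    assert by_id["rep"].category == "repeat"
    assert by_id["plain"].category == "orphan"


def test_partition_law():
    records = [
        AnnotationRecord(query_id="a", category="cdna_rbbh", subject_id="s", rbbh=True),
        AnnotationRecord(query_id="b", category="unigene_hit", subject_id="s"),
        AnnotationRecord(query_id="c", category="taxon_mrna", subject_id="s"),
        AnnotationRecord(query_id="d", category="mtDNA", subject_id="s"),
        AnnotationRecord(query_id="e", category="orphan"),
        AnnotationRecord(query_id="f", category="cross_species", subject_id="s"),
    ]
    annotation, phylogeny = partition_datasets(records)
    assert annotation == ["a", "b", "c"]
    assert phylogeny == ["a"]


def test_cross_dataset_compare_symmetric():
    # one shared lineage-specific sequence between two species' orphans
    genes = generate_reference_transcriptome(8, seed=5)
    shared = genes[-1].residues  # an ORF absent from both reference stages

    def dataset(name, orphan_seq, seed):
        frags, _ = mutate_and_fragment(genes[:3], divergence=0.02,
                                       n_fragments_per_gene=1, orphan_rate=0.0, seed=seed)
        frags = [SequenceRecord(id=f"{name}_{r.id}", residues=r.residues) for r in frags]
        frags.append(SequenceRecord(id=f"{name}_orphan", residues=orphan_seq))
        stages = [ReferenceDatabase(label="ref", db_kind="cDNA", records=genes[:3])]
        records = annotate_iterative(frags, stages)
        return AnnotatedDataset(name=name, records=records,
                                sequences={r.id: r for r in frags})

    a = dataset("A", shared, seed=0)
    b = dataset("B", shared, seed=1)
    assert {r.query_id for r in a.orphan_records()} == {"A_orphan"}
    hits = cross_dataset_compare([a, b])
    assert hits
    rec_a = {r.query_id: r for r in a.records}["A_orphan"]
    rec_b = {r.query_id: r for r in b.records}["B_orphan"]
    assert rec_a.category == rec_b.category == "cross_species"
    assert rec_a.reference_label == "B" and rec_b.reference_label == "A"
    assert rec_a.subject_id == "B_orphan" and rec_b.subject_id == "A_orphan"
    # fewer than two datasets: identity
    assert cross_dataset_compare([a]) == []


def test_find_rbbh_empty_inputs():
    from saurannot.homology import find_rbbh
    assert find_rbbh([], []) == []
    h = SearchHit(query_id="q", subject_id="s", percent_identity=100.0, alignment_length=50,
                  mismatches=0, gap_opens=0, query_start=0, query_end=50,
                  subject_start=0, subject_end=50, e_value=1e-20, bit_score=90.0)
    assert find_rbbh([h], []) == []
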