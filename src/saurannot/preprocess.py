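"""Preprocessing filters applied before annotation.

Two steps: removal of sequences of <= 90 nucleotides, and greedy
redundancy clustering of >= 95% identical sequences keeping the longest
representative of each cluster (CD-HIT-EST-style semantics: identity is
matching columns over the length of the shorter sequence, both strands
compared, greedy first-fit assignment in decreasing length order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from saurannot.seqio import SequenceRecord, reverse_complement

__all__ = ["ClusterMap", "filter_short", "cluster_redundant", "pairwise_identity"]


@dataclass
class ClusterMap:
    """representative id -> member ids (the representative is included).

    Every clustered input id appears in exactly one cluster, and each
    representative is a longest member of its cluster.
    """

    clusters: dict[str, list[str]] = field(default_factory=dict)

    def representative_of(self, member_id: str) -> str:
        for rep, members in self.clusters.items():
            if member_id in members:
                return rep
        raise KeyError(member_id)

    def __len__(self) -> int:
        return len(self.clusters)


def filter_short(
    records: Sequence[SequenceRecord], max_excluded_len: int = 90
) -> list[SequenceRecord]:
    """Keep exactly the records longer than ``max_excluded_len`` nucleotides.

    The default removes sequences of <= 90 nt; input order is preserved.
    """
    return [r for r in records if len(r) > max_excluded_len]


def _overlap_aligner() -> Align.PairwiseAligner:
    # Semi-global (overlap) alignment: end gaps free on both sequences so
    # a shorter sequence may sit anywhere inside a longer one.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    m = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            m[a, b] = 1.0 if (a == b and a != "N") else -1.0
    aligner.substitution_matrix = m
    aligner.open_internal_gap_score = -4
    aligner.extend_internal_gap_score = -1
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


_ALIGNER = _overlap_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Identity of two sequences, best strand, over the shorter sequence.

    Matching columns of a semi-global alignment (no end-gap penalties)
    divided by the length of the shorter sequence — the convention of
    greedy incremental nucleotide clustering tools.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 0.0
    for s in (short, reverse_complement(short)):
        aln = _ALIGNER.align(long_, s)[0]
        ident = aln.counts().identities
        best = max(best, ident / len(short))
    return best


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _shared_word_count(words_short: Sequence[str], rep_words: set[str]) -> int:
    return sum(1 for w in words_short if w in rep_words)


def cluster_redundant(
    records: Sequence[SequenceRecord],
    identity_threshold: float = 0.95,
    word_size: int = 10,
) -> tuple[list[SequenceRecord], ClusterMap]:
    """Greedy incremental redundancy clustering, longest representative kept.

    Records are visited in decreasing length (ties by input order); each
    joins the first existing cluster whose representative it matches at
    >= ``identity_threshold``, else founds its own cluster.  Returns the
    retained representatives (in visit order) and the cluster map.

    A word-count prefilter skips alignments that provably cannot reach the
    threshold: an alignment with identity >= t over a shorter sequence of
    length Ls has at most floor((1-t)*Ls) non-identity columns, each of
    which destroys at most ``word_size`` of the shorter sequence's
    (Ls - word_size + 1) k-mer windows, so at least
    (Ls - k + 1) - k*floor((1-t)*Ls) windows must be present verbatim in
    the representative.
    """
    order = sorted(range(len(records)), key=lambda i: (-len(records[i]), i))
    reps: list[SequenceRecord] = []
    rep_words: list[set[str]] = []
    cmap = ClusterMap()
    k = word_size
    for idx in order:
        rec = records[idx]
        ls = len(rec)
        slack = int((1.0 - identity_threshold) * ls)
        min_shared = max(1, (ls - k + 1) - k * slack)
        rc = reverse_complement(rec.residues)
        words = [rec.residues[i:i + k] for i in range(ls - k + 1)]
        words_rc = [rc[i:i + k] for i in range(ls - k + 1)]
        assigned = False
        for rep, fwd in zip(reps, rep_words):
            if (
                _shared_word_count(words, fwd) < min_shared
                and _shared_word_count(words_rc, fwd) < min_shared
            ):
                continue
            if pairwise_identity(rec.residues, rep.residues) >= identity_threshold:
                cmap.clusters[rep.id].append(rec.id)
                assigned = True
                break
        if not assigned:
            reps.append(rec)
            rep_words.append(_kmer_set(rec.residues, k))
            cmap.clusters[rec.id] = [rec.id]
    return reps, cmap
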