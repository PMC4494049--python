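"""Built-in homology search engine and best-match ranking.

A seeded local aligner stands in for an external BLASTn/tBLASTx engine:
exact-word seeding locates candidate subject regions, Smith–Waterman
(affine gaps, via Biopython's PairwiseAligner) scores them, and
Karlin–Altschul statistics convert raw scores to e-values
(``E = K * m * n * exp(-lambda * S)``, raw sequence lengths, no edge
correction).  Nucleotide mode compares both strands; translated mode
compares all 36 frame pairs at the protein level and reports coordinates
on the nucleotide sequences.

One best HSP is retained per query–subject pair; downstream ranking and
RBBH logic only consume the best HSP.  Results from any external engine
can be substituted through the tabular adapter
(:func:`saurannot.seqio.read_hits_tabular` / :func:`external_search`):
downstream modules consume :class:`~saurannot.seqio.SearchHit` regardless
of its origin.
"""

from __future__ import annotations

import math
import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from saurannot.seqio import (
    SearchHit,
    SequenceRecord,
    read_fasta,
    read_hits_tabular,
    reverse_complement,
    six_frame_translate,
    write_fasta,
)

__all__ = [
    "SearchParams",
    "BestMatch",
    "PROFILES",
    "get_profile",
    "evalue",
    "raw_to_bit_score",
    "search_nucleotide",
    "search_translated",
    "best_match",
    "best_matches_by_query",
    "external_search",
]

# Karlin–Altschul (lambda, K) pairs for the two scoring schemes shipped by
# default.  Values are the standard gapped estimates for +2/-3 with gap
# 5+2k and for BLOSUM62 with gap 11+k; they are recorded in run manifests
# for reproducibility.
_KARLIN_NUCLEOTIDE = {(2, -3, 5, 2): (0.625, 0.41)}
_KARLIN_PROTEIN = {("BLOSUM62", 11, 1): (0.267, 0.041)}


@dataclass
class SearchParams:
    """Scoring scheme, statistics, and reporting thresholds for one search.

    ``mode`` selects nucleotide (strand-aware, +2/-3 default scoring) or
    translated (six-frame protein comparison, BLOSUM62 default).  Gap
    penalties follow the BLAST convention: a gap of length g costs
    ``gap_open + g * gap_extend``.  ``min_alignment_length`` counts
    alignment columns in the mode's unit (nt or aa).  A ``None`` threshold
    is inactive.
    """

    mode: str = "nucleotide"  # "nucleotide" | "translated"
    e_value_max: float = 1e-3
    min_percent_identity: float | None = None
    min_alignment_length: int | None = 50
    match_score: int = 2
    mismatch_score: int = -3
    matrix_name: str = "BLOSUM62"
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int | None = None
    karlin_lambda: float | None = None
    karlin_k: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("nucleotide", "translated"):
            raise ValueError(f"unknown search mode {self.mode!r}")
        if self.e_value_max < 0:
            raise ValueError("e_value_max must be non-negative")
        if self.word_size is None:
            self.word_size = 11 if self.mode == "nucleotide" else 4
        if self.karlin_lambda is None or self.karlin_k is None:
            if self.mode == "nucleotide":
                key = (self.match_score, self.mismatch_score, self.gap_open, self.gap_extend)
                lam, k = _KARLIN_NUCLEOTIDE.get(key, (0.625, 0.41))
            else:
                key = (self.matrix_name, self.gap_open, self.gap_extend)
                lam, k = _KARLIN_PROTEIN.get(key, (0.267, 0.041))
            if self.karlin_lambda is None:
                self.karlin_lambda = lam
            if self.karlin_k is None:
                self.karlin_k = k
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin parameters must be positive")


def _translated_defaults(**kw) -> SearchParams:
    kw.setdefault("mode", "translated")
    kw.setdefault("gap_open", 11)
    kw.setdefault("gap_extend", 1)
    kw.setdefault("min_alignment_length", None)
    return SearchParams(**kw)


#: Named parameter profiles.  "nucleotide"/"translated" are the pipeline
#: defaults; "genome-validation" is the stringent profile (min %ID 90,
#: e-value 1e-5) used to validate genome annotations against an existing
#: gene set; "projection-reassembly" disables the minimum match length so
#: that even the shortest potential exons can align to cDNAs;
#: "completeness" is the stringent nucleotide profile for reference-set
#: comparisons.
PROFILES: Mapping[str, SearchParams] = {
    "nucleotide": SearchParams(),
    "translated": _translated_defaults(),
    "genome-validation": SearchParams(
        e_value_max=1e-5, min_percent_identity=90.0, min_alignment_length=50
    ),
    "projection-reassembly": SearchParams(min_alignment_length=None),
    "completeness": SearchParams(e_value_max=1e-5, min_alignment_length=None),
}


def get_profile(name: str) -> SearchParams:
    try:
        return replace(PROFILES[name])
    except KeyError:
        raise KeyError(
            f"unknown search profile {name!r}; available: {sorted(PROFILES)}"
        ) from None


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def evalue(score: float, query_len: int, db_len: int, params: SearchParams) -> float:
    """Karlin–Altschul expected number of hits: ``K * m * n * exp(-lambda*S)``."""
    if query_len < 1 or db_len < 1:
        raise ValueError("sequence lengths must be >= 1")
    return params.karlin_k * query_len * db_len * math.exp(-params.karlin_lambda * score)


def raw_to_bit_score(score: float, params: SearchParams) -> float:
    return (params.karlin_lambda * score - math.log(params.karlin_k)) / math.log(2.0)


# ---------------------------------------------------------------------------
# Aligner construction
# ---------------------------------------------------------------------------

def _nucleotide_matrix(params: SearchParams):
    m = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            # N scores as a mismatch against everything, including N
            m[a, b] = params.match_score if (a == b and a != "N") else params.mismatch_score
    return m


def make_aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if params.mode == "nucleotide":
        aligner.substitution_matrix = _nucleotide_matrix(params)
    else:
        aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    # BLAST convention: gap of length g costs open + g*extend
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


# ---------------------------------------------------------------------------
# Seeding and windowing
# ---------------------------------------------------------------------------

def _word_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    return index


def _seeds(query: str, subject_index: Mapping[str, list[int]], k: int) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    seen: set[str] = set()
    for i in range(len(query) - k + 1):
        w = query[i:i + k]
        if w in seen:
            continue
        seen.add(w)
        for j in subject_index.get(w, ()):
            out.append((i, j))
    return out


def _windows(
    seeds: Sequence[tuple[int, int]], qlen: int, slen: int, band: int = 64
) -> list[tuple[int, int]]:
    """Subject windows to align, from diagonal-clustered seeds.

    Small subjects are aligned whole; for long subjects (genomes) seeds are
    grouped by diagonal and each group yields a window of about one query
    length of context on either side.  Overlapping windows are merged.
    """
    if slen <= max(2000, 4 * qlen):
        return [(0, slen)]
    by_diag = sorted(seeds, key=lambda t: (t[1] - t[0], t[1]))
    windows: list[tuple[int, int]] = []
    group: list[tuple[int, int]] = []

    def flush() -> None:
        if not group:
            return
        lo = max(0, min(j for _, j in group) - qlen - 32)
        hi = min(slen, max(j for _, j in group) + qlen + 32)
        windows.append((lo, hi))
        group.clear()

    prev_diag = None
    for i, j in by_diag:
        d = j - i
        if prev_diag is not None and d - prev_diag > band:
            flush()
        group.append((i, j))
        prev_diag = d
    flush()
    windows.sort()
    merged: list[tuple[int, int]] = []
    for lo, hi in windows:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


# ---------------------------------------------------------------------------
# Hit construction
# ---------------------------------------------------------------------------

def _alignment_stats(alignment) -> tuple[int, int, int, int, int, int, int, int]:
    """(identities, mismatches, gap_opens, length, qs, qe, ss, se) of a local alignment."""
    c = alignment.counts()
    gap_opens = (
        c.open_internal_insertions
        + c.open_internal_deletions
        + c.open_left_insertions
        + c.open_left_deletions
        + c.open_right_insertions
        + c.open_right_deletions
    )
    coords = alignment.coordinates
    qs, qe = int(coords[0][0]), int(coords[0][-1])
    ss, se = int(coords[1][0]), int(coords[1][-1])
    return c.identities, c.mismatches, gap_opens, alignment.length, qs, qe, ss, se


def _passes(hit: SearchHit, params: SearchParams) -> bool:
    if hit.e_value > params.e_value_max:
        return False
    if params.min_percent_identity is not None and hit.percent_identity < params.min_percent_identity:
        return False
    if params.min_alignment_length is not None and hit.alignment_length < params.min_alignment_length:
        return False
    return True


def _sort_grouped(hits: list[SearchHit], query_order: Sequence[str]) -> list[SearchHit]:
    order = {qid: i for i, qid in enumerate(query_order)}
    return sorted(hits, key=lambda h: (order[h.query_id], h.rank_key()))


def search_nucleotide(
    queries: Sequence[SequenceRecord],
    database: Sequence[SequenceRecord],
    params: SearchParams | None = None,
) -> list[SearchHit]:
    """Strand-aware seeded nucleotide search of ``queries`` against ``database``.

    Hits are normalized so query coordinates ascend on the query's forward
    strand; a reverse-strand match carries ``subject_frame = -1`` with
    subject coordinates on the subject's forward strand.  Hits failing any
    active threshold are discarded; output is grouped per query (input
    order) and sorted by the ordered criteria.
    """
    params = params or get_profile("nucleotide")
    if params.mode != "nucleotide":
        raise ValueError("search_nucleotide requires nucleotide-mode params")
    aligner = make_aligner(params)
    k = params.word_size
    db_len = sum(len(s) for s in database)
    if db_len == 0:
        return []
    subject_indexes = [(s, _word_index(s.residues, k)) for s in database]
    hits: list[SearchHit] = []
    for q in queries:
        qf = q.residues
        qr = reverse_complement(qf)
        for subject, sindex in subject_indexes:
            best: tuple[float, int, tuple[int, int]] | None = None  # (score, strand, window)
            for strand, qseq in ((1, qf), (-1, qr)):
                seeds = _seeds(qseq, sindex, k)
                if not seeds:
                    continue
                for lo, hi in _windows(seeds, len(qseq), len(subject)):
                    s = aligner.score(qseq, subject.residues[lo:hi])
                    if best is None or s > best[0]:
                        best = (s, strand, (lo, hi))
            if best is None:
                continue
            score, strand, (lo, hi) = best
            e = evalue(score, len(q), db_len, params)
            if e > params.e_value_max:
                continue
            qseq = qf if strand == 1 else qr
            aln = aligner.align(qseq, subject.residues[lo:hi])[0]
            ident, mism, gaps_open, length, qs, qe, ss, se = _alignment_stats(aln)
            if strand == -1:
                qs, qe = len(q) - qe, len(q) - qs
            hit = SearchHit(
                query_id=q.id,
                subject_id=subject.id,
                percent_identity=100.0 * ident / length if length else 0.0,
                alignment_length=length,
                mismatches=mism,
                gap_opens=gaps_open,
                query_start=qs,
                query_end=qe,
                subject_start=lo + ss,
                subject_end=lo + se,
                e_value=e,
                bit_score=raw_to_bit_score(score, params),
                query_frame=1,
                subject_frame=strand,
                score=score,
            )
            if _passes(hit, params):
                hits.append(hit)
    return _sort_grouped(hits, [q.id for q in queries])


def _prot_to_nt(frame: int, p_start: int, p_end: int, nt_len: int) -> tuple[int, int]:
    """Map a protein interval in a translation frame to forward-strand nt coordinates."""
    off = abs(frame) - 1
    if frame > 0:
        return off + 3 * p_start, off + 3 * p_end
    return nt_len - (off + 3 * p_end), nt_len - (off + 3 * p_start)


def search_translated(
    queries: Sequence[SequenceRecord],
    database: Sequence[SequenceRecord],
    params: SearchParams | None = None,
) -> list[SearchHit]:
    """Six-frame translated search: all 36 frame pairs scored at the protein level.

    Percent identity and alignment length are in amino acids; hit
    coordinates are reported on the forward strands of the nucleotide
    sequences, with the matching frames recorded.
    """
    params = params or get_profile("translated")
    if params.mode != "translated":
        raise ValueError("search_translated requires translated-mode params")
    aligner = make_aligner(params)
    k = params.word_size
    db_len = sum(len(s) for s in database)
    if db_len == 0:
        return []
    subject_frames = []
    for s in database:
        frames = six_frame_translate(s.residues)
        indexes = {f: _word_index(p, k) for f, p in frames.items() if len(p) >= k}
        subject_frames.append((s, frames, indexes))
    hits: list[SearchHit] = []
    for q in queries:
        q_frames = six_frame_translate(q.residues)
        q_words = {
            f: {p[i:i + k] for i in range(len(p) - k + 1)}
            for f, p in q_frames.items()
            if len(p) >= k
        }
        for subject, s_frames, s_indexes in subject_frames:
            best: tuple[float, int, int] | None = None  # (score, qframe, sframe)
            for fq, words in q_words.items():
                for fs, sindex in s_indexes.items():
                    if words.isdisjoint(sindex.keys()):
                        continue
                    s = aligner.score(q_frames[fq], s_frames[fs])
                    if best is None or s > best[0]:
                        best = (s, fq, fs)
            if best is None:
                continue
            score, fq, fs = best
            e = evalue(score, len(q), db_len, params)
            if e > params.e_value_max:
                continue
            aln = aligner.align(q_frames[fq], s_frames[fs])[0]
            ident, mism, gaps_open, length, ps_q, pe_q, ps_s, pe_s = _alignment_stats(aln)
            q_nt = _prot_to_nt(fq, ps_q, pe_q, len(q))
            s_nt = _prot_to_nt(fs, ps_s, pe_s, len(subject))
            hit = SearchHit(
                query_id=q.id,
                subject_id=subject.id,
                percent_identity=100.0 * ident / length if length else 0.0,
                alignment_length=length,
                mismatches=mism,
                gap_opens=gaps_open,
                query_start=q_nt[0],
                query_end=q_nt[1],
                subject_start=s_nt[0],
                subject_end=s_nt[1],
                e_value=e,
                bit_score=raw_to_bit_score(score, params),
                query_frame=fq,
                subject_frame=fs,
                score=score,
            )
            if _passes(hit, params):
                hits.append(hit)
    return _sort_grouped(hits, [q.id for q in queries])


def search(
    queries: Sequence[SequenceRecord],
    database: Sequence[SequenceRecord],
    params: SearchParams,
) -> list[SearchHit]:
    """Dispatch on ``params.mode``."""
    if params.mode == "nucleotide":
        return search_nucleotide(queries, database, params)
    return search_translated(queries, database, params)


# ---------------------------------------------------------------------------
# Best-match ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BestMatch:
    """The winning hit of one query under the ordered criteria.

    Ranking is lexicographic: smallest e-value, then largest match length,
    then largest percent identity; residual ties are broken by ascending
    subject id.
    """

    query_id: str
    hit: SearchHit
    criteria: tuple[float, int, float] = field(default=(0.0, 0, 0.0))

    @property
    def subject_id(self) -> str:
        return self.hit.subject_id


def best_match(hits_for_one_query: Sequence[SearchHit]) -> BestMatch | None:
    """Pick the best hit of a single query; ``None`` for an empty list."""
    if not hits_for_one_query:
        return None
    qids = {h.query_id for h in hits_for_one_query}
    if len(qids) > 1:
        raise ValueError(f"best_match received hits from multiple queries: {sorted(qids)}")
    chosen = min(hits_for_one_query, key=SearchHit.rank_key)
    return BestMatch(
        query_id=chosen.query_id,
        hit=chosen,
        criteria=(chosen.e_value, chosen.alignment_length, chosen.percent_identity),
    )


def best_matches_by_query(hits: Iterable[SearchHit]) -> dict[str, BestMatch]:
    grouped: dict[str, list[SearchHit]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    return {qid: best_match(hs) for qid, hs in grouped.items()}


# ---------------------------------------------------------------------------
# External engine adapter
# ---------------------------------------------------------------------------

def external_search(
    queries: Sequence[SequenceRecord],
    database: Sequence[SequenceRecord],
    command_template: str,
    workdir: str | Path | None = None,
) -> list[SearchHit]:
    """Run an external search engine declared as a command template.

    The template receives ``{query}``, ``{db}`` and ``{out}`` placeholders
    (FASTA query path, FASTA database path, tabular output path) and must
    produce a 12-column tabular file, which is parsed into
    :class:`SearchHit` objects identical in shape to built-in hits.
    """
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmp = Path(tmp)
        qpath, dpath, opath = tmp / "queries.fasta", tmp / "db.fasta", tmp / "hits.tsv"
        write_fasta(queries, qpath)
        write_fasta(database, dpath)
        cmd = command_template.format(query=qpath, db=dpath, out=opath)
        subprocess.run(shlex.split(cmd), check=True)
        return read_hits_tabular(opath)
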