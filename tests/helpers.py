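"""Independent oracles for the test suite.

Alignment scores are recomputed with scikit-bio's ``pair_align`` (a
separate Smith-Waterman implementation) and translations with Biopython's
``Seq.translate`` called directly, so none of the oracle code shares a
code path with the package's search engine.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq
from skbio.alignment import pair_align
from skbio.sequence import SubstitutionMatrix

BLOSUM62 = SubstitutionMatrix.by_name("BLOSUM62")


def rc(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate(rng: np.random.Generator, seq: str, p: float) -> str:
    """Substitute each position with probability p (uniform other base)."""
    chars = list(seq)
    for i in np.flatnonzero(rng.random(len(chars)) < p):
        chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
    return "".join(chars)


def sw_score_nt(a: str, b: str, match=2.0, mismatch=-3.0, gap_open=5.0, gap_extend=2.0) -> float:
    """Smith-Waterman score, BLAST gap convention (gap of g costs open + g*extend)."""
    res = pair_align(
        a, b, mode="local", sub_score=(float(match), float(mismatch)),
        gap_cost=(float(gap_open), float(gap_extend)),
    )
    return float(res.score)


def sw_best_nt(query: str, subject: str, **kw) -> float:
    """Best local score over both strands of the query."""
    return max(sw_score_nt(query, subject, **kw), sw_score_nt(rc(query), subject, **kw))


def sw_score_prot(a: str, b: str, gap_open=11.0, gap_extend=1.0) -> float:
    if not a or not b:
        return 0.0
    res = pair_align(
        a, b, mode="local", sub_score=BLOSUM62,
        gap_cost=(float(gap_open), float(gap_extend)),
    )
    return float(res.score)


def translate_six_frames(nt: str) -> dict[int, str]:
    """Independent six-frame translation (stops as '*', partial codons dropped)."""
    out: dict[int, str] = {}
    rcs = rc(nt)
    for f in (1, 2, 3):
        for seq, key in ((nt, f), (rcs, -f)):
            s = seq[f - 1:]
            s = s[: len(s) - len(s) % 3]
            out[key] = str(Seq(s).translate(table=1, stop_symbol="*")) if s else ""
    return out


def sw_best_translated(query_nt: str, subject_nt: str) -> float:
    """Exhaustive best protein SW score over all 36 frame pairs."""
    qf = translate_six_frames(query_nt)
    sf = translate_six_frames(subject_nt)
    return max(sw_score_prot(a, b) for a in qf.values() for b in sf.values())


def union_length(intervals) -> int:
    """Set-based interval-union oracle (half-open intervals)."""
    covered: set[int] = set()
    for lo, hi in intervals:
        covered.update(range(lo, hi))
    return len(covered)
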