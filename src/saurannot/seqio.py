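"""Sequence I/O and sequence-level utilities.

Houses the two core value types of the pipeline (:class:`SequenceRecord`,
:class:`SearchHit`), FASTA reading/writing, adaptor excision, six-frame
translation, and the 12-column tabular hit format used to interchange
search results with external engines.

Coordinate convention: all in-memory coordinates are 0-based half-open on
the forward strand.  The tabular format converts to the conventional
1-based inclusive coordinates (and encodes subject strand by swapping
sstart/send) only at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "SearchHit",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "trim_adaptors",
    "six_frame_translate",
    "read_hits_tabular",
    "write_hits_tabular",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SequenceRecord:
    """A single nucleotide sequence: contig, singleton, reference gene, or contig fragment.

    ``residues`` is stored uppercase over the alphabet {A, C, G, T, N};
    RNA 'U' is mapped to 'T' on construction through :func:`read_fasta`.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if not self.residues:
            raise ValueError(f"sequence record {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SearchHit:
    """One local-alignment hit between a query and a subject sequence.

    Coordinates are 0-based half-open on the forward strand of each
    sequence, with ``query_start < query_end`` and
    ``subject_start < subject_end`` always.  Strand/frame is carried in
    ``query_frame`` / ``subject_frame``: ±1 in nucleotide mode (sign only),
    {±1, ±2, ±3} in translated mode.  ``alignment_length`` counts alignment
    columns (nucleotides in nucleotide mode, amino acids in translated
    mode).  ``score`` is the raw alignment score under the scoring scheme
    that produced the hit; ``bit_score`` its Karlin–Altschul normalization.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    e_value: float
    bit_score: float
    query_frame: int = 1
    subject_frame: int = 1
    score: float = field(default=0.0, compare=False)

    def rank_key(self) -> tuple:
        """Lexicographic ranking key: e-value asc, match length desc, %id desc, subject id asc."""
        return (
            self.e_value,
            -self.alignment_length,
            -self.percent_identity,
            self.subject_id,
        )


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly wrapped) multi-record FASTA file.

    Residues are uppercased and 'U' mapped to 'T'.  An empty file yields an
    empty list.  Raises ``ValueError`` on content before the first header
    or on duplicate record ids.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: sequence data before first FASTA header"
                    )
                break
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().replace("U", "T")
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 80) -> None:
    """Write records as FASTA, wrapped at ``wrap`` columns."""
    bio = (
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Adaptor trimming
# ---------------------------------------------------------------------------

def _occurrences(haystack: str, needle: str) -> Iterator[tuple[int, int]]:
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return
        yield i, i + len(needle)
        start = i + 1


def trim_adaptors(
    record: SequenceRecord,
    adaptor_list: Sequence[str],
    min_retained_len: int = 91,
) -> list[SequenceRecord]:
    """Excise every exact adaptor occurrence (both orientations) from a record.

    Terminal occurrences shorten the record; internal occurrences split it
    into fragments named ``<id>_1``, ``<id>_2``, ...  Fragments shorter than
    ``min_retained_len`` are dropped, so an empty result is legal.  The
    default of 91 makes trimming compose with the downstream "> 90 nt"
    length filter.  Matching is exact substring; no mismatches are
    tolerated.
    """
    for a in adaptor_list:
        if len(a) < 8:
            raise ValueError(f"adaptor {a!r} shorter than 8 nt")
    patterns = set()
    for a in adaptor_list:
        a = a.upper()
        patterns.add(a)
        patterns.add(reverse_complement(a))

    seq = record.residues
    # Mark every position covered by any adaptor occurrence, then keep the
    # maximal uncovered runs.
    covered = bytearray(len(seq))
    for pat in patterns:
        for s, e in _occurrences(seq, pat):
            for i in range(s, e):
                covered[i] = 1
    if not any(covered):
        return [record]

    fragments: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        if covered[i]:
            i += 1
            continue
        j = i
        while j < n and not covered[j]:
            j += 1
        fragments.append(seq[i:j])
        i = j
    fragments = [f for f in fragments if len(f) >= min_retained_len]
    if not fragments:
        return []
    if len(fragments) == 1:
        return [replace(record, residues=fragments[0])]
    return [
        SequenceRecord(id=f"{record.id}_{k}", residues=f, description=record.description)
        for k, f in enumerate(fragments, 1)
    ]


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def _translate_frame(residues: str) -> str:
    usable = len(residues) - len(residues) % 3
    if usable < 3:
        return ""
    # Standard genetic code; '*' for stops (no truncation); codons with N -> 'X'.
    return str(Seq(residues[:usable]).translate(table=1, stop_symbol="*", to_stop=False))


def six_frame_translate(residues: str) -> dict[int, str]:
    """Translate a nucleotide sequence in all six frames.

    Keys are +1..+3 (offsets 0..2 on the forward strand) and -1..-3
    (offsets 0..2 on the reverse complement).  Stop codons emit '*' without
    truncating; codons containing 'N' emit 'X'; trailing partial codons are
    dropped.  Sequences shorter than 3 nt give six empty strings.
    """
    rc = reverse_complement(residues)
    out: dict[int, str] = {}
    for f in (1, 2, 3):
        out[f] = _translate_frame(residues[f - 1:])
        out[-f] = _translate_frame(rc[f - 1:])
    return out


# ---------------------------------------------------------------------------
# Tabular hit interchange (12-column BLAST "outfmt 6" dialect)
# ---------------------------------------------------------------------------
#
# Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
# send evalue bitscore [qframe sframe].  The two optional frame columns are
# our extension; 12-column files from external engines are accepted, with
# subject strand inferred from sstart > send.

_N_STD_COLS = 12


def write_hits_tabular(hits: Iterable[SearchHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = h.query_start + 1, h.query_end
            if h.subject_frame < 0:
                ss, se = h.subject_end, h.subject_start + 1
            else:
                ss, se = h.subject_start + 1, h.subject_end
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        # shortest round-trippable float text so the tabular
                        # form is lossless for all 12 standard fields
                        repr(float(h.percent_identity)),
                        str(h.alignment_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(qs),
                        str(qe),
                        str(ss),
                        str(se),
                        repr(float(h.e_value)),
                        repr(float(h.bit_score)),
                        str(h.query_frame),
                        str(h.subject_frame),
                    ]
                )
                + "\n"
            )


def read_hits_tabular(path: str | Path) -> list[SearchHit]:
    hits: list[SearchHit] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (_N_STD_COLS, _N_STD_COLS + 2):
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 or 14 tab-separated "
                    f"columns, found {len(cols)}"
                )
            qs, qe = int(cols[6]), int(cols[7])
            ss, se = int(cols[8]), int(cols[9])
            if len(cols) == _N_STD_COLS + 2:
                qframe, sframe = int(cols[12]), int(cols[13])
            else:
                qframe = 1
                sframe = -1 if ss > se else 1
            if ss > se:
                ss, se = se, ss
            if qs > qe:
                qs, qe = qe, qs
            hits.append(
                SearchHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    query_start=qs - 1,
                    query_end=qe,
                    subject_start=ss - 1,
                    subject_end=se,
                    e_value=float(cols[10]),
                    bit_score=float(cols[11]),
                    query_frame=qframe,
                    subject_frame=sframe,
                )
            )
    return hits
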