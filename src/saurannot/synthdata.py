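"""Deterministic synthetic-data generators with ground truth.

Every pipeline stage is testable without downloads: generators produce
reference transcriptomes (with forced open reading frames so translated
search is exercised), fragmented and mutated "assemblies" emulating
contig/singleton inputs (variable coverage, planted adaptors, redundant
near-duplicates, lineage-specific orphans), and annotated genomes
(exons/introns/intergenic spacers with exact GFF3 coordinates).  All
choices are recorded in a truth table keyed by fragment id, and every
generator is fully deterministic per seed.

Divergence is substitution-only by default (2:1 transition:transversion
bias, so nucleotide and amino-acid identity diverge realistically);
indels are deliberately excluded so identity arithmetic in downstream
checks stays exact.

Each generator draws from a domain-separated random stream
(``default_rng([seed, tag])`` with a distinct tag per generator), so the
same seed may safely be passed to every generator: without the
separation, e.g. a genome's "random" intergenic spacers would replay the
bit stream that produced the genes' codons and be spuriously similar to
the genes themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from saurannot.seqio import SequenceRecord, reverse_complement

__all__ = [
    "TruthEntry",
    "TruthTable",
    "GenomeTruth",
    "random_sequences",
    "generate_reference_transcriptome",
    "mutate_and_fragment",
    "generate_annotated_genome",
]

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
# transition partner, then the two transversions, per base
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one generated fragment."""

    fragment_id: str
    true_gene_id: str | None  # None for planted orphans
    gene_start: int  # interval on the gene, 0-based half-open (0,0 for orphans)
    gene_end: int
    strand: int
    divergence: float
    n_substitutions: int
    adaptor_start: int  # -1 when no adaptor planted
    adaptor_end: int
    redundancy_group: int  # fragments sharing a group are >= 95% identical


@dataclass
class TruthTable:
    entries: dict[str, TruthEntry] = field(default_factory=dict)

    def add(self, e: TruthEntry) -> None:
        if e.fragment_id in self.entries:
            raise ValueError(f"duplicate fragment id {e.fragment_id!r}")
        self.entries[e.fragment_id] = e

    def __getitem__(self, fragment_id: str) -> TruthEntry:
        return self.entries[fragment_id]

    def __len__(self) -> int:
        return len(self.entries)

    def non_orphans(self) -> list[TruthEntry]:
        return [e for e in self.entries.values() if e.true_gene_id is not None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries.values()])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def random_sequences(
    n: int, length_range: tuple[int, int], gc: float = 0.42, seed: int = 0, prefix: str = "seq"
) -> list[SequenceRecord]:
    """Plain i.i.d. random nucleotide records (e.g., mock ncRNA/mtDNA sets)."""
    rng = np.random.default_rng([seed, 1])
    lo, hi = length_range
    if n < 1 or lo < 1 or hi < lo:
        raise ValueError("invalid count or length range")
    out = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        out.append(SequenceRecord(id=f"{prefix}{i:04d}", residues=_random_seq(rng, length, gc)))
    return out


def generate_reference_transcriptome(
    n_genes: int,
    length_range: tuple[int, int] = (450, 1200),
    gc: float = 0.42,
    seed: int = 0,
    prefix: str = "gene",
) -> list[SequenceRecord]:
    """Random coding "cDNAs": ATG start, no in-frame internal stops, final stop.

    Lengths are rounded down to a multiple of 3 within ``length_range``.
    Deterministic per seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo < 9 or hi < lo:
        raise ValueError("invalid length range (need at least 9 nt)")
    rng = np.random.default_rng([seed, 2])
    genes = []
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1)) // 3 * 3
        n_codons = length // 3 - 2  # minus start and stop
        codons = ["ATG"]
        while len(codons) < n_codons + 1:
            c = _random_seq(rng, 3, gc)
            if c not in _STOPS:
                codons.append(c)
        codons.append(("TAA", "TAG", "TGA")[int(rng.integers(3))])
        genes.append(SequenceRecord(id=f"{prefix}{i:04d}", residues="".join(codons)))
    return genes


def _substitute(rng: np.random.Generator, seq: str, divergence: float) -> tuple[str, int]:
    """Substitute each position with probability ``divergence`` (ts:tv = 2:1)."""
    if divergence <= 0:
        return seq, 0
    chars = list(seq)
    hit = np.flatnonzero(rng.random(len(chars)) < divergence)
    for i in hit:
        base = chars[i]
        if base not in _BASE_INDEX:
            continue
        if rng.random() < 2 / 3:
            chars[i] = _TRANSITION[base]
        else:
            chars[i] = _TRANSVERSIONS[base][int(rng.integers(2))]
    return "".join(chars), int(len(hit))


def _substitute_exact(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute exactly ``n_subs`` distinct positions (for bounded-identity duplicates)."""
    chars = list(seq)
    pos = rng.choice(len(chars), size=min(n_subs, len(chars)), replace=False)
    for i in pos:
        base = chars[i]
        if base not in _BASE_INDEX:
            continue
        if rng.random() < 2 / 3:
            chars[i] = _TRANSITION[base]
        else:
            chars[i] = _TRANSVERSIONS[base][int(rng.integers(2))]
    return "".join(chars)


def mutate_and_fragment(
    genes: Sequence[SequenceRecord],
    divergence: float = 0.05,
    n_fragments_per_gene: int = 5,
    frag_length_range: tuple[int, int] = (150, 450),
    adaptor: str | None = None,
    adaptor_rate: float = 0.0,
    redundancy_rate: float = 0.0,
    orphan_rate: float = 0.1,
    seed: int = 0,
    gc: float = 0.42,
) -> tuple[list[SequenceRecord], TruthTable]:
    """Sample mutated fragments from genes, emulating contig/singleton input.

    Per gene, ``n_fragments_per_gene`` fragments are drawn uniformly; each
    position is substituted with probability ``divergence`` (2:1
    transition bias); the reverse strand is taken with probability 0.5.
    With probability ``orphan_rate`` a fragment is replaced by fresh
    random sequence (a true orphan, absent from every reference).  With
    probability ``adaptor_rate`` the adaptor is planted at a random
    terminal or internal position (recorded).  With probability
    ``redundancy_rate`` a fragment additionally emits a near-duplicate
    (exactly 2% of positions substituted, guaranteeing >= 95% identity),
    sharing its redundancy group.  All choices are recorded in the
    returned :class:`TruthTable`.
    """
    for rate in (divergence, adaptor_rate, redundancy_rate, orphan_rate):
        if not 0 <= rate <= 1:
            raise ValueError("rates must be within [0, 1]")
    rng = np.random.default_rng([seed, 3])
    lo, hi = frag_length_range
    fragments: list[SequenceRecord] = []
    truth = TruthTable()
    counter = 0
    group_counter = 0

    def emit(residues: str, entry_kwargs: dict) -> None:
        nonlocal counter
        fid = f"frag{counter:05d}"
        counter += 1
        fragments.append(SequenceRecord(id=fid, residues=residues))
        truth.add(TruthEntry(fragment_id=fid, **entry_kwargs))

    for gene in genes:
        glen = len(gene)
        for _ in range(n_fragments_per_gene):
            group_counter += 1
            is_orphan = rng.random() < orphan_rate
            if is_orphan:
                length = int(rng.integers(lo, min(hi, max(lo, glen)) + 1))
                seq = _random_seq(rng, length, gc)
                base_entry = dict(
                    true_gene_id=None, gene_start=0, gene_end=0, strand=1,
                    divergence=0.0, n_substitutions=0,
                )
            else:
                length = int(rng.integers(lo, hi + 1))
                length = min(length, glen)
                start = int(rng.integers(0, glen - length + 1))
                sub = gene.residues[start:start + length]
                seq, n_subs = _substitute(rng, sub, divergence)
                strand = -1 if rng.random() < 0.5 else 1
                if strand == -1:
                    seq = reverse_complement(seq)
                base_entry = dict(
                    true_gene_id=gene.id, gene_start=start, gene_end=start + length,
                    strand=strand, divergence=divergence, n_substitutions=n_subs,
                )
            a_start = a_end = -1
            if adaptor is not None and rng.random() < adaptor_rate:
                choice = int(rng.integers(3))  # 0 prefix, 1 suffix, 2 internal
                if choice == 0:
                    pos = 0
                elif choice == 1:
                    pos = len(seq)
                else:
                    pos = int(rng.integers(1, len(seq)))
                seq = seq[:pos] + adaptor + seq[pos:]
                a_start, a_end = pos, pos + len(adaptor)
            emit(seq, dict(base_entry, adaptor_start=a_start, adaptor_end=a_end,
                           redundancy_group=group_counter))
            if rng.random() < redundancy_rate:
                dup = _substitute_exact(rng, seq, int(0.02 * len(seq)))
                emit(dup, dict(base_entry, adaptor_start=a_start, adaptor_end=a_end,
                               redundancy_group=group_counter))
    return fragments, truth


@dataclass
class GenomeTruth:
    """Ground truth of a generated annotated genome."""

    # transcript id -> (contig id, strand, [(exon_start, exon_end), ...] genomic, ascending)
    transcripts: dict[str, tuple[str, int, list[tuple[int, int]]]] = field(default_factory=dict)

    def spliced(self, genome: Sequence[SequenceRecord], transcript_id: str) -> str:
        contig_id, strand, exons = self.transcripts[transcript_id]
        contig = {r.id: r for r in genome}[contig_id]
        seq = "".join(contig.residues[s:e] for s, e in exons)
        return seq if strand == 1 else reverse_complement(seq)


def generate_annotated_genome(
    genes: Sequence[SequenceRecord],
    exons_per_gene_range: tuple[int, int] = (2, 5),
    intron_length_range: tuple[int, int] = (60, 300),
    intergenic_length_range: tuple[int, int] = (500, 1500),
    seed: int = 0,
    gc: float = 0.42,
    contig_id: str = "contig1",
) -> tuple[list[SequenceRecord], str, GenomeTruth]:
    """Embed genes as exon/intron structures in a random genome.

    Each gene is split into ``exons_per_gene_range`` exons separated by
    random introns, placed on a random strand between random intergenic
    spacers.  Returns the genome (single contig), the GFF3 text
    (1-based inclusive, transcript + exon features), and the truth object;
    splicing the GFF3 exons reconstructs each gene exactly.
    """
    for lo, hi in (exons_per_gene_range, intron_length_range, intergenic_length_range):
        if lo < 1 or hi < lo:
            raise ValueError("ranges must be positive with lo <= hi")
    rng = np.random.default_rng([seed, 4])
    parts: list[str] = []
    pos = 0
    truth = GenomeTruth()
    gff_lines = ["##gff-version 3"]

    def spacer() -> None:
        nonlocal pos
        n = int(rng.integers(intergenic_length_range[0], intergenic_length_range[1] + 1))
        parts.append(_random_seq(rng, n, gc))
        pos += n

    feature_rows: list[tuple[int, str]] = []  # (start for sorting, line)
    for gene in genes:
        spacer()
        n_exons = int(rng.integers(exons_per_gene_range[0], exons_per_gene_range[1] + 1))
        n_exons = min(n_exons, max(1, len(gene) // 30))
        # cut the transcript into n_exons non-empty pieces
        if n_exons > 1:
            cuts = sorted(rng.choice(np.arange(1, len(gene)), size=n_exons - 1, replace=False))
        else:
            cuts = []
        bounds = [0, *map(int, cuts), len(gene)]
        exon_seqs = [gene.residues[bounds[i]:bounds[i + 1]] for i in range(n_exons)]
        introns = [
            _random_seq(rng, int(rng.integers(intron_length_range[0], intron_length_range[1] + 1)), gc)
            for _ in range(n_exons - 1)
        ]
        region = exon_seqs[0]
        offsets = [(0, len(exon_seqs[0]))]
        for intron, exon in zip(introns, exon_seqs[1:]):
            region += intron
            offsets.append((len(region), len(region) + len(exon)))
            region += exon
        strand = -1 if rng.random() < 0.5 else 1
        region_start = pos
        if strand == -1:
            placed = reverse_complement(region)
            exon_coords = [
                (region_start + len(region) - e, region_start + len(region) - s)
                for s, e in offsets
            ]
            exon_coords.sort()
        else:
            placed = region
            exon_coords = [(region_start + s, region_start + e) for s, e in offsets]
        parts.append(placed)
        pos += len(region)
        tid = f"{gene.id}.t1"
        truth.transcripts[tid] = (contig_id, strand, exon_coords)
        strand_sym = "+" if strand == 1 else "-"
        t_start, t_end = exon_coords[0][0], exon_coords[-1][1]
        feature_rows.append(
            (t_start,
             f"{contig_id}\tsynth\tmRNA\t{t_start + 1}\t{t_end}\t.\t{strand_sym}\t.\tID={tid}")
        )
        for k, (s, e) in enumerate(exon_coords, 1):
            feature_rows.append(
                (s,
                 f"{contig_id}\tsynth\texon\t{s + 1}\t{e}\t.\t{strand_sym}\t.\t"
                 f"ID={tid}.exon{k};Parent={tid}")
            )
    spacer()
    genome = [SequenceRecord(id=contig_id, residues="".join(parts))]
    feature_rows.sort(key=lambda t: t[0])
    gff_lines.extend(line for _, line in feature_rows)
    return genome, "\n".join(gff_lines) + "\n", truth
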