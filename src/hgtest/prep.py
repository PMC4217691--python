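"""Pre-filters applied before tree inference.

Two data-reduction steps: greedy dereplication of near-identical sequences
(no surviving pair above a pairwise-identity ceiling, 90% by default) and
extraction of high-scoring alignment columns from per-column consistency
scores (the 0-9 integer scores emitted by consistency-based aligners;
columns scoring 5-9 are kept by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AA_ALPHABET
from .phylik import ProteinAlignment

__all__ = [
    "SequenceSet",
    "read_fasta",
    "write_fasta",
    "read_column_scores",
    "pairwise_identity",
    "dereplicate",
    "extract_columns",
]

_VALID = set(AA_ALPHABET) | set("-X")


@dataclass
class SequenceSet:
    """Named amino-acid sequences (possibly gapped, possibly unaligned)."""

    records: list  # of (label, sequence)

    def __post_init__(self):
        labels = [l for l, _ in self.records]
        dup = {l for l in labels if labels.count(l) > 1}
        if dup:
            raise ValueError(f"duplicate sequence labels: {sorted(dup)}")
        for label, seq in self.records:
            bad = set(seq.upper()) - _VALID
            if bad:
                raise ValueError(
                    f"record {label!r} contains non-amino-acid characters "
                    f"{sorted(bad)}")

    def __len__(self):
        return len(self.records)

    def labels(self):
        return [l for l, _ in self.records]

    @property
    def aligned(self) -> bool:
        return len({len(s) for _, s in self.records}) <= 1


def read_fasta(path) -> list:
    """(label, sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_alignment_file(path) -> list:
    """(label, sequence) pairs from FASTA or relaxed PHYLIP, sniffed from
    the first non-blank character ('>' means FASTA)."""
    with open(path) as fh:
        head = fh.read(200).lstrip()
    if head.startswith(">"):
        return read_fasta(path)
    return [(rec.id, str(rec.seq))
            for rec in SeqIO.parse(str(path), "phylip-relaxed")]


def write_fasta(records, path, width: int = 60):
    recs = [SeqRecord(Seq(seq), id=label, description="")
            for label, seq in records]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(recs)


def read_column_scores(path) -> np.ndarray:
    """Per-column integer scores 0-9: either one line of digits or
    whitespace-separated integers."""
    with open(path) as fh:
        text = fh.read()
    toks = text.split()
    if len(toks) == 1 and toks[0].isdigit() and len(toks[0]) > 1:
        scores = np.array([int(ch) for ch in toks[0]])
    else:
        scores = np.array([int(t) for t in toks])
    if np.any((scores < 0) | (scores > 9)):
        raise ValueError("column scores must lie in [0, 9]")
    return scores


def pairwise_identity(seq1: str, seq2: str, aligned: bool | None = None) -> float:
    """Fraction of matching residues over columns where neither sequence has
    a gap; ``X`` never counts as a match; zero ungapped overlap counts as 0.

    Equal-length inputs are treated as aligned; unaligned pairs are globally
    aligned first (BLOSUM-free, match/mismatch scoring) and the same column
    convention is applied to the resulting alignment.
    """
    s1, s2 = seq1.upper(), seq2.upper()
    if aligned is None:
        aligned = len(s1) == len(s2)
    if not aligned:
        aligner = PairwiseAligner(mode="global", match_score=1,
                                  mismatch_score=-1, open_gap_score=-2,
                                  extend_gap_score=-0.5)
        best = aligner.align(s1.replace("-", ""), s2.replace("-", ""))[0]
        s1, s2 = str(best[0]), str(best[1])
    a = np.frombuffer(s1.encode(), dtype=np.uint8)
    b = np.frombuffer(s2.encode(), dtype=np.uint8)
    gap, unk = ord("-"), ord("X")
    both = (a != gap) & (b != gap)
    if not both.any():
        return 0.0
    match = both & (a == b) & (a != unk)
    return float(match.sum() / both.sum())


def dereplicate(seqs: SequenceSet, max_identity: float = 0.90) -> SequenceSet:
    """Greedy redundancy filter: scan in input order, keep a record only if
    its identity to every already-kept record is <= ``max_identity``.

    The output therefore contains no pair above the ceiling, earlier records
    win ties, and input order is preserved.  Idempotent."""
    if not 0.0 < max_identity <= 1.0:
        raise ValueError("max_identity must be in (0, 1]")
    aligned = seqs.aligned
    kept: list = []
    for label, seq in seqs.records:
        if all(pairwise_identity(seq, kseq, aligned) <= max_identity
               for _, kseq in kept):
            kept.append((label, seq))
    return SequenceSet(kept)


def extract_columns(aln: ProteinAlignment, scores, min_score: int = 5,
                    max_score: int = 9) -> ProteinAlignment:
    """Sub-alignment of the columns whose score lies in
    [min_score, max_score], original order preserved."""
    scores = np.asarray(scores)
    if not (0 <= min_score <= max_score <= 9):
        raise ValueError(f"invalid score window [{min_score}, {max_score}]")
    if len(scores) != aln.n_sites:
        raise ValueError(
            f"score vector length {len(scores)} does not match alignment "
            f"length {aln.n_sites}")
    keep = np.nonzero((scores >= min_score) & (scores <= max_score))[0]
    if keep.size == 0:
        raise ValueError(
            f"no column has a score in [{min_score}, {max_score}]; "
            "the extracted alignment would be empty")
    return aln.subset_columns(keep)
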