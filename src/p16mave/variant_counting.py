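"""Paired amplicon reads -> per-residue amino-acid variant counts.

The assay reads out variant representation by amplicon sequencing (150-bp
paired-end).  Each read pair is first merged into a single contiguous
sequence by finding the ungapped 3'-overlap between mate 1 and the
reverse-complemented mate 2, resolving overlap disagreements to the
higher-quality base.  Merged reads are then anchored to the reference CDS by
best ungapped match, the codon at the target residue is translated with the
standard genetic code, and the count for that amino acid incremented.  Counts
are reported per amino acid (19 missense + 1 synonymous per residue), the
assay's unit of analysis; stop codons are tallied separately.

Coordinates: residues and CDS positions are 1-based; codon ``i`` spans CDS
positions ``3i-2 .. 3i``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "ReadPair",
    "MergedRead",
    "CountResult",
    "FormatError",
    "reverse_complement",
    "merge_read_pair",
    "count_variants",
    "read_fastq_pairs",
    "translate_codon",
]

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: sense codon -> amino acid; stop codons are absent (see :func:`translate_codon`).
CODON_TO_AA = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)


class FormatError(ValueError):
    """Malformed read or reference input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Standard-genetic-code translation; stop codons return ``"*"``."""
    if codon in STOP_CODONS:
        return "*"
    try:
        return CODON_TO_AA[codon]
    except KeyError:
        raise FormatError(f"untranslatable codon {codon!r}") from None


@dataclass
class ReadPair:
    """One paired-end observation; mate 2 is stored as sequenced (it is
    reverse-complemented during merging)."""

    seq1: str
    qual1: Sequence[int]
    seq2: str
    qual2: Sequence[int]

    def __post_init__(self) -> None:
        for seq, qual, name in ((self.seq1, self.qual1, "mate1"), (self.seq2, self.qual2, "mate2")):
            if len(seq) != len(qual):
                raise FormatError(f"{name}: sequence length {len(seq)} != quality length {len(qual)}")
            if not set(seq) <= _ALPHABET:
                raise FormatError(f"{name}: sequence contains characters outside ACGTN")


@dataclass
class MergedRead:
    """Consensus of an overlapping read pair."""

    sequence: str
    quality: list[int]
    overlap: int


def merge_read_pair(
    pair: ReadPair,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> MergedRead | None:
    """Merge mates into one contiguous sequence, or reject the pair.

    Searches ungapped overlaps of mate 1's 3' end with the reverse-complemented
    mate 2's 5' end, keeping the longest overlap whose mismatch fraction is at
    most ``max_mismatch_frac`` and whose length is at least ``min_overlap``.
    Within the overlap, disagreements are resolved to the base with the higher
    Phred quality (ties go to mate 1).  Returns ``None`` — a rejection, not an
    error — when no admissible overlap exists.
    """
    if not pair.seq1 or not pair.seq2:
        raise FormatError("empty read")
    s1, q1 = pair.seq1, list(pair.qual1)
    s2 = reverse_complement(pair.seq2)
    q2 = list(pair.qual2)[::-1]

    best = None
    for olap in range(min(len(s1), len(s2)), min_overlap - 1, -1):
        tail, head = s1[-olap:], s2[:olap]
        mismatches = sum(a != b for a, b in zip(tail, head))
        if mismatches <= max_mismatch_frac * olap:
            best = olap
            break  # longest admissible overlap wins
    if best is None:
        return None

    olap = best
    cons_seq: list[str] = []
    cons_q: list[int] = []
    off1 = len(s1) - olap
    for i in range(olap):
        b1, b2 = s1[off1 + i], s2[i]
        p1, p2 = q1[off1 + i], q2[i]
        if b1 == b2:
            cons_seq.append(b1)
            cons_q.append(max(p1, p2))
        elif p2 > p1:
            cons_seq.append(b2)
            cons_q.append(p2)
        else:  # quality tie -> mate 1
            cons_seq.append(b1)
            cons_q.append(p1)
    sequence = s1[:off1] + "".join(cons_seq) + s2[olap:]
    quality = q1[:off1] + cons_q + q2[olap:]
    return MergedRead(sequence, quality, olap)


@dataclass
class CountResult:
    """Per-amino-acid counts at one residue plus discard accounting."""

    counts: dict[str, int]
    stop_count: int
    n_input: int
    discards: Counter = field(default_factory=Counter)

    @property
    def n_discarded(self) -> int:
        return sum(self.discards.values())


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _best_offset(read: np.ndarray, ref_windows: np.ndarray) -> tuple[int, int]:
    """(offset, n_mismatches) of the best ungapped placement of ``read``."""
    mism = (ref_windows != read).sum(axis=1)
    off = int(mism.argmin())
    return off, int(mism[off])


def count_variants(
    merged_reads: Iterable[MergedRead],
    cds: str,
    residue_index: int,
    expected_length: int | None = None,
    max_offtarget_mismatch: int = 0,
) -> CountResult:
    """Count amino-acid variants at ``residue_index`` from merged reads.

    Each read is anchored to the reference by its best ungapped placement.
    Reads are discarded (tallied, never silently dropped) when their length
    differs from ``expected_length`` (if given), the target codon is not
    covered or contains N, or mismatches outside the target codon exceed
    ``max_offtarget_mismatch``.  Sense codons increment the per-amino-acid
    count; stop codons go to a separate tally.
    """
    if len(cds) % 3:
        raise FormatError("reference CDS length must be divisible by 3")
    if not 1 <= residue_index <= len(cds) // 3:
        raise FormatError(f"residue {residue_index} outside the reference CDS")
    codon_start = 3 * (residue_index - 1)

    ref = _encode(cds)
    from numpy.lib.stride_tricks import sliding_window_view

    counts: Counter = Counter()
    stop_count = 0
    discards: Counter = Counter()
    n_input = 0

    # Reads from an amplicon are highly duplicated: process unique sequences.
    uniq: Counter = Counter()
    for read in merged_reads:
        n_input += 1
        uniq[read.sequence] += 1

    windows_cache: dict[int, np.ndarray] = {}
    for seq, n in uniq.items():
        if expected_length is not None and len(seq) != expected_length:
            discards["length"] += n
            continue
        if len(seq) > len(cds):
            discards["length"] += n
            continue
        L = len(seq)
        if L not in windows_cache:
            windows_cache[L] = sliding_window_view(ref, L)
        offset, _ = _best_offset(_encode(seq), windows_cache[L])
        if not (offset <= codon_start and codon_start + 3 <= offset + L):
            discards["codon_not_covered"] += n
            continue
        codon = seq[codon_start - offset: codon_start - offset + 3]
        if "N" in codon:
            discards["ambiguous_codon"] += n
            continue
        # mismatches to the reference outside the target codon
        arr = _encode(seq)
        ref_slice = ref[offset: offset + L]
        mismatch_pos = np.nonzero(arr != ref_slice)[0] + offset
        offtarget = int(((mismatch_pos < codon_start) | (mismatch_pos >= codon_start + 3)).sum())
        if offtarget > max_offtarget_mismatch:
            discards["offtarget_mismatch"] += n
            continue
        aa = translate_codon(codon)
        if aa == "*":
            stop_count += n
        else:
            counts[aa] += n

    return CountResult(dict(counts), stop_count, n_input, discards)


def read_fastq_pairs(path1, path2) -> Iterator[ReadPair]:
    """Stream read pairs from two Phred+33 FASTQ files (4-line records)."""
    with open(path1) as f1, open(path2) as f2:
        while True:
            rec1 = [f1.readline() for _ in range(4)]
            rec2 = [f2.readline() for _ in range(4)]
            if not rec1[0] and not rec2[0]:
                return
            if not rec1[0] or not rec2[0]:
                raise FormatError("FASTQ files have unequal numbers of records")
            seq1, qs1 = rec1[1].strip(), rec1[3].strip()
            seq2, qs2 = rec2[1].strip(), rec2[3].strip()
            yield ReadPair(
                seq1, [ord(c) - 33 for c in qs1],
                seq2, [ord(c) - 33 for c in qs2],
            )
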