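"""Read-level stages: quality trimming, paired-end merging, exact-length filter.

Amplicon reads are primer-anchored, so read 1 always starts at the amplicon
5' end and read 2 (after reverse complementing) always ends at its 3' end.
Merging is therefore an ungapped overlap scan: among all overlap lengths of
at least ``min_overlap`` choose the one with the smallest mismatch fraction
(ties go to the longer overlap), reject the pair if even the best overlap
exceeds ``max_mismatch_fraction``.  Within the overlap a disagreeing base is
resolved toward the higher-quality call (tie: read 1) and the merged quality
is the maximum of the two.

Because the screen scores substitutions only, any merged read whose length
differs from the reference amplicon — an insertion, a deletion, or a
mis-merge — is discarded before mutation calling.

Qualities are Sanger phred+33 throughout; gzipped FASTQ is transparent.
"""

from __future__ import annotations

import gzip
import io
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core import decode_seq, encode_seq, revcomp

PHRED_OFFSET = 33
MAX_PHRED = 60

NO_OVERLAP = "no_overlap"
TOO_MANY_MISMATCHES = "too_many_mismatches"

#: a candidate overlap counts as detected only below this mismatch fraction;
#: random sequence mismatches ~75% of the time, so anything above this bar
#: means the mates simply do not overlap by at least ``min_overlap``
OVERLAP_DETECTION_FRACTION = 0.25


@dataclass
class ReadRecord:
    """One FASTQ record: id, sequence (may contain N), per-base phred scores."""

    id: str
    seq: str
    quals: np.ndarray

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.seq) != len(self.quals):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")
        if len(self.quals) and (
            self.quals.min() < 0 or self.quals.max() > MAX_PHRED
        ):
            raise ValueError(f"{self.id}: phred scores must lie in [0, {MAX_PHRED}]")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class MergedRead:
    """A merged pair: sequence, qualities, realized overlap, source read ids."""

    seq: str
    quals: np.ndarray
    overlap_length: int
    source_ids: tuple[str, str]

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MergeFailure:
    """Why a pair could not be merged: ``no_overlap`` or ``too_many_mismatches``."""

    reason: str
    source_ids: tuple[str, str] = ("", "")


def open_maybe_gzip(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode:
            # fixed mtime so identical content gives byte-identical archives
            gz = gzip.GzipFile(path, "wb", mtime=0)
            return io.TextIOWrapper(gz) if "t" in mode else gz
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream a (possibly gzipped) phred+33 FASTQ file."""
    with open_maybe_gzip(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            quals = (
                np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16)
                - PHRED_OFFSET
            )
            yield ReadRecord(id=title.split()[0], seq=seq, quals=quals)


def write_fastq(path, records: Iterable[ReadRecord]) -> None:
    with open_maybe_gzip(path, "wt") as handle:
        for rec in records:
            qual = (rec.quals + PHRED_OFFSET).astype(np.uint8).tobytes().decode("ascii")
            handle.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# quality trimming


def _trim_cuts(quals: np.ndarray, q_threshold: float) -> np.ndarray:
    """Vectorised 3'-trim cut positions for a (n, L) quality matrix.

    The cut at position c removes the suffix ``[c:]``; we choose the c
    maximising the removed running sum of (threshold - q), breaking ties
    toward the largest c (shortest removal).  c = L means no trimming.
    """
    n, L = quals.shape
    deficit = q_threshold - quals.astype(float)
    # suffix[c] = sum(deficit[c:]); build as reversed cumulative sum, with a
    # trailing zero for the "remove nothing" option
    suffix = np.zeros((n, L + 1))
    suffix[:, :L] = np.cumsum(deficit[:, ::-1], axis=1)[:, ::-1]
    # argmax on the reversed axis returns the *last* maximising index
    rev = suffix[:, ::-1]
    cuts = L - np.argmax(rev, axis=1)
    return cuts


def trim_quality(read: ReadRecord, q_threshold: float) -> ReadRecord:
    """3'-end quality trim by the running-sum rule.

    Removes the suffix maximising the sum of (q_threshold - q) over the
    removed bases; ties favour the shortest removal.  A read whose qualities
    are all below the threshold trims to an empty read.
    """
    if q_threshold < 0:
        raise ValueError("q_threshold must be non-negative")
    if len(read) == 0:
        return read
    cut = int(_trim_cuts(read.quals[None, :], q_threshold)[0])
    if cut == len(read):
        return read
    return ReadRecord(id=read.id, seq=read.seq[:cut], quals=read.quals[:cut])


# ---------------------------------------------------------------------------
# pair merging


def _best_overlap(
    a_seq: np.ndarray,
    a_qual: np.ndarray,
    b_seq: np.ndarray,
    b_qual: np.ndarray,
    min_overlap: int,
    max_mismatch_fraction: float,
):
    """Batch overlap scan for equal-length groups.

    a_* is read 1 (n, l1); b_* is read 2 already reverse-complemented into
    amplicon orientation (n, l2).  Returns (ov, frac): the chosen overlap per
    pair (0 where no admissible overlap exists) and its mismatch fraction.
    """
    n, l1 = a_seq.shape
    l2 = b_seq.shape[1]
    max_ov = min(l1, l2)
    best_frac = np.full(n, np.inf)
    best_ov = np.zeros(n, dtype=int)
    for ov in range(min_overlap, max_ov + 1):
        mism = np.sum(a_seq[:, l1 - ov :] != b_seq[:, :ov], axis=1)
        frac = mism / ov
        take = frac <= best_frac  # ties -> longer overlap wins (ov ascending)
        best_frac[take] = frac[take]
        best_ov[take] = ov
    return best_ov, best_frac


def merge_pairs(
    r1: ReadRecord,
    r2: ReadRecord,
    min_overlap: int = 30,
    max_mismatch_fraction: float = 0.02,
) -> MergedRead | MergeFailure:
    """Merge a read pair by ungapped overlap; r2 is reverse-complemented.

    Returns a :class:`MergedRead`, or a :class:`MergeFailure` whose reason is
    ``no_overlap`` (no overlap of at least ``min_overlap`` is detectable:
    the reads are too short, or every candidate mismatches like random
    sequence) or ``too_many_mismatches`` (a genuine overlap exists but its
    mismatch fraction exceeds ``max_mismatch_fraction``).
    """
    ids = (r1.id, r2.id)
    if min(len(r1), len(r2)) < min_overlap:
        return MergeFailure(NO_OVERLAP, ids)
    a_seq = encode_seq(r1.seq)[None, :]
    a_qual = r1.quals[None, :]
    b_seq = revcomp(encode_seq(r2.seq))[None, :]
    b_qual = r2.quals[::-1][None, :]
    ov, frac = _best_overlap(
        a_seq, a_qual, b_seq, b_qual, min_overlap, max_mismatch_fraction
    )
    if ov[0] == 0 or frac[0] > OVERLAP_DETECTION_FRACTION:
        return MergeFailure(NO_OVERLAP, ids)
    if frac[0] > max_mismatch_fraction:
        return MergeFailure(TOO_MANY_MISMATCHES, ids)
    seq, qual = _build_merged(
        a_seq[0], a_qual[0], b_seq[0], b_qual[0], int(ov[0])
    )
    return MergedRead(
        seq=decode_seq(seq), quals=qual, overlap_length=int(ov[0]), source_ids=ids
    )


def _build_merged(a_seq, a_qual, b_seq, b_qual, ov: int):
    """Assemble one merged read for a chosen overlap length."""
    l1 = len(a_seq)
    ov_a, ov_qa = a_seq[l1 - ov :], a_qual[l1 - ov :]
    ov_b, ov_qb = b_seq[:ov], b_qual[:ov]
    take_b = ov_qb > ov_qa  # quality tie -> read-1 base
    ov_seq = np.where(take_b, ov_b, ov_a)
    ov_qual = np.maximum(ov_qa, ov_qb)
    seq = np.concatenate([a_seq[: l1 - ov], ov_seq, b_seq[ov:]])
    qual = np.concatenate([a_qual[: l1 - ov], ov_qual, b_qual[ov:]])
    return seq.astype(np.uint8), qual.astype(np.int16)


def _build_merged_batch(a_seq, a_qual, b_seq, b_qual, ov: int):
    """Vectorised merged assembly for a batch sharing one overlap length."""
    l1 = a_seq.shape[1]
    ov_a, ov_qa = a_seq[:, l1 - ov :], a_qual[:, l1 - ov :]
    ov_b, ov_qb = b_seq[:, :ov], b_qual[:, :ov]
    take_b = ov_qb > ov_qa
    ov_s = np.where(take_b, ov_b, ov_a)
    ov_q = np.maximum(ov_qa, ov_qb)
    seq = np.concatenate([a_seq[:, : l1 - ov], ov_s, b_seq[:, ov:]], axis=1)
    qual = np.concatenate([a_qual[:, : l1 - ov], ov_q, b_qual[:, ov:]], axis=1)
    return seq.astype(np.uint8), qual.astype(np.int16)


def length_filter(merged: MergedRead, expected_length: int) -> bool:
    """Keep a merged read iff its length equals the reference amplicon length."""
    return len(merged) == expected_length


# ---------------------------------------------------------------------------
# per-sample batch pipeline


@dataclass
class SampleQC:
    """Per-sample read-processing tallies, serialisable to a QC JSON."""

    input_pairs: int = 0
    merged: int = 0
    rejected_no_overlap: int = 0
    rejected_too_many_mismatches: int = 0
    length_filtered: int = 0
    dropped_n: int = 0
    kept: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


def process_sample(
    fastq1,
    fastq2,
    expected_length: int,
    q_threshold: float = 30,
    min_overlap: int = 30,
    max_mismatch_fraction: float = 0.02,
) -> tuple[np.ndarray, SampleQC]:
    """Trim, merge and exact-length-filter one sample's read pairs.

    Returns ``(kept, qc)`` where ``kept`` is a (n_kept, expected_length)
    uint8 array of merged reads (encoded A=0..T=3) with no N bases, in input
    order, and ``qc`` tallies every pair's fate.  The heavy lifting is done
    in batches grouped by read length so that flat-quality amplicon data is
    processed fully vectorised.
    """
    qc = SampleQC()

    # read, encode and trim; group pairs by trimmed lengths for batch merging
    groups: dict[tuple[int, int], list] = defaultdict(list)
    for r1, r2 in zip(read_fastq(fastq1), read_fastq(fastq2), strict=True):
        qc.input_pairs += 1
        a = encode_seq(r1.seq)
        b = encode_seq(r2.seq)
        c1 = int(_trim_cuts(r1.quals[None, :], q_threshold)[0]) if len(a) else 0
        c2 = int(_trim_cuts(r2.quals[None, :], q_threshold)[0]) if len(b) else 0
        groups[(c1, c2)].append(
            (a[:c1], r1.quals[:c1], b[:c2], r2.quals[:c2])
        )

    kept_chunks: list[np.ndarray] = []
    for (l1, l2), items in groups.items():
        if min(l1, l2) < min_overlap:
            qc.rejected_no_overlap += len(items)
            continue
        a_seq = np.stack([it[0] for it in items])
        a_qual = np.stack([it[1] for it in items])
        b_seq = np.stack([revcomp(it[2]) for it in items])
        b_qual = np.stack([it[3][::-1] for it in items])
        ov, frac = _best_overlap(
            a_seq, a_qual, b_seq, b_qual, min_overlap, max_mismatch_fraction
        )
        undetected = frac > OVERLAP_DETECTION_FRACTION
        bad = ~undetected & (frac > max_mismatch_fraction)
        qc.rejected_no_overlap += int(undetected.sum())
        qc.rejected_too_many_mismatches += int(bad.sum())
        ok = ~undetected & ~bad
        qc.merged += int(ok.sum())
        # keep only pairs whose merged length equals the amplicon length
        target_ov = l1 + l2 - expected_length
        right = ok & (ov == target_ov)
        qc.length_filtered += int((ok & ~right).sum())
        if right.any():
            seq, _ = _build_merged_batch(
                a_seq[right], a_qual[right], b_seq[right], b_qual[right], target_ov
            )
            has_n = (seq >= 4).any(axis=1)
            qc.dropped_n += int(has_n.sum())
            if (~has_n).any():
                kept_chunks.append(seq[~has_n])

    kept = (
        np.concatenate(kept_chunks)
        if kept_chunks
        else np.empty((0, expected_length), dtype=np.uint8)
    )
    qc.kept = int(kept.shape[0])
    return kept, qc
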