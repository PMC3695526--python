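"""Mutation calling and the single-mutation count matrix.

After exact-length filtering every kept read is collinear with the reference
amplicon, so mutation calling is a position-wise comparison — no alignment.
Reads are classified by their number of mismatches; only reads carrying
exactly one substitution enter the count matrix (one row per possible
substitution, 3L rows), which is the central data object of the screen.
Multi-mutation reads are tallied in an auxiliary table but excluded from all
statistics.

Sequencing errors are not corrected: a base-call error on a wild-type read
produces a spurious single-mutation read.  The screen relies on depth to keep
the true per-mutation signal above this uniform error floor; the expected
floor is reported alongside the QC via ``design.error_free_fraction``.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    Mutation,
    MutationCountMatrix,
    ReferenceAmplicon,
    SampleMeta,
    decode_seq,
    encode_seq,
    enumerate_mutations,
    format_label,
)

HISTOGRAM_BINS = ("0", "1", "2", "3", "4+")


def call_mutations(seq: str | np.ndarray, ref: ReferenceAmplicon) -> list[Mutation]:
    """Position-wise substitution calls for one exact-length read.

    Raises ``ValueError`` on a length mismatch — exact length is a pipeline
    invariant guaranteed by the upstream filter, so a violation here means a
    stage was skipped.
    """
    arr = encode_seq(seq) if isinstance(seq, str) else np.asarray(seq)
    ref_arr = ref.encoded
    if arr.shape != ref_arr.shape:
        raise ValueError(
            f"read length {arr.shape[-1]} != reference length {len(ref.sequence)}"
        )
    diff = np.nonzero(arr != ref_arr)[0]
    seq_str = decode_seq(arr)
    return [
        Mutation(int(p), ref.sequence[int(p)], seq_str[int(p)]) for p in diff
    ]


def _as_matrix(reads, ref: ReferenceAmplicon) -> np.ndarray:
    if isinstance(reads, np.ndarray) and reads.ndim == 2:
        arr = reads
    else:
        arr = np.stack([encode_seq(r) if isinstance(r, str) else np.asarray(r) for r in reads]) \
            if len(reads) else np.empty((0, len(ref.sequence)), dtype=np.uint8)
    if arr.shape[1] != len(ref.sequence):
        raise ValueError("reads are not collinear with the reference (length mismatch)")
    return arr


def mutation_counts_per_read(reads, ref: ReferenceAmplicon) -> np.ndarray:
    """Number of mismatches vs the reference for each read."""
    arr = _as_matrix(reads, ref)
    return (arr != ref.encoded[None, :]).sum(axis=1)


def mutation_count_histogram(reads, ref: ReferenceAmplicon) -> pd.DataFrame:
    """Read tallies binned by mutation count {0, 1, 2, 3, 4+}.

    Returns a DataFrame with ``count`` and ``fraction`` columns; fractions
    are NaN for an empty input.
    """
    nmut = mutation_counts_per_read(reads, ref)
    counts = [
        int((nmut == 0).sum()),
        int((nmut == 1).sum()),
        int((nmut == 2).sum()),
        int((nmut == 3).sum()),
        int((nmut >= 4).sum()),
    ]
    total = int(len(nmut))
    frac = [c / total if total else np.nan for c in counts]
    return pd.DataFrame(
        {"count": counts, "fraction": frac}, index=pd.Index(HISTOGRAM_BINS, name="n_mutations")
    )


def _row_index_lookup(ref: ReferenceAmplicon) -> np.ndarray:
    """(L, 4) lookup: canonical matrix row of (position, alt base), -1 for ref."""
    L = len(ref.sequence)
    lut = np.full((L, 4), -1, dtype=np.int64)
    for row, m in enumerate(enumerate_mutations(ref)):
        lut[m.position, encode_seq(m.alt_base)[0]] = row
    return lut


def single_mutation_counts(reads, ref: ReferenceAmplicon) -> np.ndarray:
    """Length-3L vector of single-mutation read counts in canonical row order."""
    arr = _as_matrix(reads, ref)
    diff = arr != ref.encoded[None, :]
    singles = diff.sum(axis=1) == 1
    if not singles.any():
        return np.zeros(ref.n_single_mutations, dtype=np.int64)
    sub = arr[singles]
    pos = np.argmax(diff[singles], axis=1)
    alt = sub[np.arange(sub.shape[0]), pos]
    rows = _row_index_lookup(ref)[pos, alt]
    return np.bincount(rows, minlength=ref.n_single_mutations).astype(np.int64)


def build_count_matrix(
    sample_reads: Mapping[str, object],
    ref: ReferenceAmplicon,
    samples: Sequence[SampleMeta],
    collect_multi: bool = False,
):
    """Assemble the 3L x samples single-mutation count matrix.

    ``sample_reads`` maps sample id to that sample's kept exact-length reads
    (encoded 2-D array or list of strings).  Reads with zero or more than one
    mutation contribute nothing to the matrix.  With ``collect_multi=True``
    additionally returns a tidy DataFrame of multi-mutation genotype tallies
    (sample_id, labels, n_mutations, count) for downstream double-mutant
    analyses.
    """
    order = [s.sample_id for s in samples]
    missing = [sid for sid in order if sid not in sample_reads]
    if missing:
        raise ValueError(f"missing reads for samples {missing}")
    muts = enumerate_mutations(ref)
    labels = [format_label(m, ref) for m in muts]
    cols = {}
    multi_rows = []
    for s in samples:
        reads = sample_reads[s.sample_id]
        cols[s.sample_id] = single_mutation_counts(reads, ref)
        if collect_multi:
            arr = _as_matrix(reads, ref)
            nmut = (arr != ref.encoded[None, :]).sum(axis=1)
            tally: Counter = Counter()
            for row in arr[nmut >= 2]:
                genotype = tuple(
                    format_label(m, ref) for m in call_mutations(row, ref)
                )
                tally[genotype] += 1
            for genotype, c in sorted(tally.items()):
                multi_rows.append(
                    {
                        "sample_id": s.sample_id,
                        "labels": ";".join(genotype),
                        "n_mutations": len(genotype),
                        "count": c,
                    }
                )
    counts = pd.DataFrame(cols, index=pd.Index(labels, name="mutation"))[order]
    matrix = MutationCountMatrix(
        ref=ref, mutations=muts, samples=list(samples), counts=counts
    )
    if collect_multi:
        multi = pd.DataFrame(
            multi_rows, columns=["sample_id", "labels", "n_mutations", "count"]
        )
        return matrix, multi
    return matrix


def mutation_fractions(matrix: MutationCountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-sample mutation fractions: each count divided by its column total.

    Columns with a zero total carry no information and are excluded with a
    warning; every retained column sums to 1.
    """
    counts = matrix.counts if isinstance(matrix, MutationCountMatrix) else matrix
    totals = counts.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        warnings.warn(
            f"excluding zero-total samples from fractions: {zero}", stacklevel=2
        )
    keep = [c for c in counts.columns if c not in zero]
    return counts[keep] / totals[keep]


def region_detection_stats(
    matrix: MutationCountMatrix, ref: ReferenceAmplicon | None = None
) -> pd.DataFrame:
    """Per-sample sensitivity/specificity of the mutagenized core region.

    sensitivity: fraction of the 3*|core| target substitutions observed at
    least once in the sample.  specificity: fraction of the sample's
    single-mutation reads whose mutation lies inside the core (the remainder
    map to the primer flanks, where true mutations should be rare).
    """
    ref = ref or matrix.ref
    in_region = np.array(
        [ref.in_mutated_region(m.position) for m in matrix.mutations]
    )
    counts = matrix.counts.values
    n_target = int(in_region.sum())
    out = {}
    for j, s in enumerate(matrix.samples):
        col = counts[:, j]
        sens = float((col[in_region] >= 1).sum() / n_target)
        total = col.sum()
        spec = float(col[in_region].sum() / total) if total else np.nan
        out[s.sample_id] = {"sensitivity": sens, "specificity": spec}
    return pd.DataFrame(out).T.rename_axis("sample_id")


def fraction_cdfs(
    matrix: MutationCountMatrix, ref: ReferenceAmplicon | None = None
) -> dict[str, dict[str, np.ndarray]]:
    """Cumulative distributions of per-mutation fractions, core vs flanks.

    For each sample returns the sorted per-mutation fraction values of the
    two positional subgroups, suitable for plotting the empirical CDFs that
    separate genuine core mutations from the primer-flank error floor.
    """
    ref = ref or matrix.ref
    in_region = np.array(
        [ref.in_mutated_region(m.position) for m in matrix.mutations]
    )
    fracs = mutation_fractions(matrix)
    out = {}
    for sid in fracs.columns:
        col = fracs[sid].values
        out[sid] = {
            "core": np.sort(col[in_region]),
            "flank": np.sort(col[~in_region]),
        }
    return out
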