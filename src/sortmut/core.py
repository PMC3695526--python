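"""Domain types shared by every stage of a saturation-mutagenesis sort-seq screen.

The screen works on a short, fixed-length amplicon: a mutagenized core
(typically the regulatory region of interest) flanked by the PCR primer
footprints.  Internally every coordinate is a 0-based index into the amplicon
and every sequence is DNA.  Biologically meaningful labels are expressed on
the RNA alphabet relative to the A of the start codon, which is position +1;
the base immediately 5' of it is -1 and there is no position 0.  A single
substitution is therefore printed like ``U-75A``: reference U, seventy-five
bases upstream of the AUG, mutated to A.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

DNA_ALPHABET = "ACGT"
#: fixed project-wide alternative-base order; gives every amplicon a
#: reproducible row order of its 3L possible substitutions
ALT_ORDER = "ACGT"

_DNA_TO_RNA = str.maketrans("ACGT", "ACGU")
_RNA_TO_DNA = str.maketrans("ACGU", "ACGT")

_LABEL_RE = re.compile(r"^([ACGU])(-?\d+)([ACGU])$")

# integer encoding used throughout the package: A=0 C=1 G=2 T=3, N=4
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0, C=1, G=2, T=3, N=4)."""
    arr = _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"non-DNA character {bad!r} in sequence")
    return arr


def decode_seq(arr: np.ndarray) -> str:
    """Inverse of :func:`encode_seq`."""
    return _DECODE[arr].tobytes().decode("ascii")


def revcomp(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of an encoded sequence (N maps to N)."""
    return _COMPLEMENT[arr][::-1]


@dataclass(frozen=True)
class ReferenceAmplicon:
    """The sequenced amplicon, its mutagenized core and the AUG anchor.

    Parameters
    ----------
    name : str
        Identifier (e.g. the FASTA record id).
    sequence : str
        DNA over {A,C,G,T}; the full analysed window (default design: 158 nt).
    mutated_region : tuple[int, int]
        Half-open ``[start, end)`` interval, 0-based amplicon coordinates, of
        the error-prone-PCR mutagenized core (default design: 109 nt).
    aug_index : int
        0-based amplicon index of the A of the start codon.  May sit anywhere
        relative to the amplicon; labels are computed relative to it.
    """

    name: str
    sequence: str
    mutated_region: tuple[int, int]
    aug_index: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("amplicon sequence must be non-empty")
        if set(self.sequence) - set(DNA_ALPHABET):
            bad = sorted(set(self.sequence) - set(DNA_ALPHABET))
            raise ValueError(f"amplicon alphabet must be {{A,C,G,T}}; found {bad}")
        start, end = self.mutated_region
        if not (0 <= start < end <= len(self.sequence)):
            raise ValueError(
                f"mutated_region [{start}, {end}) outside amplicon of "
                f"length {len(self.sequence)}"
            )
        object.__setattr__(self, "mutated_region", (int(start), int(end)))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def encoded(self) -> np.ndarray:
        return encode_seq(self.sequence)

    @property
    def n_single_mutations(self) -> int:
        """Size of the single-substitution space, 3L."""
        return 3 * len(self.sequence)

    def in_mutated_region(self, position: int) -> bool:
        start, end = self.mutated_region
        return start <= position < end

    @classmethod
    def from_fasta(
        cls,
        path,
        mutated_region: tuple[int, int],
        aug_index: int,
    ) -> "ReferenceAmplicon":
        """Load the reference from a single-record FASTA file.

        ``mutated_region`` and ``aug_index`` are experiment metadata and come
        from the run configuration, not from the FASTA.
        """
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(
                f"expected exactly one FASTA record in {path}, found {len(records)}"
            )
        rec = records[0]
        return cls(
            name=rec.id,
            sequence=str(rec.seq).upper(),
            mutated_region=tuple(mutated_region),
            aug_index=int(aug_index),
        )


@dataclass(frozen=True, order=True)
class Mutation:
    """A single-nucleotide substitution in amplicon coordinates."""

    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base not in DNA_ALPHABET or self.alt_base not in DNA_ALPHABET:
            raise ValueError(f"bases must be single DNA characters: {self}")
        if self.ref_base == self.alt_base:
            raise ValueError(f"alt base equals reference base at {self.position}")


def amplicon_to_aug(position: int, ref: ReferenceAmplicon) -> int:
    """Map a 0-based amplicon index to the AUG-relative coordinate.

    The A of the start codon is +1; the base 5' of it is -1; 0 never occurs.
    """
    if not 0 <= position < len(ref.sequence):
        raise ValueError(f"position {position} outside amplicon")
    d = position - ref.aug_index
    return d + 1 if d >= 0 else d


def aug_to_amplicon(rel: int, ref: ReferenceAmplicon) -> int:
    """Inverse of :func:`amplicon_to_aug`."""
    if rel == 0:
        raise ValueError("AUG-relative coordinate 0 does not exist")
    pos = ref.aug_index + rel - 1 if rel > 0 else ref.aug_index + rel
    if not 0 <= pos < len(ref.sequence):
        raise ValueError(f"AUG-relative position {rel} outside amplicon")
    return pos


def format_label(m: Mutation, ref: ReferenceAmplicon) -> str:
    """Render a mutation as its AUG-relative RNA label, e.g. ``U-75A``."""
    if ref.sequence[m.position] != m.ref_base:
        raise ValueError(
            f"mutation ref base {m.ref_base} disagrees with reference "
            f"{ref.sequence[m.position]} at position {m.position}"
        )
    rel = amplicon_to_aug(m.position, ref)
    return (
        m.ref_base.translate(_DNA_TO_RNA)
        + str(rel)
        + m.alt_base.translate(_DNA_TO_RNA)
    )


def parse_label(label: str, ref: ReferenceAmplicon) -> Mutation:
    """Parse an AUG-relative RNA label back into a :class:`Mutation`.

    Raises ``ValueError`` for malformed labels and for labels whose reference
    base disagrees with the amplicon at that position.
    """
    match = _LABEL_RE.match(label.strip())
    if match is None:
        raise ValueError(f"malformed mutation label {label!r}")
    ref_rna, rel_s, alt_rna = match.groups()
    pos = aug_to_amplicon(int(rel_s), ref)
    ref_base = ref_rna.translate(_RNA_TO_DNA)
    alt_base = alt_rna.translate(_RNA_TO_DNA)
    if ref.sequence[pos] != ref_base:
        raise ValueError(
            f"label {label!r}: reference base is {ref.sequence[pos]} at "
            f"amplicon position {pos} (AUG-relative {rel_s}), not {ref_base}"
        )
    if alt_base == ref_base:
        raise ValueError(f"label {label!r}: alt equals reference base")
    return Mutation(position=pos, ref_base=ref_base, alt_base=alt_base)


def enumerate_mutations(ref: ReferenceAmplicon) -> list[Mutation]:
    """All 3L single substitutions of the amplicon, in canonical order.

    Order: position ascending, then alternative base in the fixed order
    A<C<G<T with the reference base skipped.  This ordering defines the row
    order of every count matrix in the package.
    """
    out: list[Mutation] = []
    for pos, ref_base in enumerate(ref.sequence):
        for alt in ALT_ORDER:
            if alt != ref_base:
                out.append(Mutation(pos, ref_base, alt))
    return out


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequenced pool: background plasmid, FACS gate, replicate."""

    sample_id: str
    plasmid: str  # {"control", "srna"}
    gate: str  # {"unsorted", "all", "high", "low"}
    replicate: int

    PLASMIDS = ("control", "srna")
    GATES = ("unsorted", "all", "high", "low")

    def __post_init__(self) -> None:
        if self.plasmid not in self.PLASMIDS:
            raise ValueError(f"plasmid must be one of {self.PLASMIDS}: {self.plasmid!r}")
        if self.gate not in self.GATES:
            raise ValueError(f"gate must be one of {self.GATES}: {self.gate!r}")
        if int(self.replicate) < 1:
            raise ValueError(f"replicate must be >= 1: {self.replicate}")
        object.__setattr__(self, "replicate", int(self.replicate))

    @property
    def condition(self) -> str:
        """The (plasmid, gate) condition label, e.g. ``srna:high``."""
        return f"{self.plasmid}:{self.gate}"


def validate_sample_metas(samples: Sequence[SampleMeta]) -> None:
    """Enforce uniqueness of sample ids and of (plasmid, gate, replicate)."""
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dup}")
    keys = [(s.plasmid, s.gate, s.replicate) for s in samples]
    if len(set(keys)) != len(keys):
        dup = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (plasmid, gate, replicate) combinations: {dup}")


@dataclass
class MutationCountMatrix:
    """Reads-with-exactly-one-mutation counts: all 3L substitutions x samples.

    ``counts`` is a DataFrame indexed by mutation label (canonical row order
    from :func:`enumerate_mutations`) with one column per sample id.
    """

    ref: ReferenceAmplicon
    mutations: list[Mutation]
    samples: list[SampleMeta]
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.mutations) != self.ref.n_single_mutations:
            raise ValueError(
                f"expected {self.ref.n_single_mutations} mutation rows, "
                f"got {len(self.mutations)}"
            )
        if self.counts.shape != (len(self.mutations), len(self.samples)):
            raise ValueError("counts shape disagrees with mutations/samples")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        validate_sample_metas(self.samples)

    @property
    def labels(self) -> list[str]:
        return list(self.counts.index)

    def sample(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def columns_for_condition(self, condition: str) -> list[str]:
        """Sample ids whose ``plasmid:gate`` condition equals *condition*."""
        return [s.sample_id for s in self.samples if s.condition == condition]

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="mutation")

    @classmethod
    def from_tsv(cls, path, ref: ReferenceAmplicon, samples: Sequence[SampleMeta]):
        df = pd.read_csv(path, sep="\t", index_col="mutation")
        muts = enumerate_mutations(ref)
        expected = [format_label(m, ref) for m in muts]
        if list(df.index) != expected:
            raise ValueError(f"{path}: rows do not match the canonical mutation order")
        order = [s.sample_id for s in samples]
        missing = [c for c in order if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing sample columns {missing}")
        return cls(ref=ref, mutations=muts, samples=list(samples), counts=df[order].astype(int))


def iter_labels(ref: ReferenceAmplicon) -> Iterator[str]:
    for m in enumerate_mutations(ref):
        yield format_label(m, ref)
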