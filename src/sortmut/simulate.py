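"""End-to-end sort-seq simulator: library -> phenotype -> FACS -> paired reads.

Emulates a saturation-mutagenesis reporter screen so that every downstream
stage of the package can be exercised on data with a known truth table:

1. an error-prone-PCR plasmid library: clones carry 0-4 substitutions, with
   positions drawn mostly from the mutagenized core and a small fraction
   from the primer flanks;
2. a phenotype model on log10 fluorescence with two effect axes per
   mutation — a constitutive ``expression_shift`` (translation rate per se)
   and a ``regulation_loss`` (fraction of the sRNA repression abolished when
   the repressing sRNA plasmid is present);
3. FACS gating on log10 fluorescence with Gaussian cell-to-cell noise
   (FACS distributions are roughly log-normal), gates placed at percentiles
   of the wild-type control distributions;
4. paired-end sequencing of each sorted pool: read 1 covers the amplicon 5'
   prefix, read 2 the reverse complement of the 3' suffix, with per-base
   substitution errors at the rate implied by the phred profile, and an
   optional indel rate to exercise the exact-length filter.

All randomness flows from one seed; identical seeds give byte-identical
outputs.  The default scenario (demo reference + effect model) mirrors the
biology of an sRNA-repressed 5'-UTR: a binding-site window whose mutations
abolish repression, a repressive stem that mutations can destabilize
(higher expression) or stabilize (lower), and a start codon whose mutations
kill expression.  The magnitudes are package defaults for testing, not
measured values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    Mutation,
    ReferenceAmplicon,
    SampleMeta,
    aug_to_amplicon,
    decode_seq,
    format_label,
    revcomp,
)
from .readproc import PHRED_OFFSET, open_maybe_gzip

# ---------------------------------------------------------------------------
# demo reference: 158-nt amplicon, 109-nt centered mutagenized core,
# start codon at amplicon index 124 (so the core spans AUG-relative -100..+9)

DEMO_REFERENCE_SEQUENCE = (
    "CTGTCTACTTGTCGACTTTCAGGGTCATAGTCACCTTACGCGCCACGCTCCACCTGTGTT"
    "TGTATAGATCTAAAACTATAAGTCCTTAATCGCGGAGGCAAGTAAGTGTGATGGGGACGC"
    "CTCAATGAAGTCCGCATCTGAGTGTCCGTCTGAGCCGT"
)
DEMO_MUTATED_REGION = (24, 133)
DEMO_AUG_INDEX = 124


def demo_reference() -> ReferenceAmplicon:
    """The package's frozen synthetic demo amplicon (158 nt, 109-nt core)."""
    return ReferenceAmplicon(
        name="demo_amplicon",
        sequence=DEMO_REFERENCE_SEQUENCE,
        mutated_region=DEMO_MUTATED_REGION,
        aug_index=DEMO_AUG_INDEX,
    )


# ---------------------------------------------------------------------------
# phenotype model


@dataclass(frozen=True)
class MutationEffect:
    """Per-mutation phenotype: constitutive shift and loss of sRNA regulation."""

    expression_shift: float = 0.0
    regulation_loss: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.regulation_loss <= 1.0:
            raise ValueError("regulation_loss must lie in [0, 1]")


@dataclass
class EffectModel:
    """Log10-fluorescence phenotype model.

    value = basal + sum(expression_shift)
            - srna_repression * [plasmid == srna] * prod(1 - regulation_loss)
            + Normal(0, noise_sd)

    Mutations without an entry in ``effects`` are phenotypically silent.
    """

    basal_log_fluorescence: float = 3.0
    srna_repression: float = 1.0
    effects: dict[Mutation, MutationEffect] = field(default_factory=dict)
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def genotype_params(self, genotype) -> tuple[float, float]:
        """(total expression shift, remaining repression fraction) of a genotype."""
        shift = 0.0
        remain = 1.0
        for m in genotype:
            eff = self.effects.get(m)
            if eff is not None:
                shift += eff.expression_shift
                remain *= 1.0 - eff.regulation_loss
        return shift, remain


def assign_fluorescence(
    genotype,
    plasmid: str,
    model: EffectModel,
    rng: np.random.Generator | None = None,
) -> float:
    """Log10 fluorescence of one cell; deterministic when noise_sd = 0."""
    shift, remain = model.genotype_params(genotype)
    value = model.basal_log_fluorescence + shift
    if plasmid == "srna":
        value -= model.srna_repression * remain
    if model.noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        value += rng.normal(0.0, model.noise_sd)
    return float(value)


# default effect layout of the demo scenario, in AUG-relative coordinates
DEFAULT_EFFECT_LAYOUT = {
    # sRNA binding site: repression abolished, translation per se untouched
    "binding_site": (range(-79, -60), MutationEffect(regulation_loss=1.0)),
    # repressive-stem destabilization: constitutively higher expression
    "destabilizing": (range(-20, -12), MutationEffect(expression_shift=0.5)),
    # repressive-stem stabilization: constitutively lower expression
    "stabilizing": (range(-8, -3), MutationEffect(expression_shift=-0.8)),
    # start codon: expression largely abolished
    "start_codon": (range(1, 4), MutationEffect(expression_shift=-1.5)),
}


def effect_positions(ref: ReferenceAmplicon) -> dict[str, list[int]]:
    """Amplicon positions of each named effect class of the default layout."""
    return {
        name: [aug_to_amplicon(rel, ref) for rel in rels]
        for name, (rels, _) in DEFAULT_EFFECT_LAYOUT.items()
    }


def default_effect_model(ref: ReferenceAmplicon) -> EffectModel:
    """The default demo phenotype model (all three alts share a position's effect)."""
    effects: dict[Mutation, MutationEffect] = {}
    for _, (rels, eff) in DEFAULT_EFFECT_LAYOUT.items():
        for rel in rels:
            pos = aug_to_amplicon(rel, ref)
            ref_base = ref.sequence[pos]
            for alt in "ACGT":
                if alt != ref_base:
                    effects[Mutation(pos, ref_base, alt)] = eff
    return EffectModel(effects=effects)


# ---------------------------------------------------------------------------
# library generation

#: default per-clone mutation-count distribution of the error-prone library
DEFAULT_MUTATION_COUNT_DIST = {0: 0.45, 1: 0.35, 2: 0.12, 3: 0.05, 4: 0.03}
#: default share of mutations landing in the mutagenized core vs the flanks
DEFAULT_REGION_WEIGHTS = {"core": 0.9, "flanks": 0.1}


@dataclass
class Library:
    """A clone library: one genotype (tuple of Mutations) per transformant."""

    ref: ReferenceAmplicon
    clones: list[tuple[Mutation, ...]]

    def __len__(self) -> int:
        return len(self.clones)

    def table(self) -> pd.DataFrame:
        """Aggregated clone table: genotype labels, mutation count, clone count."""
        from collections import Counter

        tally = Counter(self.clones)
        rows = [
            {
                "genotype": ";".join(format_label(m, self.ref) for m in g) or "WT",
                "n_mutations": len(g),
                "clones": c,
            }
            for g, c in sorted(
                tally.items(), key=lambda kv: (len(kv[0]), kv[0])
            )
        ]
        return pd.DataFrame(rows, columns=["genotype", "n_mutations", "clones"])

    def mutant_sequences(self) -> np.ndarray:
        """(n_clones, L) encoded sequences with each genotype applied."""
        base = self.ref.encoded
        out = np.tile(base, (len(self.clones), 1))
        alt_codes = {b: i for i, b in enumerate("ACGT")}
        for i, genotype in enumerate(self.clones):
            for m in genotype:
                out[i, m.position] = alt_codes[m.alt_base]
        return out


def _position_probs(ref: ReferenceAmplicon, region_weights: dict) -> np.ndarray:
    L = len(ref.sequence)
    start, end = ref.mutated_region
    n_core = end - start
    n_flank = L - n_core
    w_core = float(region_weights.get("core", 0.0))
    w_flank = float(region_weights.get("flanks", 0.0))
    if w_core < 0 or w_flank < 0 or w_core + w_flank <= 0:
        raise ValueError("region weights must be non-negative with positive sum")
    p = np.empty(L)
    p[start:end] = w_core / n_core if n_core else 0.0
    flank_idx = np.r_[0:start, end:L]
    if n_flank:
        p[flank_idx] = w_flank / n_flank
    elif w_flank > 0:
        raise ValueError("flank weight > 0 but the core spans the whole amplicon")
    return p / p.sum()


def generate_library(
    ref: ReferenceAmplicon,
    n_clones: int,
    mutation_count_distribution: dict[int, float] | None = None,
    region_weights: dict[str, float] | None = None,
    seed: int | np.random.Generator = None,
) -> Library:
    """Draw an error-prone-PCR clone library.

    Each clone's mutation count is drawn from ``mutation_count_distribution``
    (over {0,1,2,3,4}; must sum to 1); its mutated positions are distinct and
    drawn with per-region weights (mutagenized core vs primer flanks); each
    alternative base is uniform over the three non-reference bases.
    """
    if seed is None:
        raise ValueError("a seed (or Generator) is required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dist = dict(mutation_count_distribution or DEFAULT_MUTATION_COUNT_DIST)
    ks = sorted(dist)
    probs = np.array([dist[k] for k in ks], dtype=float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("mutation-count distribution must be non-negative and sum to 1")
    pos_probs = _position_probs(ref, region_weights or DEFAULT_REGION_WEIGHTS)

    counts = rng.choice(ks, size=n_clones, p=probs)
    clones: list[tuple[Mutation, ...]] = []
    for m in counts:
        if m == 0:
            clones.append(())
            continue
        positions = rng.choice(len(ref.sequence), size=int(m), replace=False, p=pos_probs)
        genotype = []
        for pos in sorted(int(p) for p in positions):
            ref_base = ref.sequence[pos]
            alts = [b for b in "ACGT" if b != ref_base]
            genotype.append(Mutation(pos, ref_base, alts[int(rng.integers(3))]))
        clones.append(tuple(genotype))
    return Library(ref=ref, clones=clones)


# ---------------------------------------------------------------------------
# FACS


@dataclass(frozen=True)
class Gate:
    """A FACS gate: a half-open interval [lo, hi) on log10 fluorescence."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"gate {self.name}: lo must be < hi")

    def contains(self, values: np.ndarray) -> np.ndarray:
        return (values >= self.lo) & (values < self.hi)


def default_gates(model: EffectModel, tail: float = 0.05) -> dict[str, Gate]:
    """Gates anchored on the wild-type control distributions.

    ``high`` spans the fluorescence range of unrepressed wild-type cells
    (from its lower ``tail`` percentile upward), ``low`` the range of
    repressed wild-type cells (up to its upper ``tail`` percentile), and
    ``all`` the whole support — mirroring gates drawn on the wild-type
    plasmid's FACS histograms.
    """
    z = float(stats.norm.ppf(tail))
    wt_on = model.basal_log_fluorescence
    wt_off = model.basal_log_fluorescence - model.srna_repression
    return {
        "high": Gate("high", wt_on + z * model.noise_sd, np.inf),
        "low": Gate("low", -np.inf, wt_off - z * model.noise_sd),
        "all": Gate("all", -np.inf, np.inf),
    }


@dataclass
class CellPool:
    """Cells of one culture or sorted pool: clone index and fluorescence per cell."""

    library: Library
    clone_indices: np.ndarray
    fluorescence: np.ndarray

    def __len__(self) -> int:
        return len(self.clone_indices)

    def single_mutant_counts(self) -> pd.Series:
        """Cells carrying exactly one mutation, tallied by mutation label."""
        ref = self.library.ref
        from collections import Counter

        tally: Counter = Counter()
        for ci in self.clone_indices:
            genotype = self.library.clones[int(ci)]
            if len(genotype) == 1:
                tally[format_label(genotype[0], ref)] += 1
        from .core import iter_labels

        return pd.Series(
            {label: tally.get(label, 0) for label in iter_labels(ref)},
            name="cells",
        )


def grow_and_measure(
    library: Library,
    plasmid: str,
    model: EffectModel,
    n_cells: int,
    rng: np.random.Generator,
) -> CellPool:
    """Grow a culture: draw cells uniformly from the clones, assign fluorescence."""
    idx = rng.integers(0, len(library), size=n_cells)
    shifts = np.empty(len(library))
    remains = np.empty(len(library))
    for i, genotype in enumerate(library.clones):
        shifts[i], remains[i] = model.genotype_params(genotype)
    values = model.basal_log_fluorescence + shifts[idx]
    if plasmid == "srna":
        values = values - model.srna_repression * remains[idx]
    if model.noise_sd > 0:
        values = values + rng.normal(0.0, model.noise_sd, size=n_cells)
    return CellPool(library=library, clone_indices=idx, fluorescence=values)


def sort_cells(
    cells: CellPool,
    gates: dict[str, Gate],
    target_cells_per_gate: int,
    rng: np.random.Generator,
) -> dict[str, CellPool]:
    """Gate the pool and subsample each gate without replacement to the target."""
    pools = {}
    for name, gate in gates.items():
        mask = gate.contains(cells.fluorescence)
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            warnings.warn(f"gate {name!r} is empty", stacklevel=2)
        elif len(idx) > target_cells_per_gate:
            idx = rng.choice(idx, size=target_cells_per_gate, replace=False)
            idx.sort()
        pools[name] = CellPool(
            library=cells.library,
            clone_indices=cells.clone_indices[idx],
            fluorescence=cells.fluorescence[idx],
        )
    return pools


# ---------------------------------------------------------------------------
# sequencing

MIN_MERGE_MARGIN = 30  # merged pairs need at least this much overlap downstream


def _quality_array(quality_profile, read_length: int) -> np.ndarray:
    if np.isscalar(quality_profile):
        q = np.full(read_length, int(quality_profile))
    else:
        q = np.asarray(quality_profile, dtype=int)
        if q.shape != (read_length,):
            raise ValueError("quality profile length must equal read_length")
    if q.min() < 0 or q.max() > 60:
        raise ValueError("phred profile must lie in [0, 60]")
    return q


def _apply_errors(seqs: np.ndarray, perr: np.ndarray, rng) -> np.ndarray:
    """Flip each base to a uniform random other base with its cycle's error rate."""
    flip = rng.random(seqs.shape) < perr[None, :]
    offset = rng.integers(1, 4, size=seqs.shape)
    return np.where(flip, (seqs + offset) % 4, seqs).astype(np.uint8)


def sequence_pool(
    pool: CellPool,
    read_length: int,
    quality_profile,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
    id_prefix: str = "read",
    error_free: bool = False,
):
    """Simulate one paired-end run over a sorted pool (one read pair per cell).

    Read 1 is the amplicon 5' prefix; read 2 the reverse complement of the 3'
    suffix.  Each base is flipped to a uniform random other base with the
    per-cycle probability 10**(-q/10) from ``quality_profile`` (a scalar
    phred or per-cycle array); ``error_free=True`` suppresses base-call
    errors entirely while keeping the quality strings.  With probability ``indel_rate`` a fragment
    suffers a one-base deletion or insertion before being read, to exercise
    the downstream exact-length filter.

    Returns ``(reads1, reads2)``: lists of ``(id, sequence, quality_string)``
    in pool order.
    """
    ref = pool.library.ref
    L = len(ref.sequence)
    if 2 * read_length < L + MIN_MERGE_MARGIN:
        raise ValueError(
            f"2*read_length ({2 * read_length}) must be >= amplicon length + "
            f"{MIN_MERGE_MARGIN} ({L + MIN_MERGE_MARGIN}) for merging to be possible"
        )
    q = _quality_array(quality_profile, read_length)
    perr = 10.0 ** (-q / 10.0)
    qual_str = (q + PHRED_OFFSET).astype(np.uint8).tobytes().decode("ascii")

    clone_seqs = pool.library.mutant_sequences()
    frags = clone_seqs[pool.clone_indices]
    n = frags.shape[0]

    indel_mask = (
        rng.random(n) < indel_rate if indel_rate > 0 else np.zeros(n, dtype=bool)
    )
    normal = ~indel_mask

    r1 = np.empty((n, read_length), dtype=np.uint8)
    r2 = np.empty((n, read_length), dtype=np.uint8)
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    if normal.any():
        sub = frags[normal]
        r1[normal] = sub[:, :read_length]
        r2[normal] = comp[sub[:, -read_length:][:, ::-1]]
    for i in np.nonzero(indel_mask)[0]:
        frag = frags[i]
        pos = int(rng.integers(L))
        if rng.random() < 0.5:  # deletion
            frag = np.delete(frag, pos)
        else:  # insertion of a random base
            frag = np.insert(frag, pos, rng.integers(4))
        r1[i] = frag[:read_length]
        r2[i] = revcomp(frag[-read_length:])

    if not error_free:
        r1 = _apply_errors(r1, perr, rng)
        r2 = _apply_errors(r2, perr, rng)

    reads1 = []
    reads2 = []
    for i in range(n):
        # indel-bearing fragments are flagged in the read id so that tests
        # (and curious users) can trace the length filter's decisions
        tag = ":indel" if indel_mask[i] else ""
        rid = f"{id_prefix}:{i}:clone{int(pool.clone_indices[i])}{tag}"
        reads1.append((rid, decode_seq(r1[i]), qual_str))
        reads2.append((rid, decode_seq(r2[i]), qual_str))
    return reads1, reads2


def write_fastq_pair(reads1, reads2, path1, path2) -> None:
    for reads, path in ((reads1, path1), (reads2, path2)):
        with open_maybe_gzip(path, "wt") as fh:
            fh.writelines(
                f"@{rid}\n{seq}\n+\n{qual}\n" for rid, seq, qual in reads
            )


# ---------------------------------------------------------------------------
# whole-experiment orchestration


@dataclass
class SamplePlan:
    """One sequenced sample of the simulated experiment."""

    plasmid: str
    gate: str
    replicate: int
    pool_size: int = 20_000

    @property
    def sample_id(self) -> str:
        return f"{self.plasmid}-{self.gate}-{self.replicate}"

    def meta(self) -> SampleMeta:
        return SampleMeta(self.sample_id, self.plasmid, self.gate, self.replicate)


def default_sample_plan(pool_size: int = 20_000) -> list[SamplePlan]:
    """Triplicates of srna x {high, all} — the canonical contrast design."""
    return [
        SamplePlan("srna", gate, rep, pool_size)
        for gate in ("high", "all")
        for rep in (1, 2, 3)
    ]


def simulate_experiment(
    outdir,
    ref: ReferenceAmplicon | None = None,
    model: EffectModel | None = None,
    plan: list[SamplePlan] | None = None,
    n_clones: int = 10_000,
    n_cells_per_replicate: int = 250_000,
    read_length: int = 100,
    quality_profile=30,
    indel_rate: float = 0.0,
    error_free: bool = False,
    mutation_count_distribution: dict[int, float] | None = None,
    region_weights: dict[str, float] | None = None,
    seed: int = None,
    gzip_fastq: bool = True,
) -> dict:
    """Simulate a full screen and write its FASTQs, sample sheet and truth tables.

    One clone library is shared by all samples (the transformant pool);
    each (plasmid, replicate) culture is grown and gated independently.
    Writes to ``outdir``: per-sample ``<id>_R1/R2.fastq[.gz]``,
    ``sample_sheet.tsv``, ``reference.fasta``, ``truth_clones.tsv`` (the
    aggregated library) and ``truth_single_counts.tsv`` (per-sample pool
    tallies of single-mutant cells — the matrix an error-free pipeline must
    reproduce exactly).  Returns a manifest dict of the written paths.
    """
    if seed is None:
        raise ValueError("a seed is required")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = ref or demo_reference()
    model = model or default_effect_model(ref)
    plan = plan if plan is not None else default_sample_plan()
    metas = [p.meta() for p in plan]
    from .core import validate_sample_metas

    validate_sample_metas(metas)

    root = np.random.SeedSequence(seed)
    lib_ss, *rest = root.spawn(1 + len(plan))
    library = generate_library(
        ref,
        n_clones,
        mutation_count_distribution=mutation_count_distribution,
        region_weights=region_weights,
        seed=np.random.default_rng(lib_ss),
    )
    gates = default_gates(model)

    ext = ".fastq.gz" if gzip_fastq else ".fastq"
    sheet_rows = []
    truth_cols = {}
    for p, ss in zip(plan, rest):
        rng = np.random.default_rng(ss)
        culture = grow_and_measure(library, p.plasmid, model, n_cells_per_replicate, rng)
        if p.gate == "unsorted":
            idx = np.arange(len(culture))
            if len(idx) > p.pool_size:
                idx = rng.choice(idx, size=p.pool_size, replace=False)
                idx.sort()
            pool = CellPool(library, culture.clone_indices[idx], culture.fluorescence[idx])
        else:
            pool = sort_cells(culture, {p.gate: gates[p.gate]}, p.pool_size, rng)[p.gate]
        reads1, reads2 = sequence_pool(
            pool,
            read_length,
            quality_profile,
            rng,
            indel_rate=indel_rate,
            id_prefix=p.sample_id,
            error_free=error_free,
        )
        f1 = outdir / f"{p.sample_id}_R1{ext}"
        f2 = outdir / f"{p.sample_id}_R2{ext}"
        write_fastq_pair(reads1, reads2, f1, f2)
        sheet_rows.append(
            {
                "sample_id": p.sample_id,
                "fastq1": f1.name,
                "fastq2": f2.name,
                "plasmid": p.plasmid,
                "gate": p.gate,
                "replicate": p.replicate,
            }
        )
        truth_cols[p.sample_id] = pool.single_mutant_counts()

    sheet = pd.DataFrame(sheet_rows)
    sheet_path = outdir / "sample_sheet.tsv"
    sheet.to_csv(sheet_path, sep="\t", index=False)

    fasta_path = outdir / "reference.fasta"
    fasta_path.write_text(f">{ref.name}\n{ref.sequence}\n")

    truth = pd.DataFrame(truth_cols)
    truth.index.name = "mutation"
    truth_path = outdir / "truth_single_counts.tsv"
    truth.to_csv(truth_path, sep="\t")
    clones_path = outdir / "truth_clones.tsv"
    library.table().to_csv(clones_path, sep="\t", index=False)

    return {
        "outdir": str(outdir),
        "sample_sheet": str(sheet_path),
        "reference": str(fasta_path),
        "truth_single_counts": str(truth_path),
        "truth_clones": str(clones_path),
        "samples": [r["sample_id"] for r in sheet_rows],
        "seed": int(seed),
    }
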