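"""Configuration, sample sheets and pipeline orchestration.

Every stage reads its inputs from disk and writes plain-text outputs, so any
stage can be rerun standalone on the previous stage's artifacts.  A manifest
(tool version, config hash, seed) accompanies each run; rerunning with
identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import cluster_samples, pattern_matrix, replicate_concordance
from .core import (
    MutationCountMatrix,
    ReferenceAmplicon,
    SampleMeta,
    validate_sample_metas,
)
from .enrich import MutationEnrichment
from .mutcall import (
    build_count_matrix,
    mutation_count_histogram,
    mutation_fractions,
    region_detection_stats,
)
from .readproc import process_sample


class ConfigError(ValueError):
    """A configuration problem, reported with the offending field path."""


@dataclass
class PipelineConfig:
    """Validated run configuration (see ``load_config`` for the YAML schema)."""

    reference_fasta: str
    mutated_region: tuple[int, int]
    aug_index: int
    quality_threshold: float = 30.0
    min_overlap: int = 30
    max_mismatch_fraction: float = 0.02
    contrast_condition: str | None = None
    contrast_baseline: str | None = None
    alpha: float = 0.05
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "complete"
    seed: int = 0

    def load_reference(self, base: Path | None = None) -> ReferenceAmplicon:
        path = Path(self.reference_fasta)
        if base is not None and not path.is_absolute():
            path = base / path
        if not path.exists():
            raise ConfigError(f"reference.fasta: file not found: {path}")
        return ReferenceAmplicon.from_fasta(path, self.mutated_region, self.aug_index)


def _require(cfg: dict, path: str, typ=None):
    node = cfg
    for part in path.split("."):
        if not isinstance(node, dict) or part not in node:
            raise ConfigError(f"{path}: required field missing")
        node = node[part]
    if typ is not None and not isinstance(node, typ):
        raise ConfigError(f"{path}: expected {typ}, got {type(node).__name__}")
    return node


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    Schema::

        reference: {fasta: <path>, mutated_region: [start, end], aug_index: <int>}
        trimming:  {quality_threshold: 30}          # optional
        merging:   {min_overlap: 30, max_mismatch_fraction: 0.02}   # optional
        analysis:  {contrast: {condition: "srna:high", baseline: "srna:all"},
                    alpha: 0.05}                    # optional
        clustering: {metric: euclidean, linkage: complete}          # optional
        seed: 0
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    cfg = yaml.safe_load(path.read_text()) or {}
    fasta = _require(cfg, "reference.fasta", str)
    region = _require(cfg, "reference.mutated_region", list)
    if len(region) != 2 or not all(isinstance(v, int) for v in region):
        raise ConfigError("reference.mutated_region: expected [start, end] integers")
    aug = _require(cfg, "reference.aug_index", int)

    trimming = cfg.get("trimming", {}) or {}
    merging = cfg.get("merging", {}) or {}
    analysis = cfg.get("analysis", {}) or {}
    clustering = cfg.get("clustering", {}) or {}
    contrast = analysis.get("contrast") or {}

    pc = PipelineConfig(
        reference_fasta=fasta,
        mutated_region=(region[0], region[1]),
        aug_index=aug,
        quality_threshold=float(trimming.get("quality_threshold", 30)),
        min_overlap=int(merging.get("min_overlap", 30)),
        max_mismatch_fraction=float(merging.get("max_mismatch_fraction", 0.02)),
        contrast_condition=contrast.get("condition"),
        contrast_baseline=contrast.get("baseline"),
        alpha=float(analysis.get("alpha", 0.05)),
        cluster_metric=str(clustering.get("metric", "euclidean")),
        cluster_linkage=str(clustering.get("linkage", "complete")),
        seed=int(cfg.get("seed", 0)),
    )
    if pc.quality_threshold < 0:
        raise ConfigError("trimming.quality_threshold: must be non-negative")
    if pc.min_overlap < 1:
        raise ConfigError("merging.min_overlap: must be >= 1")
    if not 0 <= pc.max_mismatch_fraction <= 1:
        raise ConfigError("merging.max_mismatch_fraction: must be in [0, 1]")
    if not 0 < pc.alpha < 1:
        raise ConfigError("analysis.alpha: must be in (0, 1)")
    if (pc.contrast_condition is None) != (pc.contrast_baseline is None):
        raise ConfigError("analysis.contrast: needs both condition and baseline")
    return pc


def read_sample_sheet(path) -> pd.DataFrame:
    """Read and validate a sample sheet TSV.

    Required columns: sample_id, fastq1, fastq2, plasmid, gate, replicate.
    FASTQ paths are resolved relative to the sheet's directory; missing files
    and duplicate (plasmid, gate, replicate) combinations are errors reported
    before any work starts.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"sample sheet not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = ["sample_id", "fastq1", "fastq2", "plasmid", "gate", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"sample sheet: missing columns {missing}")
    metas = [
        SampleMeta(r.sample_id, r.plasmid, r.gate, int(r.replicate))
        for r in df.itertuples()
    ]
    validate_sample_metas(metas)
    base = path.parent
    for col in ("fastq1", "fastq2"):
        df[col] = [
            str(p if Path(p).is_absolute() else base / p) for p in df[col]
        ]
        absent = [p for p in df[col] if not Path(p).exists()]
        if absent:
            raise ConfigError(f"sample sheet: missing FASTQ files {absent}")
    return df


def sheet_metas(sheet: pd.DataFrame) -> list[SampleMeta]:
    return [
        SampleMeta(r.sample_id, r.plasmid, r.gate, int(r.replicate))
        for r in sheet.itertuples()
    ]


# ---------------------------------------------------------------------------
# stages


def run_process(config: PipelineConfig, sheet: pd.DataFrame, ref, outdir: Path) -> dict:
    """Trim/merge/length-filter every sample; write kept reads + QC JSONs.

    Kept reads are written as one plain-text file of sequences per sample
    (``<id>.reads.txt``), which the counting stage consumes.
    """
    from .core import decode_seq

    outdir.mkdir(parents=True, exist_ok=True)
    qc_all = {}
    for r in sheet.itertuples():
        kept, qc = process_sample(
            r.fastq1,
            r.fastq2,
            expected_length=len(ref.sequence),
            q_threshold=config.quality_threshold,
            min_overlap=config.min_overlap,
            max_mismatch_fraction=config.max_mismatch_fraction,
        )
        reads_path = outdir / f"{r.sample_id}.reads.txt"
        with open(reads_path, "w") as fh:
            fh.writelines(decode_seq(row) + "\n" for row in kept)
        qc_all[r.sample_id] = qc.as_dict()
    (outdir / "readproc_qc.json").write_text(json.dumps(qc_all, indent=2) + "\n")
    return qc_all


def run_count(config: PipelineConfig, sheet: pd.DataFrame, ref, outdir: Path):
    """Build the single-mutation count matrix from the processed reads."""
    from .core import encode_seq

    metas = sheet_metas(sheet)
    sample_reads = {}
    for m in metas:
        reads_path = outdir / f"{m.sample_id}.reads.txt"
        if not reads_path.exists():
            raise ConfigError(f"processed reads missing for {m.sample_id}: {reads_path}")
        seqs = [line.strip() for line in open(reads_path) if line.strip()]
        sample_reads[m.sample_id] = (
            np.stack([encode_seq(s) for s in seqs])
            if seqs
            else np.empty((0, len(ref.sequence)), dtype=np.uint8)
        )
    matrix = build_count_matrix(sample_reads, ref, metas)
    matrix.to_tsv(outdir / "count_matrix.tsv")

    qc = {}
    for m in metas:
        hist = mutation_count_histogram(sample_reads[m.sample_id], ref)
        qc[m.sample_id] = {
            "histogram_counts": hist["count"].to_dict(),
            "histogram_fractions": {
                k: (None if pd.isna(v) else v) for k, v in hist["fraction"].items()
            },
        }
    stats_df = region_detection_stats(matrix)
    for sid in stats_df.index:
        qc[sid]["region"] = stats_df.loc[sid].to_dict()
    (outdir / "mutcall_qc.json").write_text(json.dumps(qc, indent=2) + "\n")
    return matrix


def run_enrich(config: PipelineConfig, matrix: MutationCountMatrix, outdir: Path):
    """Fit the configured contrast and write the enrichment table."""
    if config.contrast_condition is None:
        raise ConfigError("analysis.contrast: required for the enrichment stage")
    model = MutationEnrichment.from_count_matrix(
        matrix, config.contrast_condition, config.contrast_baseline
    )
    results = model.fit(alpha=config.alpha)
    results.to_tsv(outdir / "enrichment.tsv")
    return results

def run_cluster(config: PipelineConfig, matrix: MutationCountMatrix, sheet, outdir: Path):
    """Standardize fractions, cluster samples, export Newick + column order."""
    fracs = mutation_fractions(matrix)
    pattern = pattern_matrix(fracs)
    pattern.to_csv(outdir / "pattern_matrix.tsv", sep="\t", index_label="mutation")
    dendro = cluster_samples(
        pattern, metric=config.cluster_metric, linkage=config.cluster_linkage
    )
    (outdir / "samples.nwk").write_text(dendro.to_newick() + "\n")
    (outdir / "column_order.txt").write_text("\n".join(dendro.leaf_order()) + "\n")
    score = replicate_concordance(dendro, sheet)
    (outdir / "cluster_qc.json").write_text(
        json.dumps({"replicate_concordance": score}, indent=2) + "\n"
    )
    return dendro, score


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config_path, sample_sheet_path, outdir) -> dict:
    """Full run: process -> count -> enrich (if configured) -> cluster.

    Returns the manifest, which is also written to ``manifest.json``.
    """
    outdir = Path(outdir)
    config = load_config(config_path)
    sheet = read_sample_sheet(sample_sheet_path)
    ref = config.load_reference(base=Path(config_path).parent)

    outdir.mkdir(parents=True, exist_ok=True)
    run_process(config, sheet, ref, outdir)
    matrix = run_count(config, sheet, ref, outdir)
    if config.contrast_condition is not None:
        run_enrich(config, matrix, outdir)
    _, concordance = run_cluster(config, matrix, sheet, outdir)

    manifest = {
        "tool": "sortmut",
        "version": __version__,
        "config_sha256": _sha256(config_path),
        "sample_sheet_sha256": _sha256(sample_sheet_path),
        "seed": config.seed,
        "n_samples": int(len(sheet)),
        "replicate_concordance": concordance,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
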