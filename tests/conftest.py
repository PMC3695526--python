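"""Shared fixtures: the demo reference and two simulated experiments.

The "default scenario" experiment is simulated once per session at realistic
depth and reused by the end-to-end tests; the error-free experiment backs
the exactness invariants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sortmut.core import MutationCountMatrix
from sortmut.mutcall import build_count_matrix
from sortmut.pipeline import read_sample_sheet, sheet_metas
from sortmut.readproc import process_sample
from sortmut.simulate import (
    SamplePlan,
    default_sample_plan,
    demo_reference,
    simulate_experiment,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref():
    return demo_reference()


@dataclass
class Experiment:
    manifest: dict
    sheet: pd.DataFrame
    reads: dict
    qc: dict
    matrix: MutationCountMatrix
    truth: pd.DataFrame


def _run_experiment(outdir, **kwargs) -> Experiment:
    manifest = simulate_experiment(outdir, **kwargs)
    sheet = read_sample_sheet(manifest["sample_sheet"])
    ref = demo_reference()
    reads, qc = {}, {}
    for r in sheet.itertuples():
        kept, sample_qc = process_sample(
            r.fastq1, r.fastq2, expected_length=len(ref.sequence)
        )
        reads[r.sample_id] = kept
        qc[r.sample_id] = sample_qc.as_dict()
    matrix = build_count_matrix(reads, ref, sheet_metas(sheet))
    truth = pd.read_csv(manifest["truth_single_counts"], sep="\t", index_col="mutation")
    return Experiment(manifest, sheet, reads, qc, matrix, truth)


@pytest.fixture(scope="session")
def experiment(tmp_path_factory) -> Experiment:
    """Default scenario at realistic depth: srna x {high, all} triplicates for
    the enrichment contrast, plus srna x {low, unsorted} and control x high
    triplicates for clustering and the alternative baseline."""
    plan = (
        [SamplePlan("srna", g, r, 40_000) for g in ("high", "all") for r in (1, 2, 3)]
        + [SamplePlan("srna", "low", r, 20_000) for r in (1, 2, 3)]
        + [SamplePlan("control", "high", r, 20_000) for r in (1, 2, 3)]
        + [SamplePlan("srna", "unsorted", r, 20_000) for r in (1, 2, 3)]
    )
    return _run_experiment(
        tmp_path_factory.mktemp("scenario"),
        plan=plan,
        n_clones=10_000,
        n_cells_per_replicate=250_000,
        seed=2024,
    )


@pytest.fixture(scope="session")
def error_free_experiment(tmp_path_factory) -> Experiment:
    """Small error-free run: the count matrix must equal the truth exactly."""
    return _run_experiment(
        tmp_path_factory.mktemp("errorfree"),
        plan=default_sample_plan(3000),
        n_clones=2000,
        n_cells_per_replicate=30_000,
        seed=11,
        error_free=True,
    )
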