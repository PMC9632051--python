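"""Shared fixtures: simulated datasets and assembled pipelines.

The heavyweight datasets (the 50-kb noisy / chimeric simulations) are
session-scoped so every test that needs them shares one overlap run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pytest

from longasm.io_formats import Read, revcomp
from longasm.simulate import (
    ReadTruth,
    SimConfig,
    simulate_genome,
    simulate_reads,
    true_overlaps,
)
from longasm.overlap import OverlapParams, overlap_all
from longasm.trim import TrimResult, trim_all
from longasm.layout import layout_all
from longasm.consensus import Contig, consensus_all


@dataclass
class Dataset:
    """A simulated dataset plus every pipeline product computed so far."""

    config: SimConfig
    genome: str
    reads: List[Read]
    truths: List[ReadTruth]
    overlaps: list
    trim_results: List[TrimResult]
    clipped: list
    layout: object
    contigs: List[Contig]

    @property
    def kept(self) -> Dict[int, Optional[Tuple[int, int]]]:
        return {t.read_id: t.kept for t in self.trim_results}


def _run_dataset(config: SimConfig) -> Dataset:
    genome = simulate_genome(config)
    reads, truths = simulate_reads(genome, config)
    overlaps = overlap_all(reads)
    trim_results, clipped = trim_all(reads, overlaps)
    kept = {t.read_id: t.kept for t in trim_results}
    layout = layout_all(reads, clipped, kept)
    contigs = consensus_all(layout, reads)
    return Dataset(config, genome, reads, truths, overlaps,
                   trim_results, clipped, layout, contigs)


NOISY_ERRORS = dict(sub_rate=0.02, ins_rate=0.06, del_rate=0.04,
                    homopolymer_noise=0.1)


@pytest.fixture(scope="session")
def clean_dataset() -> Dataset:
    """30x error-free 5-kb reads of a 50-kb repeat-free genome."""
    return _run_dataset(SimConfig(
        genome_length=50_000, coverage=30, read_length_mean=5_000, seed=11,
    ))


@pytest.fixture(scope="session")
def noisy_dataset() -> Dataset:
    """30x 12%-error reads (6% ins / 4% del / 2% sub, homopolymer 0.1)."""
    return _run_dataset(SimConfig(
        genome_length=50_000, coverage=30, read_length_mean=5_000, seed=7,
        **NOISY_ERRORS,
    ))


@pytest.fixture(scope="session")
def chimera_dataset() -> Dataset:
    """The noisy conditions plus 5% chimeric junction reads."""
    return _run_dataset(SimConfig(
        genome_length=50_000, coverage=30, read_length_mean=5_000, seed=13,
        chimera_rate=0.05, **NOISY_ERRORS,
    ))


def align_identity(seq: str, reference: str) -> Tuple[float, Tuple[int, int]]:
    """Best identity of seq (either orientation) inside reference (edlib)."""
    import edlib

    best = None
    for s in (seq, revcomp(seq)):
        res = edlib.align(s, reference, mode="HW", task="locations")
        if best is None or res["editDistance"] < best["editDistance"]:
            best = res
    loc = best["locations"][0]
    return 1.0 - best["editDistance"] / len(seq), (loc[0], loc[1] + 1)
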