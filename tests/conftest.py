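"""Shared fixtures: a small toy locus and clean simulated libraries."""

import dataclasses

import pytest

from netseq_rdna import (
    StrainParams,
    generate_template,
    preprocess_reads,
    simulate_reads,
    track_from_reads,
)

#: Small unit (sum = 300) keeping per-module tests fast.
SMALL_REGIONS = (40, 60, 30, 30, 30, 80, 30)


@pytest.fixture(scope="session")
def locus_small():
    return generate_template(SMALL_REGIONS, seed=7)


@pytest.fixture(scope="session")
def locus_default():
    return generate_template(seed=11)


@pytest.fixture(scope="session")
def clean_params():
    """No duplicates, no off-target reads, linker always present."""
    return StrainParams(
        termination_prob=0.0,
        pause_gc_weight=0.0,
        duplicate_rate=0.0,
        offtarget_frac=0.0,
        linker_prob=1.0,
    )


@pytest.fixture(scope="session")
def wt_tracks_small(locus_small, clean_params):
    params = dataclasses.replace(clean_params, termination_prob=0.0005)
    tracks = []
    for rep, seed in enumerate((101, 102, 103), start=1):
        reads, _ = simulate_reads(locus_small, params, 8000, seed=seed)
        clean, _ = preprocess_reads(reads)
        tracks.append(track_from_reads(clean, locus_small, "WT", rep))
    return tracks
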