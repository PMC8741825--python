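"""Shared fixtures: seeded synthetic screens reused across the suite."""

import pytest

from funscreen.pipeline import analyze, make_fixture
from funscreen.simulate import DRAI

#: fixed seeds for the screen-scale benchmark runs
SCREEN_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def screen_runs():
    """Screen-scale fixtures (4 replicates, ~1000 inserts, 20+20 planted
    hits at the measured effect sizes) analysed end to end, per seed."""
    runs = {}
    for seed in SCREEN_SEEDS:
        fx = make_fixture("screen", seed=seed)
        runs[seed] = (fx, analyze(fx.alignments, fx.genome))
    return runs


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """Tiny smoke-scale fixture with FASTQ output, written to disk."""
    out = tmp_path_factory.mktemp("tinyfx")
    fx = make_fixture("tiny", seed=7, outdir=out, write_fastq=True)
    return fx, out


@pytest.fixture(scope="session")
def orient_fixture():
    """Single-enzyme, single-orientation library: truth fragment intervals
    are disjoint, so per-insert orientation recovery is well defined."""
    return make_fixture("tiny", seed=9, orientations="single", enzymes=(DRAI,))
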