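"""Shared fixtures: a guarded simulated dataset and dirty-sequence maker."""

from __future__ import annotations

import numpy as np
import pytest

from ssrkit.mining import ThresholdSet
from ssrkit.simulate import SimulationSpec, random_plants, simulate_genome


def make_dirty_sequence(rng: np.random.Generator, length: int,
                        n_tracts: int = 30, n_rate: float = 0.001) -> str:
    """A repeat-enriched random sequence for fuzzing the miner.

    Random background salted with repeat tracts whose counts straddle
    the detection thresholds (some below, some above), plus sparse N
    bases.  No guarding — overlaps and borderline runs are welcome.
    """
    thresholds = ThresholdSet().min_repeats
    bases = "ACGT"
    arr = list(rng.choice(list(bases), size=length))
    for _ in range(n_tracts):
        k = int(rng.integers(1, 7))
        unit = "".join(bases[int(b)] for b in rng.integers(0, 4, size=k))
        count = max(2, thresholds[k] + int(rng.integers(-3, 4)))
        tract = unit * count
        if len(tract) >= length:
            continue
        pos = int(rng.integers(0, length - len(tract)))
        arr[pos:pos + len(tract)] = list(tract)
    for pos in np.flatnonzero(rng.random(length) < n_rate):
        arr[int(pos)] = "N"
    return "".join(arr)


@pytest.fixture(scope="session")
def guarded_dataset():
    """A small guarded simulation reused across test modules."""
    spec = SimulationSpec(
        seed=11,
        n_scaffolds=3,
        scaffold_length=30_000,
        ssr_plants=random_plants(24, seed=3),
    )
    return spec, simulate_genome(spec)
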