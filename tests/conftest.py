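import numpy as np
import pytest

from cbsdetect import generate_genome, mutate_genome, simulate_reads


@pytest.fixture(scope="session")
def small_genome():
    """10 kb random genome used by unit tests."""
    return generate_genome(10_000, 0.5, seed=42, id="ref")


@pytest.fixture(scope="session")
def big_genome():
    """100 kb genome for calibration-grade checks."""
    return generate_genome(100_000, 0.5, seed=7, id="bigref")


def brute_force_depth(alignments, length):
    """Independent per-position membership count (oracle for depth_profile)."""
    depth = np.zeros(length, dtype=int)
    for aln in alignments:
        for pos in range(aln.ref_start, aln.ref_end):
            depth[pos] += 1
    return depth
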