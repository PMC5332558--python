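import numpy as np
import pytest

from polwave.annotation import TranscriptModel
from polwave.coverage import GeneWindowCoverage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_plus_transcript():
    # 100 kb gene on +, first/internal/last exons
    exons = (
        (50_000, 50_300),
        (60_000, 60_150),
        (80_000, 80_150),
        (149_000, 150_000),
    )
    return TranscriptModel("G1", "G1.t1", "chrT", "+", 50_000, 150_000, exons)


@pytest.fixture
def simple_minus_transcript():
    exons = ((50_000, 51_000), (120_000, 120_150), (149_700, 150_000))
    return TranscriptModel("G2", "G2.t1", "chrT", "-", 50_000, 150_000, exons)


def make_window(depth, gene_id="G", sample=None):
    """Wrap a raw downstream depth vector (offset 0 = TSS) as a window."""
    return GeneWindowCoverage(gene_id=gene_id, depth=np.asarray(depth, dtype=float),
                              sample=sample)


def brute_force_front(depth, mask, threshold, gap):
    """Sequential-scan reference for the island caller.

    Walks the window base by base, skipping masked positions; tracks the
    last above-threshold base and the current run of consecutive
    below-threshold (unmasked) bases, declaring a halt when the run
    reaches ``gap`` after at least one island.
    Returns (front or None, reached_window_end).
    """
    last_above = None
    run = 0
    for i in range(len(depth)):
        if mask is not None and mask[i]:
            continue
        if depth[i] >= threshold:
            last_above = i
            run = 0
        elif last_above is not None:
            run += 1
            if run >= gap:
                return last_above, False
    return last_above, True
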