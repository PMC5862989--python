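import numpy as np
import pytest

import scwga_eval as sw


@pytest.fixture(scope="session")
def small_genome():
    """Two-chromosome 100 kb genome with a pronounced GC landscape."""
    return sw.generate_genome(2, [60_000, 40_000],
                              sw.GCLandscape(mean=0.42, amplitude=0.12,
                                             correlation_length=2000),
                              seed=11)


@pytest.fixture(scope="session")
def small_windows(small_genome):
    track = sw.full_mappability(small_genome, read_length=50, step=5)
    return sw.build_windows(track, small_genome, reads_per_window=100,
                            overlap_reads=20, read_length=50, step=5)


@pytest.fixture(scope="session")
def diploid_truth():
    return sw.TruthProfile(line_id="NEG", segments=(), label="negative")


@pytest.fixture(scope="session")
def flat_kit():
    return sw.KitProfile(name="flat", gc_efficiency=sw.flat_efficiency(),
                         dispersion_single=0.0, dispersion_multi=0.0,
                         duplication_rate=0.0, error_rates=(0.0, 0.0, 0.0))


def gc_only_windows(gc, **kw):
    """Abstract window set from a GC vector (no concrete sequence)."""
    return sw.WindowSet.from_gc(np.asarray(gc, dtype=float), **kw)
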