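"""Generate a synthetic reference and build equal-mappability windows.

Builds a two-chromosome 100 kb genome with a smooth GC landscape, tiles it
into 50 bp simulated reads (every 5 bp), groups them into windows of 100
reads sharing 20 with their neighbour, and annotates per-window GC.
"""

import numpy as np

import scwga_eval as sw

genome = sw.generate_genome(2, [60_000, 40_000],
                            sw.GCLandscape(mean=0.42, amplitude=0.12,
                                           correlation_length=2000),
                            seed=11)
track = sw.full_mappability(genome, read_length=50, step=5)
windows = sw.build_windows(track, genome, reads_per_window=100,
                           overlap_reads=20, read_length=50, step=5)

print(f"genome: {genome.lengths}")
print(f"windows: {windows.n_windows} "
      f"({int(windows.flagged.sum())} flagged short)")
print(f"window GC range: {np.nanmin(windows.gc):.3f}-{np.nanmax(windows.gc):.3f}")
print(windows.to_dataframe().head(5).to_string(index=False))
# Each row is one window: its genomic span, the start of its last
# simulated read, its GC fraction and its simulated-read budget.
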