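"""Aggregate raw contact events into a snapshot series.

Builds a tiny SocioPatterns-style "t i j" event list in memory (timestamps in
seconds, 20-s resolution), windows it into 10-minute snapshots, and prints the
per-window counts the inference consumes.  The same functions read real tij
files, gzipped or plain, via densiswitch.read_contacts(path).
"""

from densiswitch import ContactEvent, WindowingSpec, build_snapshot_series, density_report
import numpy as np

raw = """\
0    alice bob
20   alice bob
40   bob   carol
600  alice bob
640  carol dave
660  alice dave
1260 bob   carol
"""

events = [ContactEvent(int(t), i, j)
          for t, i, j in (line.split() for line in raw.strip().splitlines())]

series = build_snapshot_series(events, WindowingSpec(width=600, origin=0))
print("window_start   N   M")
for t, n, m in zip(series.window_start, series.n_active, series.m_edges):
    print(f"{t:12.0f} {n:3d} {m:3d}")
print("Repeated contacts of the same pair inside a window collapse to one"
      " edge;\nN counts only nodes with at least one contact in the window.")

rep = density_report(series, np.array(["gray"] * len(series), dtype=object))
print("\nobserved density 2M/(N(N-1)) per window:",
      np.round(rep["density"].to_numpy(), 3))
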