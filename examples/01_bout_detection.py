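"""Call sleep bouts from a beam-break count series.

A fly is scored asleep after 5 consecutive minutes without a beam crossing.
This example builds a two-hour trace by hand and prints the called bouts.
"""

import numpy as np

from damsleep import ActivityTrace, detect_sleep_bouts

# 120 one-minute bins: activity, a 20-min nap, a 3-min pause (too short to
# be sleep), then a 40-min sleep bout
counts = np.array([2] * 30 + [0] * 20 + [3] * 12 + [0] * 3 + [1] * 15 + [0] * 40)
trace = ActivityTrace(fly_id="demo", monitor_channel=1, t0_zt=0.0, bin_width=1,
                      counts=counts, light=np.ones(len(counts), dtype=bool))

bouts = detect_sleep_bouts(trace)
print(f"{len(bouts)} sleep bouts called:")
for b in bouts:
    print(f"  ZT {b.start_zt:5.0f}-{b.end_zt:5.0f} min  ({b.duration:.0f} min)")
print("The 3-minute pause at ZT 62 is wake: it never reaches the 5-min rule.")
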