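"""The six per-window sleep parameters for one simulated fly.

Simulates a control female under a 12:12 light-dark cycle and prints total
sleep, latency to sleep after lights-off, activity index (counts per waking
minute), mean and maximum sleep-episode length, and episode count for the
day (ZT 0-12) and night (ZT 12-24) windows.
"""

from damsleep import (
    FlyModelConfig,
    compute_sleep_parameters,
    detect_sleep_bouts,
    make_schedule,
    simulate_fly,
)

ld = make_schedule("LD")
trace, truth = simulate_fly(FlyModelConfig(seed=42), ld, fly_seed=42)
bouts = detect_sleep_bouts(trace)

for label, window in (("day   ZT 0-12", (0.0, 720.0)), ("night ZT 12-24", (720.0, 1440.0))):
    p = compute_sleep_parameters(trace, bouts, window, ld)
    lat = f"{p.sleep_latency:6.0f}" + ("*" if p.latency_censored else " ")
    print(f"{label}: total {p.total_sleep:5.0f} min | latency {lat} min | "
          f"activity {p.activity_index:5.2f}/min | mean {p.mean_sleep:5.1f} | "
          f"max {p.max_sleep:4.0f} | episodes {p.sleep_frequency:2d}")
print("(* latency censored at the window length: no sleep after lights-off there.")
print(" Flies sleep more, and in longer episodes, during the dark phase.)")
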