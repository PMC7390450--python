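"""Synthetic fly-activity generator with ground truth.

The study's raw recordings are not deposited, so every pipeline stage is
exercised against simulated flies instead.  Each fly is an
alternating-renewal process: wake and sleep bouts alternate, with bout
durations drawn from a phase-appropriate distribution (phase = photoperiod
light status at bout onset), rounded to whole minutes so ground-truth bouts
tile the 1-minute analysis grid exactly.  During wake, each minute's
beam-break count is Poisson with the configured waking rate; during sleep,
counts are zero.  Night-time deprivation stimuli (shakes or light pulses)
terminate an ongoing sleep bout with probability ``arousal_prob``; each
night's first sleep onset after lights-off is delayed by ``latency_shift``.
Drug/genotype effects enter as multipliers on the sleep-bout mean, the
waking rate and the latency shift, applied before sampling.

Defaults describe a healthy control female: waking rate 2.5 counts/min,
sleep-bout means 15 min (lit) / 35 min (dark), wake-bout means 30 / 15 min,
latency shift 20 min.  Ground-truth bout sequences, per-phase realized
means and realized latencies are returned alongside each trace so recovery
tests can compare pipeline output against censoring-adjusted truth (bouts
shorter than the 5-min detection threshold are legitimate in simulation;
the truth side, never the detector, applies the censor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .dam_io import N_CHANNELS, ActivityTrace, write_dam_file
from .errors import ConfigurationError, EmptyInputError
from .protocol import MINUTES_PER_DAY, NOMINAL_LIGHTS_OFF_ZT, ProtocolSchedule, light_vector
from .sleep_metrics import MIN_SLEEP_MIN

VEHICLE = "vehicle"


@dataclass(frozen=True)
class TreatmentEffect:
    """Multiplicative effect of one treatment on the fly model."""

    sleep_bout: float = 1.0   # scales sleep-bout means (both phases)
    wake_rate: float = 1.0    # scales the Poisson waking count rate
    latency: float = 1.0      # scales the post-lights-off latency shift


@dataclass
class FlyModelConfig:
    """Parameters of the alternating-renewal fly model.

    ``sleep_bout_mean`` / ``wake_bout_mean`` are minutes, keyed by phase
    (``"light"`` / ``"dark"``).  ``effects`` maps treatment names to
    :class:`TreatmentEffect`; a ``vehicle`` arm with identity effect is
    always implied.  ``n_flies`` is the cohort size per arm.
    """

    wake_rate: float = 2.5
    sleep_bout_mean: dict = field(default_factory=lambda: {"light": 15.0, "dark": 35.0})
    wake_bout_mean: dict = field(default_factory=lambda: {"light": 30.0, "dark": 15.0})
    bout_distribution: str = "exponential"
    gamma_shape: float = 2.0
    latency_shift: float = 20.0
    arousal_prob: float = 0.9
    effects: dict = field(default_factory=dict)
    n_flies: int = 16
    n_days: int = 1
    seed: int = 0
    sex: str = "female"
    genotype: str = "control"

    def __post_init__(self) -> None:
        for d in (self.sleep_bout_mean, self.wake_bout_mean):
            for phase in ("light", "dark"):
                if phase not in d or d[phase] <= 0:
                    raise ConfigurationError(f"bout mean for phase {phase!r} must be > 0")
        if self.wake_rate <= 0:
            raise ConfigurationError("wake_rate must be > 0")
        if not (0 <= self.arousal_prob <= 1):
            raise ConfigurationError("arousal_prob must lie in [0, 1]")
        if self.bout_distribution not in ("exponential", "gamma"):
            raise ConfigurationError("bout_distribution must be 'exponential' or 'gamma'")
        if self.bout_distribution == "gamma" and self.gamma_shape <= 0:
            raise ConfigurationError("gamma_shape must be > 0")
        if self.latency_shift < 0:
            raise ConfigurationError("latency_shift must be >= 0")
        if self.n_flies < 1 or self.n_days < 1:
            raise ConfigurationError("n_flies and n_days must be >= 1")

    def arms(self) -> list[str]:
        return [VEHICLE] + [a for a in self.effects if a != VEHICLE]

    def effect_for(self, treatment: str | None) -> TreatmentEffect:
        if treatment in (None, VEHICLE):
            return TreatmentEffect()
        if treatment not in self.effects:
            raise ConfigurationError(f"unknown treatment {treatment!r}")
        return self.effects[treatment]


@dataclass
class GroundTruth:
    """Realized bout sequence and derived truths for one simulated fly."""

    fly_id: str
    treatment: str
    bouts: list  # (state, start_zt, end_zt) tuples, tiling [0, n_days*1440)
    n_days: int

    def sleep_bouts(self) -> list[tuple[float, float]]:
        return [(s, e) for st, s, e in self.bouts if st == "sleep"]

    def realized_phase_means(self, schedule: ProtocolSchedule) -> dict:
        """Mean realized sleep-bout duration per onset phase."""
        out = {}
        for phase in ("light", "dark"):
            durs = [e - s for s, e in self.sleep_bouts()
                    if schedule.is_light(s) == (phase == "light")]
            out[phase] = float(np.mean(durs)) if durs else float("nan")
        return out

    def realized_latency(self, day: int) -> float | None:
        """Minutes from nominal lights-off to the night's first sleep onset."""
        loff = day * MINUTES_PER_DAY + NOMINAL_LIGHTS_OFF_ZT
        onsets = [s for s, _e in self.sleep_bouts() if s >= loff]
        return (onsets[0] - loff) if onsets else None

    def censored_sleep_segments(self, window: tuple[float, float],
                                min_duration: float = MIN_SLEEP_MIN
                                ) -> list[tuple[float, float]]:
        """Truth sleep bouts surviving the detection censor, clipped to a window.

        A bout must reach ``min_duration`` in full before clipping (the
        detector censors on the uninterrupted run, then windows clip it).
        """
        out = []
        lo, hi = window
        for s, e in self.sleep_bouts():
            if e - s < min_duration:
                continue
            cs, ce = max(s, lo), min(e, hi)
            if ce > cs:
                out.append((cs, ce))
        return out

    def censored_mean_sleep(self, window: tuple[float, float],
                            min_duration: float = MIN_SLEEP_MIN) -> float:
        segs = self.censored_sleep_segments(window, min_duration)
        return float(np.mean([e - s for s, e in segs])) if segs else 0.0


def _draw_duration(rng: np.random.Generator, mean: float, config: FlyModelConfig) -> int:
    if config.bout_distribution == "exponential":
        x = rng.exponential(mean)
    else:
        x = rng.gamma(config.gamma_shape, mean / config.gamma_shape)
    return max(1, int(round(x)))


def simulate_fly(config: FlyModelConfig, schedule: ProtocolSchedule, fly_seed,
                 fly_id: str = "fly", channel: int = 1,
                 treatment: str | None = None) -> tuple[ActivityTrace, GroundTruth]:
    """Simulate one fly under a schedule; returns its trace and ground truth.

    ``fly_seed`` may be an int or a :class:`numpy.random.SeedSequence`
    child; identical (config, schedule, seed) give bit-identical output.
    """
    eff = config.effect_for(treatment)
    sleep_mean = {ph: m * eff.sleep_bout for ph, m in config.sleep_bout_mean.items()}
    lam = config.wake_rate * eff.wake_rate
    lshift = int(round(config.latency_shift * eff.latency))

    rng = np.random.default_rng(fly_seed)
    total = config.n_days * MINUTES_PER_DAY
    stim_onsets = np.asarray(schedule.stimulus_onsets_between(0, total), dtype=float)

    bouts: list[tuple[str, float, float]] = []
    t = 0
    state = "wake"  # lights-on at ZT0 finds the fly awake
    nights_shifted: set[int] = set()
    while t < total:
        phase = "light" if schedule.is_light(t) else "dark"
        if state == "wake":
            d = _draw_duration(rng, config.wake_bout_mean[phase], config)
            s = t + d
            day = int(s // MINUTES_PER_DAY)
            loff = day * MINUTES_PER_DAY + NOMINAL_LIGHTS_OFF_ZT
            if lshift > 0 and s >= loff and day not in nights_shifted:
                s += lshift
                nights_shifted.add(day)
            s = min(s, total)
            bouts.append(("wake", float(t), float(s)))
            t = s
            state = "sleep"
        else:
            d = _draw_duration(rng, sleep_mean[phase], config)
            e = t + d
            if config.arousal_prob > 0 and len(stim_onsets):
                # stimuli strictly inside the bout can wake the fly; one
                # landing exactly on the onset minute does not prevent sleep
                lo = np.searchsorted(stim_onsets, t, side="right")
                hi = np.searchsorted(stim_onsets, e, side="left")
                for onset in stim_onsets[lo:hi]:
                    if rng.random() < config.arousal_prob:
                        e = onset
                        break
            # stimuli lie strictly inside (t, e) and durations are >= 1 min,
            # so e > t always holds and bouts never degenerate
            e = min(e, total)
            bouts.append(("sleep", float(t), float(e)))
            t = e
            state = "wake"

    truth = GroundTruth(fly_id=fly_id, treatment=treatment or VEHICLE,
                        bouts=bouts, n_days=config.n_days)

    asleep = np.zeros(total, dtype=bool)
    for s, e in truth.sleep_bouts():
        asleep[int(s): int(e)] = True
    counts = rng.poisson(lam, total)
    counts[asleep] = 0
    trace = ActivityTrace(
        fly_id=fly_id,
        monitor_channel=channel,
        t0_zt=0.0,
        bin_width=1,
        counts=counts,
        light=np.asarray(light_vector(schedule, 0.0, total, 1), dtype=bool),
        meta={"sex": config.sex, "genotype": config.genotype,
              "treatment": treatment or VEHICLE, "protocol": schedule.name},
    )
    return trace, truth


@dataclass
class CohortResult:
    """In-memory cohort plus any files written to disk."""

    traces: list
    truths: list
    design: pd.DataFrame
    monitor_paths: list = field(default_factory=list)
    design_path: Path | None = None
    truth_path: Path | None = None


def simulate_cohort(config: FlyModelConfig, schedule: ProtocolSchedule,
                    outdir: "Path | str | None" = None,
                    basename: str = "monitor") -> CohortResult:
    """Simulate ``n_flies`` per arm (vehicle + each configured treatment).

    With ``outdir`` set, writes DAM monitor files (splitting across files
    beyond 32 channels, never truncating), a design CSV and a ground-truth
    bout CSV; everything is deterministic in ``config.seed``.
    """
    arms = config.arms()
    total_flies = len(arms) * config.n_flies
    children = np.random.SeedSequence(config.seed).spawn(total_flies)

    traces, truths, design_rows = [], [], []
    idx = 0
    for arm in arms:
        for i in range(config.n_flies):
            monitor_no = idx // N_CHANNELS
            channel = idx % N_CHANNELS + 1
            fly_id = f"{arm}_{i + 1:03d}"
            tr, gt = simulate_fly(config, schedule, children[idx], fly_id=fly_id,
                                  channel=channel, treatment=arm)
            traces.append(tr)
            truths.append(gt)
            design_rows.append({
                "monitor_file": f"{basename}{monitor_no + 1}.txt",
                "channel": channel,
                "fly_id": fly_id,
                "sex": config.sex,
                "genotype": config.genotype,
                "treatment": arm,
                "protocol": schedule.name,
            })
            idx += 1
    design = pd.DataFrame(design_rows)

    result = CohortResult(traces=traces, truths=truths, design=design)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        n_monitors = math.ceil(total_flies / N_CHANNELS)
        for m in range(n_monitors):
            batch = traces[m * N_CHANNELS: (m + 1) * N_CHANNELS]
            path = outdir / f"{basename}{m + 1}.txt"
            write_dam_file(batch, path)
            result.monitor_paths.append(path)
        result.design_path = outdir / "design.csv"
        design.to_csv(result.design_path, index=False)
        result.truth_path = outdir / "ground_truth.csv"
        truth_frame(truths).to_csv(result.truth_path, index=False)
    return result


def truth_frame(truths: Iterable[GroundTruth]) -> pd.DataFrame:
    """Long-format ground-truth bout table (one row per realized bout)."""
    rows = [
        {"fly_id": gt.fly_id, "treatment": gt.treatment, "state": st,
         "start_zt": s, "end_zt": e, "duration": e - s}
        for gt in truths for st, s, e in gt.bouts
    ]
    if not rows:
        raise EmptyInputError("no ground truth")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# presets

def _control_female() -> FlyModelConfig:
    return FlyModelConfig()


def _control_male() -> FlyModelConfig:
    # males sleep more at night than females under LD
    return FlyModelConfig(sex="male",
                          sleep_bout_mean={"light": 20.0, "dark": 45.0},
                          wake_bout_mean={"light": 25.0, "dark": 12.0})


def _ad(base: FlyModelConfig) -> FlyModelConfig:
    # amyloid-beta expressing flies: shorter, more fragmented sleep and
    # slower sleep onset after lights-off
    return replace(base, genotype="AD",
                   sleep_bout_mean={ph: m * 0.6 for ph, m in base.sleep_bout_mean.items()},
                   latency_shift=60.0)


_DRUG_EFFECTS = {
    "drug_sleep_promoter": TreatmentEffect(sleep_bout=1.5),
    "drug_sleep_fragmenter": TreatmentEffect(sleep_bout=0.5),
    "drug_sedative": TreatmentEffect(wake_rate=0.5),
    "drug_stimulant": TreatmentEffect(wake_rate=1.5),
    "drug_fast_onset": TreatmentEffect(latency=0.25),
    "drug_null": TreatmentEffect(),
}


def preset(name: str) -> FlyModelConfig:
    """Named model configurations.

    ``control_female`` / ``control_male`` — healthy flies with the expected
    sex difference (males sleep more at night).  ``ad_female`` /
    ``ad_male`` — amyloid-beta models with reduced sleep-bout means and a
    raised latency shift.  ``drug_*`` — a control-female cohort carrying one
    treatment arm that perturbs a single model parameter (sleep-bout scale,
    waking rate or latency), for screen testing; ``drug_null`` carries an
    identity arm.  ``screen_panel`` — a control-female cohort with all six
    drug arms at once.
    """
    key = name.strip().lower()
    if key == "control_female":
        return _control_female()
    if key == "control_male":
        return _control_male()
    if key == "ad_female":
        return _ad(_control_female())
    if key == "ad_male":
        return _ad(_control_male())
    if key in _DRUG_EFFECTS:
        cfg = _control_female()
        cfg.effects = {key: _DRUG_EFFECTS[key]}
        return cfg
    if key == "screen_panel":
        cfg = _control_female()
        cfg.effects = dict(_DRUG_EFFECTS)
        return cfg
    raise ConfigurationError(
        f"unknown preset {name!r}; known: control_female, control_male, ad_female, "
        f"ad_male, screen_panel, {', '.join(_DRUG_EFFECTS)}"
    )
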