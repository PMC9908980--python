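"""Ground-truth-labelled synthetic inputs for every analysis stage.

The generators emulate the kinds of recordings the pipeline consumes:

* populations of somatic calcium traces from a slow indicator, imaged at
  1.3–1.7 Hz over ~2.5 min, with a controllable rate of population-wide
  co-activation events (the knob that injects synchrony);
* single-channel ECoG sampled at 5 kHz, modelled as 1/f^alpha background
  plus a duty-cycle-gated band-limited oscillation;
* logistic psychometric responders for up-down filament testing;
* longitudinal dendritic-protrusion tables with known identity labels and
  set formation/elimination probabilities.

Everything is deterministic given its config and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSimConfig",
    "GroundTruth",
    "EcogSimConfig",
    "gen_population_traces",
    "gen_ecog",
    "gen_updown_responder",
    "gen_spine_views",
]


# ---------------------------------------------------------------------------
# configs

@dataclass(frozen=True)
class PopulationSimConfig:
    """Forward model for a population of somatic calcium traces.

    Fluorescence for each neuron is

        F(t) = baseline_f * (1 + amplitude_dff * sum_k kernel(t - t_k)) + noise

    where events t_k are the union of per-neuron background Poisson events
    (rate ``background_rate_hz``) and population co-events (rate
    ``ensemble_rate_hz``) that each neuron joins with probability
    ``participation_prob``.  The kernel is a difference of exponentials
    normalised to unit peak, so one isolated event peaks at
    ``amplitude_dff`` in ΔF/F0 units.
    """

    n_neurons: int
    duration_s: float = 150.0
    frame_rate_hz: float = 1.5
    background_rate_hz: float = 0.05
    ensemble_rate_hz: float = 0.0
    participation_prob: float = 1.0
    amplitude_dff: float = 1.0
    kernel_rise_s: float = 0.18
    kernel_decay_s: float = 1.8
    baseline_f: float = 100.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("duration_s", "frame_rate_hz", "background_rate_hz",
                     "ensemble_rate_hz", "participation_prob", "amplitude_dff",
                     "kernel_rise_s", "kernel_decay_s", "baseline_f",
                     "noise_sd"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if min(self.background_rate_hz, self.ensemble_rate_hz) < 0:
            raise ValueError("event rates must be >= 0")
        if not 0.0 <= self.participation_prob <= 1.0:
            raise ValueError("participation_prob must lie in [0, 1]")
        if self.baseline_f <= 0:
            raise ValueError("baseline_f must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.kernel_rise_s, self.kernel_decay_s) <= 0:
            raise ValueError("kernel time constants must be > 0")
        if self.kernel_rise_s >= self.kernel_decay_s:
            raise ValueError("kernel_rise_s must be < kernel_decay_s")
        if self.duration_s * self.frame_rate_hz < 2:
            raise ValueError("recording must span at least 2 frames")


@dataclass
class GroundTruth:
    """Event bookkeeping for a generated population.

    ``event_times_s[i]`` holds every event time of neuron i (background and
    joined co-events).  ``coevent_times_s[j]`` / ``coevent_members[j]`` record
    each population co-event and the set of neurons that joined it.
    ``pair_coevent_counts[i, j]`` counts co-events that both i and j joined.
    """

    event_times_s: list[np.ndarray]
    coevent_times_s: np.ndarray
    coevent_members: list[frozenset[int]]
    pair_coevent_counts: np.ndarray = field(repr=False)

    @property
    def n_neurons(self) -> int:
        return len(self.event_times_s)


@dataclass(frozen=True)
class EcogSimConfig:
    """1/f^alpha background plus a duty-cycle-gated sinusoid.

    The gate is deterministic: within each ``burst_period_s`` cycle the
    oscillation is on for the first ``burst_duty`` fraction, so
    ``burst_duty=1`` yields a continuous tone and ``burst_duty=0`` none.
    ``noise_sd`` scales the background; with ``one_over_f_exponent=0`` the
    background is white.
    """

    fs_hz: float = 5000.0
    duration_s: float = 60.0
    one_over_f_exponent: float = 1.0
    osc_freq_hz: float = 6.0
    osc_amplitude: float = 1.0
    burst_duty: float = 1.0
    burst_period_s: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("fs_hz", "duration_s", "one_over_f_exponent",
                     "osc_freq_hz", "osc_amplitude", "burst_duty",
                     "burst_period_s", "noise_sd"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.fs_hz <= 2 * self.osc_freq_hz:
            raise ValueError("fs_hz must exceed twice osc_freq_hz")
        if not 0.0 <= self.burst_duty <= 1.0:
            raise ValueError("burst_duty must lie in [0, 1]")
        if self.duration_s <= 0 or self.burst_period_s <= 0:
            raise ValueError("durations must be > 0")
        if self.noise_sd < 0 or self.osc_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")


# ---------------------------------------------------------------------------
# calcium population

def _dual_exp_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials indicator kernel, unit peak, zero for t<0."""
    k = np.where(t >= 0,
                 np.exp(-np.maximum(t, 0.0) / decay_s)
                 - np.exp(-np.maximum(t, 0.0) / rise_s),
                 0.0)
    # analytic peak location/height of exp(-t/d) - exp(-t/r)
    tpk = (rise_s * decay_s / (decay_s - rise_s)) * math.log(decay_s / rise_s)
    peak = math.exp(-tpk / decay_s) - math.exp(-tpk / rise_s)
    return k / peak


def gen_population_traces(config: PopulationSimConfig):
    """Simulate a trace population; returns ``(TraceMatrix, GroundTruth)``.

    Frames are instantaneous point samples of the continuous fluorescence
    model at times ``i / frame_rate_hz``; noise is additive i.i.d. Gaussian
    on fluorescence.
    """
    from .traces import TraceMatrix  # local import to avoid a cycle

    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_neurons
    n_frames = int(math.floor(config.duration_s * config.frame_rate_hz))
    t_frames = np.arange(n_frames) / config.frame_rate_hz

    # population co-events
    n_co = rng.poisson(config.ensemble_rate_hz * config.duration_s)
    coevent_times = np.sort(rng.uniform(0.0, config.duration_s, size=n_co))
    members: list[frozenset[int]] = []
    for _ in range(n_co):
        joined = np.flatnonzero(rng.random(n) < config.participation_prob)
        members.append(frozenset(int(i) for i in joined))

    # per-neuron background events
    event_times: list[np.ndarray] = []
    for i in range(n):
        n_bg = rng.poisson(config.background_rate_hz * config.duration_s)
        bg = rng.uniform(0.0, config.duration_s, size=n_bg)
        co = [coevent_times[j] for j in range(n_co) if i in members[j]]
        event_times.append(np.sort(np.concatenate([bg, np.asarray(co)])))

    pair_counts = np.zeros((n, n), dtype=int)
    for mem in members:
        idx = np.fromiter(mem, dtype=int)
        if idx.size:
            pair_counts[np.ix_(idx, idx)] += 1

    values = np.empty((n_frames, n))
    for i in range(n):
        ev = event_times[i]
        if ev.size:
            k = _dual_exp_kernel(t_frames[:, None] - ev[None, :],
                                 config.kernel_rise_s, config.kernel_decay_s)
            drive = k.sum(axis=1)
        else:
            drive = np.zeros(n_frames)
        values[:, i] = config.baseline_f * (1.0 + config.amplitude_dff * drive)
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    values = np.maximum(values, 1e-9)  # fluorescence is non-negative

    tm = TraceMatrix(values=values,
                     frame_rate_hz=config.frame_rate_hz,
                     roi_ids=[f"roi{i:03d}" for i in range(n)])
    gt = GroundTruth(event_times_s=event_times,
                     coevent_times_s=coevent_times,
                     coevent_members=members,
                     pair_coevent_counts=pair_counts)
    return tm, gt


# ---------------------------------------------------------------------------
# ECoG

def gen_ecog(config: EcogSimConfig):
    """Simulate a single-channel ECoG record; returns :class:`EcogRecording`.

    The 1/f^alpha background is built by spectrally shaping white Gaussian
    noise (amplitude ∝ f^(-alpha/2)) and rescaling to ``noise_sd`` RMS.
    """
    from .spectral import EcogRecording

    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.fs_hz * config.duration_s))
    t = np.arange(n) / config.fs_hz

    if config.noise_sd > 0:
        white = rng.standard_normal(n)
        if config.one_over_f_exponent != 0:
            spec = np.fft.rfft(white)
            f = np.fft.rfftfreq(n, d=1.0 / config.fs_hz)
            shape = np.zeros_like(f)
            shape[1:] = f[1:] ** (-config.one_over_f_exponent / 2.0)
            colored = np.fft.irfft(spec * shape, n=n)
            colored_sd = colored.std()
            noise = colored * (config.noise_sd / colored_sd) if colored_sd > 0 \
                else np.zeros(n)
        else:
            noise = config.noise_sd * white
    else:
        noise = np.zeros(n)

    gate = (t % config.burst_period_s) < config.burst_duty * config.burst_period_s
    osc = config.osc_amplitude * np.sin(2 * np.pi * config.osc_freq_hz * t) * gate

    return EcogRecording(samples=noise + osc, fs_hz=config.fs_hz,
                         epochs=[(0.0, config.duration_s)])


# ---------------------------------------------------------------------------
# psychometric responder

def gen_updown_responder(true_threshold_g: float, slope: float, seed: int = 0):
    """Return a stochastic ``responder(force_g) -> bool`` for up-down testing.

    Withdrawal probability is logistic in log10 force,
    ``p = expit(slope * (log10(force) - log10(threshold)))``, so p = 0.5
    exactly at ``true_threshold_g``.  ``slope=inf`` gives a deterministic
    step responder (withdraws iff force > threshold).
    """
    if not (true_threshold_g > 0):
        raise ValueError("true_threshold_g must be > 0")
    if not (slope > 0):
        raise ValueError("slope must be > 0")
    rng = np.random.default_rng(seed)
    log_thr = math.log10(true_threshold_g)

    def responder(force_g: float) -> bool:
        if force_g <= 0:
            raise ValueError("force_g must be > 0")
        x = math.log10(force_g) - log_thr
        if math.isinf(slope):
            p = 0.5 if x == 0 else (1.0 if x > 0 else 0.0)
        else:
            p = 1.0 / (1.0 + math.exp(-slope * x))
        return bool(rng.random() < p)

    responder.true_threshold_g = true_threshold_g
    responder.slope = slope
    return responder


def withdraw_probability(force_g: float, true_threshold_g: float,
                         slope: float) -> float:
    """Closed-form logistic withdrawal probability of the responder model."""
    x = math.log10(force_g) - math.log10(true_threshold_g)
    if math.isinf(slope):
        return 0.5 if x == 0 else (1.0 if x > 0 else 0.0)
    return 1.0 / (1.0 + math.exp(-slope * x))


# ---------------------------------------------------------------------------
# spine views

_SPINE_GEOM = dict(length_um=1.2, head_diameter_um=0.8, neck_diameter_um=0.5)


def _place_new(rng: np.random.Generator, occupied: np.ndarray, n_new: int,
               branch_len_um: float, min_gap_um: float) -> np.ndarray:
    """Rejection-sample positions at least min_gap_um from occupied and each other."""
    out: list[float] = []
    taken = list(occupied)
    for _ in range(n_new):
        for _attempt in range(10_000):
            p = float(rng.uniform(0.0, branch_len_um))
            if all(abs(p - q) > min_gap_um for q in taken):
                out.append(p)
                taken.append(p)
                break
        else:
            raise RuntimeError("branch too crowded to place a new spine")
    return np.asarray(out)


def gen_spine_views(n_initial: int, p_elim: float, p_form: float,
                    n_views: int, seed: int = 0, *,
                    branch_len_um: float | None = None,
                    min_gap_um: float = 1.5) -> list[pd.DataFrame]:
    """Simulate longitudinal protrusion tables with ground-truth identities.

    Each inter-view interval removes every existing spine i.i.d. with
    probability ``p_elim`` and adds ``Binomial(n_initial, p_form)`` new
    spines at positions more than ``min_gap_um`` (> 2 x the 0.7 μm matching
    tolerance by default) from every site ever occupied.  The persistent ``truth_id``
    column carries spine identity across views; positions are exact between
    views, so position-based matching can be checked against the labels.

    Returns one protrusion table per view with columns
    id, branch_id, position_um, length_um, head_diameter_um,
    neck_diameter_um, class, session, truth_id.
    """
    if not (0.0 <= p_elim <= 1.0 and 0.0 <= p_form <= 1.0):
        raise ValueError("p_elim and p_form must lie in [0, 1]")
    if n_views < 2:
        raise ValueError("n_views must be >= 2")
    if n_initial < 1:
        raise ValueError("n_initial must be >= 1")
    rng = np.random.default_rng(seed)
    if branch_len_um is None:
        # room for every site ever occupied across the whole series
        expected_sites = n_initial * (1.0 + p_form * (n_views - 1))
        branch_len_um = max(40.0, 4.0 * min_gap_um * expected_sites)

    positions = _place_new(rng, np.asarray([]), n_initial,
                           branch_len_um, min_gap_um)
    next_label = n_initial
    live = {f"sp{i:04d}": float(p) for i, p in enumerate(positions)}
    # new spines keep the gap to every site ever occupied, not just current
    # survivors, so position-based matching stays unambiguous between any
    # pair of views
    ever_used = list(positions)

    def table(session: str) -> pd.DataFrame:
        rows = [dict(id=tid, branch_id="b0", position_um=pos,
                     **_SPINE_GEOM, **{"class": "spine"},
                     session=session, truth_id=tid)
                for tid, pos in sorted(live.items(), key=lambda kv: kv[1])]
        return pd.DataFrame(rows)

    views = [table("view0")]
    for v in range(1, n_views):
        # i.i.d. elimination of existing spines
        for tid in list(live):
            if rng.random() < p_elim:
                del live[tid]
        # formation
        n_new = int(rng.binomial(n_initial, p_form))
        if n_new:
            for p in _place_new(rng, np.asarray(ever_used), n_new,
                                branch_len_um, min_gap_um):
                live[f"sp{next_label:04d}"] = float(p)
                ever_used.append(float(p))
                next_label += 1
        views.append(table(f"view{v}"))
    return views
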