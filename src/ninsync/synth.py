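"""Synthetic two-region miniscope sessions with full ground truth.

The generator emulates a dual-site recording (cerebellar Purkinje cell
dendrites + cortical neurons): per-cell Poisson calcium-event trains with
region-specific rates and decay kinetics, planted synchronous ensembles,
an accelerometer stream with movement bouts coupled to the planted
synchronous events, rearing and turn templates, and an optogenetic
stimulation schedule with known per-cell response classes.

Defaults are the statistics reported for this preparation: event rates
0.62 Hz (cerebellum) / 0.22 Hz (cortex), half-decay times 0.217 s / 0.488 s,
rearing rate 1.47/min with 2.2 s duration, movement-bout latency ~80 ms
after a synchronous event, 31% of synchronous events followed by movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .io import AccelRecord, StimLog, TraceMatrix

__all__ = ["SynthConfig", "GroundTruth", "gcamp_kernel", "simulate_session"]


@lru_cache(maxsize=64)
def _decay_rate(rise_tau_s: float, t_half_s: float) -> float:
    """Decay exponent such that the peak-to-half time equals t_half.

    The half-decay time reported for calcium transients is measured from
    the transient peak, but with a finite rise the unsaturated rise factor
    makes the apparent post-peak decay slower than the asymptotic
    exponent. Solving for the exponent that puts the half-amplitude
    crossing exactly t_half after the peak makes "configured t_half" mean
    the measured quantity. As rise_tau -> 0 this reduces to ln2/t_half.
    """
    def peak_to_half(lam: float) -> float:
        t_peak = rise_tau_s * np.log1p(1.0 / (lam * rise_tau_s))
        def f(t):
            return (1.0 - np.exp(-t / rise_tau_s)) * np.exp(-lam * t)
        target = 0.5 * f(t_peak)
        return brentq(
            lambda t: f(t) - target, t_peak, t_peak + 20.0 / lam
        ) - t_peak

    lam0 = np.log(2.0) / t_half_s
    return float(
        brentq(lambda lam: peak_to_half(lam) - t_half_s, 0.2 * lam0, 5.0 * lam0)
    )


def gcamp_kernel(t, rise_tau_s: float, t_half_s: float) -> np.ndarray:
    """Unit-peak double-exponential calcium transient.

    k(t) = (1 - exp(-t/tau_r)) * exp(-lam * t) for t >= 0, else 0,
    normalized so the peak equals 1 exactly. The decay exponent lam is
    calibrated so the time from the kernel peak to half amplitude equals
    ``t_half_s`` (the quantity the half-decay estimator measures); in the
    fast-rise limit lam -> ln2/t_half. The peak time has the closed form
    t* = tau_r * ln(1 + 1/(lam*tau_r)).
    """
    if rise_tau_s <= 0 or t_half_s <= 0:
        raise ValueError("time constants must be positive")
    t = np.asarray(t, dtype=float)
    lam = _decay_rate(float(rise_tau_s), float(t_half_s))
    raw = np.where(t >= 0, (1.0 - np.exp(-t / rise_tau_s)) * np.exp(-lam * t), 0.0)
    t_peak = rise_tau_s * np.log1p(1.0 / (lam * rise_tau_s))
    peak = (1.0 - np.exp(-t_peak / rise_tau_s)) * np.exp(-lam * t_peak)
    return raw / peak


@dataclass
class SynthConfig:
    """Parameters of a simulated dual-region session.

    Region "A" plays the cerebellum (CBL), region "B" the cortex (CTX).
    The seed fully determines the output; sub-generators draw from
    independent child streams of a single ``numpy.random.SeedSequence``.
    """

    # population
    n_cells_a: int = 20
    n_cells_b: int = 20
    region_a: str = "CBL"
    region_b: str = "CTX"
    # event statistics
    baseline_rate_a_hz: float = 0.62
    baseline_rate_b_hz: float = 0.22
    t_half_a_s: float = 0.217
    t_half_b_s: float = 0.488
    rise_tau_s: float = 0.03
    amplitude: float = 1.0
    noise_sd: float = 0.05
    # acquisition
    duration_s: float = 300.0
    frame_rate_hz: float = 30.0
    accel_rate_hz: float = 104.0
    # planted synchrony
    sp_rate_hz: float = 0.1
    sp_ensemble_fraction_a: float = 0.3
    sp_ensemble_fraction_b: float = 0.3
    sp_jitter_sd_s: float = 0.01
    # movement coupling
    p_move_given_sp: float = 0.31
    move_latency_mean_s: float = 0.08
    move_latency_sd_s: float = 0.02
    move_bout_duration_s: float = 0.4
    move_bout_amplitude_g: float = 0.3
    #: rate of movement bouts unrelated to any SP (an awake mouse moves
    #: spontaneously; without these the random-trigger null is degenerate)
    spont_bout_rate_hz: float = 0.05
    accel_noise_sd_g: float = 0.02
    # rearing / turns
    rearing_rate_per_min: float = 1.47
    rearing_duration_s: float = 2.2
    rearing_amplitude_g: float = 0.3
    turn_rate_per_min: float = 0.0
    turn_amplitude_g: float = 0.25
    turn_duration_s: float = 0.5
    # stimulation
    n_stimuli: int = 0
    stim_isi_s: float = 20.0
    stim_duration_s: float = 0.05
    stim_site: str = "cbl_crus2"
    stim_response_latency_s: float = 0.22
    stim_response_amplitude: float = 3.0
    #: extra event rate of "increased" cells during the stimulation window
    #: (on top of baseline; 0.22 + 1.4 ~ the 1.63 Hz increased cluster)
    stim_extra_rate_hz: float = 1.4
    p_increased: float = 0.25
    p_decreased: float = 0.25
    stim_suppression: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "baseline_rate_a_hz",
            "baseline_rate_b_hz",
            "sp_rate_hz",
            "rearing_rate_per_min",
            "turn_rate_per_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "sp_ensemble_fraction_a",
            "sp_ensemble_fraction_b",
            "p_move_given_sp",
            "p_increased",
            "p_decreased",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_increased + self.p_decreased > 1.0:
            raise ValueError("response class probabilities exceed 1")


@dataclass
class GroundTruth:
    """Everything the generator planted, for scoring downstream stages."""

    onsets: dict[str, np.ndarray]
    ensemble_members: list[str]
    ensemble_pairs: list[tuple[str, str]]
    sp_times: np.ndarray
    movement_bouts: list[tuple[float, float]]
    moved_sp_mask: np.ndarray
    rearing_intervals: list[tuple[float, float]]
    turn_intervals: list[tuple[float, float, str]]
    response_class: dict[str, str] = field(default_factory=dict)


def _poisson_times(rng: np.random.Generator, rate_hz: float, duration_s: float):
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def _half_sine(t_rel: np.ndarray, duration: float) -> np.ndarray:
    env = np.sin(np.pi * t_rel / duration)
    return np.where((t_rel >= 0) & (t_rel <= duration), np.maximum(env, 0.0), 0.0)


def _rearing_template(t_rel: np.ndarray, duration: float) -> np.ndarray:
    """Rise-plateau-fall envelope (lifting and falling phases around a hold)."""
    edge = min(0.3, duration / 4)
    up = np.clip(t_rel / edge, 0.0, 1.0)
    down = np.clip((duration - t_rel) / edge, 0.0, 1.0)
    return np.where((t_rel >= 0) & (t_rel <= duration), np.minimum(up, down), 0.0)


def simulate_session(
    config: SynthConfig,
) -> tuple[TraceMatrix, AccelRecord, StimLog | None, GroundTruth]:
    """Generate one session: traces, accelerometer, stimulation log, truth.

    Identical config (including seed) gives bit-identical arrays.
    """
    cfg = config
    if cfg.n_stimuli > 0 and cfg.duration_s < cfg.n_stimuli * cfg.stim_isi_s:
        raise ValueError("duration too short for the requested stimulus schedule")
    if cfg.rearing_rate_per_min > 0 and cfg.duration_s < cfg.rearing_duration_s:
        raise ValueError("duration too short to place a rearing template")

    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_ev = np.random.default_rng(streams[0])  # baseline + planted events
    rng_tr = np.random.default_rng(streams[1])  # trace noise
    rng_mv = np.random.default_rng(streams[2])  # movement bouts
    rng_bh = np.random.default_rng(streams[3])  # rearing / turns
    rng_ax = np.random.default_rng(streams[4])  # accel noise
    rng_st = np.random.default_rng(streams[5])  # stimulation responses

    cell_ids = [f"{cfg.region_a}_{i:03d}" for i in range(cfg.n_cells_a)] + [
        f"{cfg.region_b}_{i:03d}" for i in range(cfg.n_cells_b)
    ]
    regions = [cfg.region_a] * cfg.n_cells_a + [cfg.region_b] * cfg.n_cells_b
    t_half = {cfg.region_a: cfg.t_half_a_s, cfg.region_b: cfg.t_half_b_s}

    # --- stimulation schedule and per-cell response classes ----------------
    stim: StimLog | None = None
    response_class: dict[str, str] = {}
    if cfg.n_stimuli > 0:
        first = cfg.stim_isi_s / 2.0
        onsets = first + cfg.stim_isi_s * np.arange(cfg.n_stimuli)
        stim = StimLog(
            onsets=onsets,
            duration_s=np.full(cfg.n_stimuli, cfg.stim_duration_s),
            site=[cfg.stim_site] * cfg.n_stimuli,
        )
        draw = rng_st.uniform(size=len(cell_ids))
        for cid, u in zip(cell_ids, draw):
            if u < cfg.p_increased:
                response_class[cid] = "increased"
            elif u < cfg.p_increased + cfg.p_decreased:
                response_class[cid] = "decreased"
            else:
                response_class[cid] = "unchanged"

    # --- planted synchronous ensemble --------------------------------------
    n_a_members = int(round(cfg.sp_ensemble_fraction_a * cfg.n_cells_a))
    n_b_members = int(round(cfg.sp_ensemble_fraction_b * cfg.n_cells_b))
    members = cell_ids[:n_a_members] + cell_ids[cfg.n_cells_a : cfg.n_cells_a + n_b_members]
    sp_times = _poisson_times(rng_ev, cfg.sp_rate_hz, cfg.duration_s)

    # --- per-cell event trains ----------------------------------------------
    rates = [cfg.baseline_rate_a_hz] * cfg.n_cells_a + [
        cfg.baseline_rate_b_hz
    ] * cfg.n_cells_b
    onsets: dict[str, np.ndarray] = {}
    for cid, rate in zip(cell_ids, rates):
        ev = _poisson_times(rng_ev, rate, cfg.duration_s)
        if cid in members and sp_times.size:
            jit = rng_ev.normal(0.0, cfg.sp_jitter_sd_s, size=sp_times.size)
            ev = np.sort(np.concatenate([ev, sp_times + jit]))
        ev = ev[(ev >= 0) & (ev < cfg.duration_s)]
        # "increased" cells fire extra events during the stimulation window
        if stim is not None and response_class.get(cid) == "increased":
            extra = []
            for s_on, s_dur in zip(stim.onsets, stim.duration_s):
                k = rng_st.poisson(cfg.stim_extra_rate_hz * s_dur)
                extra.append(rng_st.uniform(s_on, s_on + s_dur, size=k))
            ev = np.sort(np.concatenate([ev, *extra]))
        # suppression of baseline events during stimulation for "decreased"
        if stim is not None and response_class.get(cid) == "decreased":
            keep = np.ones(ev.size, dtype=bool)
            for s_on, s_dur in zip(stim.onsets, stim.duration_s):
                in_win = (ev >= s_on) & (ev < s_on + s_dur + 10.0)
                drop = in_win & (rng_st.uniform(size=ev.size) < cfg.stim_suppression)
                keep &= ~drop
            ev = ev[keep]
        onsets[cid] = ev

    # extra stimulus-locked transients for "increased" cells
    stim_extras: dict[str, np.ndarray] = {}
    if stim is not None:
        for cid in cell_ids:
            if response_class.get(cid) == "increased":
                lat = np.abs(
                    rng_st.normal(
                        cfg.stim_response_latency_s, 0.03, size=stim.n_stimuli
                    )
                )
                stim_extras[cid] = stim.onsets + stim.duration_s + lat

    # --- traces -------------------------------------------------------------
    n_frames = int(round(cfg.duration_s * cfg.frame_rate_hz))
    frame_t = np.arange(n_frames) / cfg.frame_rate_hz
    values = np.zeros((len(cell_ids), n_frames))
    kern_support = {
        reg: 5.0 * th / np.log(2.0) for reg, th in t_half.items()
    }  # ~ transient gone after 5 decay constants
    for i, (cid, reg) in enumerate(zip(cell_ids, regions)):
        row = values[i]
        ev = onsets[cid]
        extra = stim_extras.get(cid)
        all_ev = ev if extra is None else np.sort(np.concatenate([ev, extra]))
        amps = np.where(
            np.isin(all_ev, extra) if extra is not None else np.zeros(all_ev.size, bool),
            cfg.stim_response_amplitude,
            cfg.amplitude,
        )
        for t0, a in zip(all_ev, amps):
            j0 = int(np.searchsorted(frame_t, t0))
            j1 = int(np.searchsorted(frame_t, t0 + kern_support[reg]))
            if j0 >= j1:
                continue
            row[j0:j1] += a * gcamp_kernel(
                frame_t[j0:j1] - t0, cfg.rise_tau_s, t_half[reg]
            )
    if cfg.noise_sd > 0:
        values += rng_tr.normal(0.0, cfg.noise_sd, size=values.shape)
    traces = TraceMatrix(
        cell_ids=cell_ids,
        region=regions,
        t=frame_t,
        values=values,
        frame_rate_hz=cfg.frame_rate_hz,
    )

    # --- accelerometer ------------------------------------------------------
    n_acc = int(round(cfg.duration_s * cfg.accel_rate_hz))
    acc_t = np.arange(n_acc) / cfg.accel_rate_hz
    acc = (
        rng_ax.normal(0.0, cfg.accel_noise_sd_g, size=(3, n_acc))
        if cfg.accel_noise_sd_g > 0
        else np.zeros((3, n_acc))
    )

    moved = (
        rng_mv.uniform(size=sp_times.size) < cfg.p_move_given_sp
        if sp_times.size
        else np.zeros(0, dtype=bool)
    )
    bouts: list[tuple[float, float]] = []

    def add_bout(t0: float) -> None:
        t1 = t0 + cfg.move_bout_duration_s
        if t1 >= cfg.duration_s:
            return
        direction = rng_mv.normal(size=3)
        direction /= np.linalg.norm(direction)
        env = cfg.move_bout_amplitude_g * _half_sine(
            acc_t - t0, cfg.move_bout_duration_s
        )
        acc[:, :] += direction[:, None] * env[None, :]
        bouts.append((t0, t1))

    for sp_t, m in zip(sp_times, moved):
        if not m:
            continue
        # lognormal latency with the configured mean and sd
        mu = cfg.move_latency_mean_s
        sd = cfg.move_latency_sd_s
        sigma2 = np.log1p((sd / mu) ** 2)
        lat = rng_mv.lognormal(np.log(mu) - sigma2 / 2, np.sqrt(sigma2))
        add_bout(sp_t + lat)
    for t0 in _poisson_times(rng_mv, cfg.spont_bout_rate_hz, cfg.duration_s):
        add_bout(float(t0))

    # rearing: y rises/falls with plateau; z co-moves at reduced gain
    n_rear = rng_bh.poisson(cfg.rearing_rate_per_min * cfg.duration_s / 60.0)
    rear_iv: list[tuple[float, float]] = []
    guard = cfg.rearing_duration_s + 1.0
    attempts = 0
    while len(rear_iv) < n_rear and attempts < 50 * max(n_rear, 1):
        attempts += 1
        t0 = rng_bh.uniform(1.0, cfg.duration_s - guard)
        if all(abs(t0 - a) > guard for a, _ in rear_iv):
            rear_iv.append((t0, t0 + cfg.rearing_duration_s))
    rear_iv.sort()
    for t0, t1 in rear_iv:
        env = cfg.rearing_amplitude_g * _rearing_template(acc_t - t0, t1 - t0)
        acc[1] += env
        acc[2] += 0.6 * env

    n_turn = rng_bh.poisson(cfg.turn_rate_per_min * cfg.duration_s / 60.0)
    turn_iv: list[tuple[float, float, str]] = []
    guard_t = cfg.turn_duration_s + 1.0
    attempts = 0
    while len(turn_iv) < n_turn and attempts < 50 * max(n_turn, 1):
        attempts += 1
        t0 = rng_bh.uniform(1.0, cfg.duration_s - guard_t)
        if all(abs(t0 - a) > guard_t for a, _, _ in turn_iv):
            sign = 1.0 if rng_bh.uniform() < 0.5 else -1.0
            turn_iv.append((t0, t0 + cfg.turn_duration_s, "left" if sign > 0 else "right"))
    turn_iv.sort()
    for t0, t1, kind in turn_iv:
        sgn = 1.0 if kind == "left" else -1.0
        acc[0] += sgn * cfg.turn_amplitude_g * _half_sine(acc_t - t0, t1 - t0)

    np.clip(acc, -2.0, 2.0, out=acc)
    accel = AccelRecord(
        t=acc_t, x=acc[0], y=acc[1], z=acc[2], nominal_rate_hz=cfg.accel_rate_hz
    )

    pairs = [
        (a, b) for i, a in enumerate(members) for b in members[i + 1 :]
    ]
    truth = GroundTruth(
        onsets=onsets,
        ensemble_members=members,
        ensemble_pairs=pairs,
        sp_times=sp_times,
        movement_bouts=bouts,
        moved_sp_mask=moved,
        rearing_intervals=rear_iv,
        turn_intervals=turn_iv,
        response_class=response_class,
    )
    return traces, accel, stim, truth
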