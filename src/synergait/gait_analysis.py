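"""Gait events, cycle-normalized waveforms, COM/GRF metrics and waveform
similarity scores.

Conventions follow standard treadmill gait analysis: a gait cycle runs from a
right-leg touchdown to the next right-leg touchdown; touchdown/liftoff are
threshold crossings of the vertical ground reaction force (with hysteresis
debounce); every per-cycle waveform is resampled to 500 points before
averaging.  Agreement between two waveforms is scored with the cosine
similarity S (nonnegative traces such as vertical GRF and muscle activity)
or the Pearson correlation R (signed traces).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import warnings

import numpy as np
from scipy import signal

from .motor_control import MUSCLES
from .record import GaitRecord
from .skeleton_dynamics import BodyParameters, whole_body_com

__all__ = [
    "GaitEvents",
    "GaitMetrics",
    "CycleWaveform",
    "SimilarityScore",
    "detect_events",
    "cycle_normalize",
    "similarity",
    "com_metrics",
    "grf_peak_count",
    "filter_emg",
    "normalize_emg",
    "analyze_record",
]

N_CYCLE_POINTS = 500
STEADY_FIRST_CYCLE = 2  # metrics use cycles 3..end (0-based index 2)


@dataclass
class GaitEvents:
    """Touchdown/liftoff times per leg and right-to-right cycle boundaries."""

    td_r: np.ndarray
    lo_r: np.ndarray
    td_l: np.ndarray
    lo_l: np.ndarray

    @property
    def cycles(self) -> np.ndarray:
        """(n_cycles, 2) start/end times, right touchdown to next right touchdown."""
        td = np.asarray(self.td_r)
        if td.size < 2:
            return np.empty((0, 2))
        return np.column_stack([td[:-1], td[1:]])


@dataclass
class CycleWaveform:
    """Per-cycle traces resampled to 500 points plus their across-cycle mean."""

    cycles: np.ndarray  # (n_cycles, 500)
    mean: np.ndarray  # (500,)


@dataclass
class SimilarityScore:
    S: float
    R: float


@dataclass
class GaitMetrics:
    """Summary metrics of one record over the steady-state cycles."""

    gait: str = "unknown"
    success: bool = False
    steps: int = 0
    average_speed: float = float("nan")
    cycle_duration: float = float("nan")
    duty_factor: float = float("nan")
    double_stance_fraction: float = float("nan")
    flight_fraction: float = float("nan")
    double_stance_durations: list = field(default_factory=list)
    flight_durations: list = field(default_factory=list)
    grf_peaks: int = 0
    com_height_speed_correlation: float = float("nan")
    regulator_contribution_pct: float = float("nan")
    n_steady_cycles: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in self.__dict__.items()},
                fh,
                indent=2,
            )


def detect_events(
    t: np.ndarray,
    grf_r: np.ndarray,
    grf_l: np.ndarray,
    threshold: float = 5.0,
    debounce: float = 0.01,
) -> GaitEvents:
    """Threshold crossings of the vertical GRF per leg.

    Touchdown is an upward crossing of ``threshold`` (N), liftoff a downward
    crossing; crossings closer than ``debounce`` seconds to the previous event
    of the same leg are ignored (the discrete-point sole makes the force
    fluctuate).
    """
    t = np.asarray(t, dtype=float)
    out = {}
    for key, grf in (("r", grf_r), ("l", grf_l)):
        grf = np.asarray(grf, dtype=float)
        if grf.shape != t.shape:
            raise ValueError("time and GRF series must have equal length")
        loaded = grf > threshold
        td, lo = [], []
        last = -np.inf
        for k in range(1, len(t)):
            if loaded[k] != loaded[k - 1] and (t[k] - last) > debounce:
                (td if loaded[k] else lo).append(t[k])
                last = t[k]
        out[key] = (np.asarray(td), np.asarray(lo))
    ev = GaitEvents(td_r=out["r"][0], lo_r=out["r"][1], td_l=out["l"][0], lo_l=out["l"][1])
    if ev.td_r.size == 0 and ev.td_l.size == 0:
        warnings.warn("no gait events detected", stacklevel=2)
    return ev


def cycle_normalize(
    t: np.ndarray,
    series: np.ndarray,
    cycles: np.ndarray,
    n: int = N_CYCLE_POINTS,
) -> CycleWaveform:
    """Resample each cycle to ``n`` points by linear interpolation and average.

    ``cycles`` is (n_cycles, 2) start/end times (see :class:`GaitEvents`).
    """
    t = np.asarray(t, dtype=float)
    series = np.asarray(series, dtype=float)
    cycles = np.atleast_2d(np.asarray(cycles, dtype=float))
    if cycles.size == 0:
        raise ValueError("need at least one complete cycle")
    out = np.empty((cycles.shape[0], n))
    for k, (t0, t1) in enumerate(cycles):
        if t1 <= t0:
            raise ValueError("cycle end must follow cycle start")
        ti = np.linspace(t0, t1, n)
        out[k] = np.interp(ti, t, series)
    return CycleWaveform(cycles=out, mean=out.mean(axis=0))


def similarity(x: np.ndarray, y: np.ndarray) -> SimilarityScore:
    """Cosine similarity S and Pearson correlation R between two waveforms."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("waveforms must have equal length")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine similarity undefined for zero-norm input")
    S = float(x @ y / (nx * ny))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    R = float(np.corrcoef(x, y)[0, 1])
    return SimilarityScore(S=S, R=R)


def grf_peak_count(
    waveform: np.ndarray,
    smooth_window: int = 11,
    prominence_fraction: float = 0.05,
) -> int:
    """Number of local maxima of a stance-phase vertical-GRF waveform.

    The waveform is smoothed with a moving average before peak counting and
    peaks must have prominence of at least ``prominence_fraction`` of the
    waveform maximum; both guards suppress the force fluctuation caused by
    the four discrete sole points.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < smooth_window:
        raise ValueError("waveform shorter than the smoothing window")
    kernel = np.ones(smooth_window) / smooth_window
    ws = np.convolve(w, kernel, mode="same")
    peaks, _ = signal.find_peaks(ws, prominence=prominence_fraction * ws.max())
    return int(len(peaks))


def com_metrics(
    record: GaitRecord, body: BodyParameters, cycles: np.ndarray | None = None
) -> dict:
    """Whole-body COM trajectory, horizontal speed and per-cycle correlation
    between COM height and horizontal speed.

    Walking shows pendular exchange (height and speed in antiphase, negative
    correlation); running shows in-phase spring-mass behaviour (positive
    correlation).
    """
    pos, vel = whole_body_com(record.q(), body, record.qd())
    t = record.t
    out = {"t": t, "com": pos, "com_speed": vel[:, 0]}
    if cycles is None:
        ev = detect_events(t, record.grf("r")[:, 1], record.grf("l")[:, 1])
        cycles = ev.cycles
    cycles = np.atleast_2d(np.asarray(cycles))
    corrs = []
    for t0, t1 in cycles:
        m = (t >= t0) & (t < t1)
        h = pos[m, 1]
        v = vel[m, 0]
        if m.sum() < 4 or np.ptp(h) == 0 or np.ptp(v) == 0:
            raise ValueError("degenerate cycle for COM correlation")
        corrs.append(float(np.corrcoef(h, v)[0, 1]))
    out["height_speed_correlation"] = corrs
    out["mean_correlation"] = float(np.mean(corrs)) if corrs else float("nan")
    return out


def filter_emg(raw: np.ndarray, fs: float, hp_cut: float = 1.0, lp_cut: float = 5.0) -> np.ndarray:
    """EMG envelope: 2nd-order Butterworth high-pass, demean, rectify,
    zero-lag (forward-backward) Butterworth low-pass."""
    raw = np.asarray(raw, dtype=float)
    if fs <= 2 * max(hp_cut, lp_cut):
        raise ValueError("sampling rate too low for the filter cutoffs")
    sos_hp = signal.butter(2, hp_cut, btype="highpass", fs=fs, output="sos")
    x = signal.sosfilt(sos_hp, raw)
    x = x - x.mean()
    x = np.abs(x)
    sos_lp = signal.butter(2, lp_cut, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos_lp, x)


def normalize_emg(
    emg_walk: np.ndarray,
    emg_run: np.ndarray,
    sim_walk: np.ndarray,
    sim_run: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scale one muscle's EMG envelopes so that the walk/run average of the
    envelope maxima equals that of the simulated activations.

    Returns the scaled walking and running envelopes and the gain applied.
    """
    emg_walk = np.asarray(emg_walk, dtype=float)
    emg_run = np.asarray(emg_run, dtype=float)
    target = 0.5 * (np.max(sim_walk) + np.max(sim_run))
    mref = 0.5 * (emg_walk.max() + emg_run.max())
    if mref <= 0:
        raise ValueError("EMG envelope is identically zero")
    g = target / mref
    return g * emg_walk, g * emg_run, float(g)


def _stance_flags_from_events(t, ev: GaitEvents) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample stance occupancy rebuilt from the debounced events.

    The raw force flags flicker when the discrete four-point sole briefly
    unloads; the event reconstruction removes sub-debounce gaps.
    """
    out = []
    for td, lo in ((ev.td_r, ev.lo_r), (ev.td_l, ev.lo_l)):
        flag = np.zeros(len(t), dtype=bool)
        edges = sorted([(x, 1) for x in td] + [(x, 0) for x in lo])
        state = bool(edges and edges[0][1] == 0)  # loaded before first event?
        prev = t[0]
        for when, kind in edges:
            if state:
                flag[(t >= prev) & (t < when)] = True
            state = kind == 1
            prev = when
        if state:
            flag[t >= prev] = True
        out.append(flag)
    return out[0], out[1]


def _phase_fractions(t, stance_r, stance_l, cycles):
    """Double-stance / single-stance / flight occupancy over given cycles."""
    ds_dur, fl_dur = [], []
    ds_frac = fl_frac = 0.0
    total = 0.0
    for t0, t1 in cycles:
        m = (t >= t0) & (t < t1)
        if m.sum() < 2:
            continue
        dt = np.diff(t[m]).mean()
        both = (stance_r[m] > 0) & (stance_l[m] > 0)
        neither = (stance_r[m] == 0) & (stance_l[m] == 0)
        ds = both.sum() * dt
        fl = neither.sum() * dt
        ds_dur.append(float(ds))
        fl_dur.append(float(fl))
        ds_frac += ds
        fl_frac += fl
        total += t1 - t0
    if total == 0:
        return [], [], float("nan"), float("nan")
    return ds_dur, fl_dur, ds_frac / total, fl_frac / total


def analyze_record(
    record: GaitRecord,
    body: BodyParameters | None = None,
    threshold: float = 5.0,
    min_phase_fraction: float = 0.01,
) -> GaitMetrics:
    """Full metric extraction over the steady-state cycles (cycles 3..end).

    The gait label is behavioural: double-stance phases and no flight is
    walking, flight phases and no double stance is running.
    """
    from .motor_control import regulator_contribution

    body = body or BodyParameters()
    t = record.t
    ev = detect_events(t, record.grf("r")[:, 1], record.grf("l")[:, 1], threshold)
    cycles = ev.cycles
    steady = cycles[STEADY_FIRST_CYCLE:] if len(cycles) > STEADY_FIRST_CYCLE else cycles
    m = GaitMetrics(success=record.success, steps=record.step_count)
    if len(steady) == 0:
        return m
    m.n_steady_cycles = int(len(steady))
    t0, t1 = steady[0][0], steady[-1][1]
    win = (t >= t0) & (t < t1)

    m.average_speed = float(record.qd()[win, 0].mean())
    m.cycle_duration = float(np.mean(steady[:, 1] - steady[:, 0]))

    stance_r, stance_l = _stance_flags_from_events(t, ev)
    ds_dur, fl_dur, ds_frac, fl_frac = _phase_fractions(t, stance_r, stance_l, steady)
    m.double_stance_durations = ds_dur
    m.flight_durations = fl_dur
    m.double_stance_fraction = float(ds_frac)
    m.flight_fraction = float(fl_frac)
    m.duty_factor = float(stance_r[win].mean())

    has_ds = ds_frac > min_phase_fraction
    has_fl = fl_frac > min_phase_fraction
    if has_ds and not has_fl:
        m.gait = "walking"
    elif has_fl and not has_ds:
        m.gait = "running"
    else:
        m.gait = "mixed" if (has_ds and has_fl) else "unknown"

    wf = cycle_normalize(t, record.grf("r")[:, 1], steady)
    stance_mask = wf.mean > threshold
    if stance_mask.any():
        first, last = np.flatnonzero(stance_mask)[[0, -1]]
        m.grf_peaks = grf_peak_count(wf.mean[first : last + 1])

    if body is not None:
        cm = com_metrics(record, body, steady)
        m.com_height_speed_correlation = cm["mean_correlation"]

    u = record.muscle("u")[win]
    u_reg = record.muscle("ureg")[win]
    if np.abs(u).sum() > 0:
        m.regulator_contribution_pct = regulator_contribution(u, u_reg)
    return m
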