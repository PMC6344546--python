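"""Preset management, gait runs, the seven-parameter gait switch, speed
sweeps, and the synthetic fixture generator for the analysis stage.

The two shipped presets hold the published hand-tuned motor-control sets for
walking and running at a desired speed of 1.6 m/s; they differ in exactly
seven parameters (cycle duration T, second-pulse onset Phi_2, and the five
pulse amplitudes Lambda_i).  Speed sweeps replay user-supplied rows of those
same seven parameters per desired speed; there is no automatic optimisation,
mirroring the hand-tuning procedure.
"""

from __future__ import annotations

import copy
import importlib.resources as resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .gait_analysis import GaitMetrics, analyze_record
from .motor_control import MUSCLES, PulseParameters, RegulatorParameters
from .muscle_model import MuscleSet
from .record import GaitRecord
from .skeleton_dynamics import BodyParameters, simulate

__all__ = [
    "GaitPreset",
    "available_presets",
    "load_preset",
    "preset_diff",
    "default_body",
    "default_muscles",
    "run_gait",
    "speed_sweep",
    "make_synthetic_gait_fixture",
]

#: The seven parameters allowed to change between gaits and speeds.
SWITCH_PARAMETERS = ("T", "Phi_2", "Lambda_1", "Lambda_2", "Lambda_3", "Lambda_4", "Lambda_5")


@dataclass
class GaitPreset:
    """A complete 69-parameter motor-control set plus provenance note.

    ``launch`` optionally carries a packed 37-component simulator state (the
    limit-cycle launch condition found for the shipped plant fixtures); when
    present, :func:`run_gait` starts from it instead of the generic posture.
    """

    label: str
    pulses: PulseParameters
    regulator: RegulatorParameters
    provenance: str = ""
    launch: np.ndarray | None = None

    def flat(self) -> dict[str, float]:
        """Scalar view of all 69 parameters, keyed by conventional names."""
        out = {"T": self.pulses.T}
        for i in range(5):
            out[f"Phi_{i+1}"] = float(self.pulses.onset[i])
            out[f"Delta_{i+1}"] = float(self.pulses.duration[i])
            out[f"Lambda_{i+1}"] = float(self.pulses.amplitude[i])
        for m, name in enumerate(MUSCLES):
            for i in range(5):
                out[f"w_{name}_{i+1}"] = float(self.pulses.weights[m, i])
        r = self.regulator
        out.update(
            kappa_IL=r.kappa_IL, kappa_GM=r.kappa_GM, sigma_IL=r.sigma_IL,
            sigma_GM=r.sigma_GM, lambda_TA=r.lambda_TA, lambda_SO=r.lambda_SO,
            theta_ref=r.theta_ref, v_ref=r.v_ref,
        )
        return out

    def with_overrides(self, **kv: float) -> "GaitPreset":
        """New preset with named scalar parameters replaced (e.g. T=0.8,
        Phi_2=0.16, Lambda_1=1.34, v_ref=1.4).

        Changing any movement-generator parameter invalidates the stored
        limit-cycle launch state (it belongs to the original pulse train), so
        the derived preset drops it; regulator-only overrides keep it.
        """
        pp = copy.deepcopy(self.pulses)
        rp = copy.deepcopy(self.regulator)
        generator_changed = any(
            k == "T" or k.startswith(("Phi_", "Delta_", "Lambda_", "w_"))
            for k in kv
        )
        for key, val in kv.items():
            if key == "T":
                pp.T = float(val)
            elif key.startswith("Phi_"):
                pp.onset[int(key[4:]) - 1] = float(val)
            elif key.startswith("Delta_"):
                pp.duration[int(key[6:]) - 1] = float(val)
            elif key.startswith("Lambda_"):
                pp.amplitude[int(key[7:]) - 1] = float(val)
            elif key.startswith("w_"):
                _, mname, idx = key.split("_")
                pp.weights[MUSCLES.index(mname), int(idx) - 1] = float(val)
            elif hasattr(rp, key):
                setattr(rp, key, float(val))
            else:
                raise KeyError(f"unknown parameter {key!r}")
        launch = None
        if self.launch is not None and not generator_changed:
            launch = self.launch.copy()
        return GaitPreset(label=self.label, pulses=pp, regulator=rp,
                          provenance=self.provenance + " (with overrides)",
                          launch=launch)


def _preset_path(name: str):
    return resources.files("synergait") / "presets" / name


def available_presets() -> list[str]:
    root = resources.files("synergait") / "presets"
    return sorted(
        p.name[: -len(".yaml")]
        for p in root.iterdir()
        if p.name.endswith(".yaml") and "pulses:" in p.read_text()
    )


def load_preset(label: str) -> GaitPreset:
    """Load a shipped (or path-like) motor-control preset."""
    path = _preset_path(f"{label}.yaml")
    try:
        text = path.read_text()
    except FileNotFoundError as exc:
        raise KeyError(
            f"unknown preset {label!r}; available: {available_presets()}"
        ) from exc
    doc = yaml.safe_load(text)
    p = doc["pulses"]
    weights = np.array([p["weights"][m] for m in MUSCLES], dtype=float)
    pulses = PulseParameters(
        T=float(p["T"]),
        onset=np.asarray(p["onset"], dtype=float),
        duration=np.asarray(p["duration"], dtype=float),
        weights=weights,
        amplitude=np.asarray(p["amplitude"], dtype=float),
    )
    regulator = RegulatorParameters(**doc["regulator"])
    launch = doc.get("launch")
    if launch is not None:
        launch = np.asarray(launch["state"], dtype=float)
        if launch.shape != (37,):
            raise ValueError("launch state must have 37 components")
    return GaitPreset(
        label=doc.get("label", label),
        pulses=pulses,
        regulator=regulator,
        provenance=doc.get("provenance", ""),
        launch=launch,
    )


def preset_diff(a: GaitPreset, b: GaitPreset, atol: float = 0.0) -> list[str]:
    """Names of scalar parameters that differ between two presets."""
    fa, fb = a.flat(), b.flat()
    return [k for k in fa if abs(fa[k] - fb[k]) > atol]


def default_body() -> BodyParameters:
    with resources.as_file(_preset_path("body_default.yaml")) as p:
        return BodyParameters.from_yaml(p)


def default_muscles() -> MuscleSet:
    with resources.as_file(_preset_path("muscles_default.yaml")) as p:
        return MuscleSet.from_yaml(p)


def run_gait(
    preset: GaitPreset | str,
    duration: float = 15.0,
    overrides: dict | None = None,
    body: BodyParameters | None = None,
    muscles: MuscleSet | None = None,
    dt: float = 2e-5,
    **simulate_kwargs,
) -> tuple[GaitRecord, GaitMetrics]:
    """Simulate one preset and analyze the result.

    Success requires at least 10 steps without falling; failure is reported in
    the metrics, not raised.
    """
    if isinstance(preset, str):
        preset = load_preset(preset)
    if overrides:
        preset = preset.with_overrides(**overrides)
    body = body or default_body()
    muscles = muscles or default_muscles()
    if preset.launch is not None and "y0" not in simulate_kwargs:
        simulate_kwargs["y0"] = preset.launch
    record = simulate(
        body, muscles, preset.pulses, preset.regulator, duration,
        dt=dt, meta={"preset": preset.label}, **simulate_kwargs,
    )
    metrics = analyze_record(record, body)
    return record, metrics


def speed_sweep(
    schedule: list[dict],
    preset: GaitPreset | str = "walking_1.6",
    duration: float = 15.0,
    **run_kwargs,
) -> pd.DataFrame:
    """Run one gait per schedule row and tabulate the outcome.

    Each row supplies the desired speed ``v_ref`` and any of the seven switch
    parameters (T, Phi_2, Lambda_1..5).  Rows are run independently; failures
    are recorded and the sweep continues.  Within a gait the generated speed
    is expected (not enforced) to increase with the desired speed.
    """
    if isinstance(preset, str):
        preset = load_preset(preset)
    rows = []
    for entry in schedule:
        entry = dict(entry)
        label = entry.pop("label", preset.label)
        try:
            record, metrics = run_gait(
                preset, duration=duration, overrides=entry, **run_kwargs
            )
            rows.append(
                {
                    "label": label,
                    "v_ref": entry.get("v_ref", preset.regulator.v_ref),
                    **{k: entry.get(k, preset.flat()[k]) for k in SWITCH_PARAMETERS},
                    "speed": metrics.average_speed,
                    "gait": metrics.gait,
                    "steps": metrics.steps,
                    "success": metrics.success,
                    "error": "",
                }
            )
        except Exception as exc:  # pragma: no cover - defensive per-row guard
            rows.append({"label": label, "success": False, "error": str(exc)})
    df = pd.DataFrame(rows)
    if len(df) > 1 and df["success"].all():
        sp = df.sort_values("v_ref")["speed"].to_numpy()
        if np.any(np.diff(sp) < 0):
            import warnings

            warnings.warn("generated speed is not monotone in desired speed", stacklevel=2)
    return df


# ---------------------------------------------------------------------------
# synthetic fixtures for the analysis stage
# ---------------------------------------------------------------------------

def make_synthetic_gait_fixture(
    gait: str = "walking",
    n_cycles: int = 5,
    T: float = 1.0,
    fs: float = 1000.0,
    body_weight: float = 620.0,
    noise: float = 0.0,
    seed: int = 0,
) -> dict:
    """Analytically known gait traces for unit-testing the analysis stage.

    Walking: duty factor 0.62 (double stance, no flight) and a two-Gaussian
    vertical GRF per stance; running: duty factor 0.35 (flight, no double
    stance) and a single-Gaussian GRF.  COM height and horizontal speed are
    sinusoids at two oscillations per cycle, in antiphase for walking and in
    phase for running.  EMG is a rectangular burst per cycle.  All event times
    are returned as ground truth.
    """
    rng = np.random.default_rng(seed)
    duty = 0.62 if gait == "walking" else 0.35
    t = np.arange(0.0, n_cycles * T, 1.0 / fs)

    def leg_grf(offset: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        grf = np.zeros_like(t)
        tds, los = [], []
        for k in range(-1, n_cycles + 1):
            t0 = k * T + offset
            t1 = t0 + duty * T
            tds.append(t0)
            los.append(t1)
            mask = (t >= t0) & (t <= t1)
            ts = (t[mask] - t0) / (duty * T)
            if gait == "walking":
                w = np.exp(-0.5 * ((ts - 0.25) / 0.12) ** 2) + np.exp(
                    -0.5 * ((ts - 0.75) / 0.12) ** 2
                )
            else:
                w = 1.6 * np.exp(-0.5 * ((ts - 0.5) / 0.15) ** 2)
            grf[mask] += body_weight * 1.1 * w
        tds = [x for x in tds if 0 <= x < n_cycles * T]
        los = [x for x in los if 0 <= x < n_cycles * T]
        return grf, np.asarray(tds), np.asarray(los)

    grf_r, td_r, lo_r = leg_grf(0.0)
    grf_l, td_l, lo_l = leg_grf(T / 2.0)

    phase = 2.0 * np.pi * 2.0 * t / T  # two COM oscillations per cycle
    com_height = 0.95 + 0.02 * np.cos(phase)
    sign = -1.0 if gait == "walking" else 1.0
    com_speed = 1.5 + sign * 0.1 * np.cos(phase)

    emg_onset, emg_dur = 0.1 * T, 0.25 * T
    emg = np.zeros((len(t), len(MUSCLES)))
    for m in range(len(MUSCLES)):
        for k in range(n_cycles):
            t0 = k * T + emg_onset + 0.05 * m * T
            emg[(t >= t0) & (t < t0 + emg_dur), m] = 1.0

    if noise > 0:
        grf_r = grf_r + noise * body_weight * rng.standard_normal(len(t))
        grf_l = grf_l + noise * body_weight * rng.standard_normal(len(t))
        emg = emg + noise * rng.standard_normal(emg.shape)

    return {
        "gait": gait,
        "t": t,
        "fs": fs,
        "T": T,
        "duty": duty,
        "grf_r": grf_r,
        "grf_l": grf_l,
        "td_r": td_r,
        "lo_r": lo_r,
        "td_l": td_l,
        "lo_l": lo_l,
        "com_height": com_height,
        "com_speed": com_speed,
        "emg": emg,
        "emg_onset": emg_onset,
        "emg_duration": emg_dur,
    }
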