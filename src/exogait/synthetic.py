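"""Synthetic gait data: artificial-muscle force templates, ground
reaction force, five-muscle sEMG envelopes, and simulated protocol
subjects for preferred-walking-speed estimation.

Everything downstream of this module (curve design, controller replay,
the statistics stage) runs on data generated here, with controllable
effect sizes, noise, and seeds.  Base envelope templates are smooth bump
mixtures (wrapped Gaussians on the phase circle): the measured anchors of
real traces are ranges and peak timings, and the shape between anchors is
a documented free choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trace import ForceTrace, phase_grid

MUSCLES = ("HAM", "RF", "VAS", "GAS", "SOL")
CONDITIONS = ("NE", "NC", "Emp", "RL")

#: default per-condition mean step durations (s) for the fixed slow-speed
#: protocol and the preferred-walking-speed protocol; generator defaults,
#: not reproduction claims.
SLOW_STEP_DURATIONS = {"NE": 1.333, "NC": 1.340, "Emp": 1.309, "RL": 1.334}
PWS_STEP_DURATIONS = {"NE": 1.054, "NC": 1.089, "Emp": 1.048, "RL": 1.163}


class SyntheticDataError(ValueError):
    pass


def _wrapped_bump(phi: np.ndarray, center: float, width: float) -> np.ndarray:
    """Gaussian bump wrapped onto the unit phase circle (peak value 1)."""
    d = np.mod(phi - center + 0.5, 1.0) - 0.5
    return np.exp(-0.5 * (d / width) ** 2)


@dataclass
class GaitTemplateConfig:
    """Shape parameters of the artificial HAM / RF force templates.

    Defaults reflect the blocked-motor identification recordings: HAM
    forces span 6-23 N with the peak at 92% of the gait cycle (leg fully
    stretched, swinging back toward the body) and high force early in
    stance; RF forces span 4-22.5 N peaking around toe-off (default 60%).
    """

    n_phase_points: int = 200
    ham_force_range: tuple[float, float] = (6.0, 23.0)
    ham_peak_phase: float = 0.92
    rf_force_range: tuple[float, float] = (4.0, 22.5)
    rf_peak_phase: float = 0.60
    noise_sd: float = 0.0  # N
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phase_points < 16:
            raise SyntheticDataError("n_phase_points must be >= 16")
        for lo, hi in (self.ham_force_range, self.rf_force_range):
            if lo > hi:
                raise SyntheticDataError("force range must have min <= max")
        for p in (self.ham_peak_phase, self.rf_peak_phase):
            if not (0.0 <= p < 1.0):
                raise SyntheticDataError("peak phase must lie in [0, 1)")
        if self.noise_sd < 0:
            raise SyntheticDataError("noise_sd must be >= 0")


def _range_mapped_template(
    phi: np.ndarray, shape: np.ndarray, lo: float, hi: float,
) -> np.ndarray:
    """Affinely map a shape onto [lo, hi] (constant if lo == hi)."""
    smin, smax = float(shape.min()), float(shape.max())
    if hi == lo or smax == smin:
        return np.full_like(phi, lo)
    return lo + (hi - lo) * (shape - smin) / (smax - smin)


def make_force_templates(
    config: GaitTemplateConfig | None = None,
) -> tuple[ForceTrace, ForceTrace]:
    """Artificial HAM and RF force traces over one normalized gait cycle.

    With noise off, each trace spans its configured range exactly and
    attains its maximum exactly at the configured peak phase (provided the
    peak phase lies on the grid, as it does for the defaults).
    """
    cfg = config or GaitTemplateConfig()
    phi = phase_grid(cfg.n_phase_points)
    rng = np.random.default_rng(cfg.seed)

    # HAM: dominant late-swing peak, a broad early-stance shoulder, and a
    # deep mid/late-stance trough where the HAM is slack.  The narrow
    # "kicker" bump on top of each main peak pins the discrete argmax to
    # the configured peak phase even under the shoulders' tails.
    ham_shape = (
        1.00 * _wrapped_bump(phi, cfg.ham_peak_phase, 0.055)
        + 0.50 * _wrapped_bump(phi, cfg.ham_peak_phase, 0.015)
        + 0.72 * _wrapped_bump(phi, 0.07, 0.11)
    )
    # RF: dominant toe-off peak with a smaller early-stance shoulder.
    rf_shape = (
        1.00 * _wrapped_bump(phi, cfg.rf_peak_phase, 0.10)
        + 0.30 * _wrapped_bump(phi, cfg.rf_peak_phase, 0.025)
        + 0.25 * _wrapped_bump(phi, 0.10, 0.05)
    )
    ham = _range_mapped_template(phi, ham_shape, *cfg.ham_force_range)
    rf = _range_mapped_template(phi, rf_shape, *cfg.rf_force_range)
    if cfg.noise_sd > 0:
        ham = ham + rng.normal(0.0, cfg.noise_sd, size=ham.shape)
        rf = rf + rng.normal(0.0, cfg.noise_sd, size=rf.shape)
    return (
        ForceTrace(ham, phi, domain="phase", units="N", label="HAM"),
        ForceTrace(rf, phi, domain="phase", units="N", label="RF"),
    )


def make_grf_trace(
    step_duration: float,
    n_steps: int,
    stance_fraction: float = 0.61,
    peak_force: float = 800.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    rate: float = 100.0,
) -> ForceTrace:
    """Vertical GRF over ``n_steps`` gait cycles at ``rate`` Hz.

    Each cycle has the classic double-hump stance profile (loading and
    push-off peaks with a mid-stance valley) followed by an exactly-zero
    swing interval.  The default 61% stance fraction matches typical
    walking; noise perturbs stance samples only, clamped at zero.
    """
    if step_duration <= 0:
        raise SyntheticDataError("step_duration must be > 0")
    if not (0.0 < stance_fraction < 1.0):
        raise SyntheticDataError("stance_fraction must lie in (0, 1)")
    if n_steps < 1:
        raise SyntheticDataError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    n_per = int(round(step_duration * rate))
    n = n_steps * n_per
    t = np.arange(n) / rate
    phase = (np.arange(n) % n_per) / n_per
    in_stance = phase < stance_fraction
    u = np.where(in_stance, phase / stance_fraction, 0.0)  # stance-local 0..1
    profile = (
        1.00 * np.exp(-0.5 * ((u - 0.25) / 0.13) ** 2)
        + 1.00 * np.exp(-0.5 * ((u - 0.78) / 0.12) ** 2)
        + 0.35
    )
    grf = np.where(in_stance, peak_force / profile.max() * profile, 0.0)
    if noise_sd > 0:
        grf = np.where(in_stance, grf + rng.normal(0, noise_sd, size=n), grf)
    grf = np.clip(grf, 0.0, None)
    # keep stance strictly positive so stance/swing structure survives noise
    grf[in_stance] = np.maximum(grf[in_stance], 1e-6)
    return ForceTrace(grf, t, domain="time", units="N", label="GRF")


@dataclass
class ConditionEffect:
    """Per-condition ground-truth effect on the five muscle envelopes.

    ``mav_multipliers`` scale each muscle's whole envelope (and hence its
    mean absolute value); ``peak_multipliers`` additionally scale the
    envelope's dominant bump, sharpening or flattening the peak.  The
    no-exosuit baseline (NE) must have all multipliers equal to 1.
    """

    condition: str
    mav_multipliers: dict[str, float] = field(
        default_factory=lambda: {m: 1.0 for m in MUSCLES})
    peak_multipliers: dict[str, float] = field(
        default_factory=lambda: {m: 1.0 for m in MUSCLES})
    step_duration: float = 1.333  # s

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise SyntheticDataError(f"unknown condition {self.condition!r}")
        for d in (self.mav_multipliers, self.peak_multipliers):
            for m in MUSCLES:
                if d.get(m, 1.0) <= 0:
                    raise SyntheticDataError("multipliers must be > 0")
        if self.condition == "NE":
            for d in (self.mav_multipliers, self.peak_multipliers):
                if any(abs(d.get(m, 1.0) - 1.0) > 1e-12 for m in MUSCLES):
                    raise SyntheticDataError("NE multipliers must all be 1")
        if self.step_duration <= 0:
            raise SyntheticDataError("step_duration must be > 0")


def default_condition_effects(protocol: str = "slow") -> list[ConditionEffect]:
    """Qualitative default effects for the four conditions.

    Directions follow the observed pattern at slow speed: both controllers
    reduce posterior-chain activity (HAM, GAS, SOL for the empirical
    controller; HAM, GAS for the learned one) and raise anterior activity
    (RF, VAS), with the learned controller also raising SOL.  Step
    durations come from the per-protocol defaults.
    """
    durations = SLOW_STEP_DURATIONS if protocol == "slow" else PWS_STEP_DURATIONS
    eff = {
        "NE": {m: 1.0 for m in MUSCLES},
        "NC": {m: 1.05 for m in MUSCLES},  # extra suit weight, no assistance
        "Emp": {"HAM": 0.80, "RF": 1.08, "VAS": 1.05, "GAS": 0.88, "SOL": 0.95},
        "RL": {"HAM": 0.85, "RF": 1.15, "VAS": 1.20, "GAS": 0.90, "SOL": 1.10},
    }
    return [
        ConditionEffect(
            condition=c,
            mav_multipliers=dict(eff[c]),
            peak_multipliers=dict(eff[c]),
            step_duration=durations[c],
        )
        for c in CONDITIONS
    ]


# base sEMG envelope templates: (center, width, weight) bumps per muscle,
# reflecting standard activation timing over the gait cycle
_EMG_BUMPS = {
    "HAM": [(0.02, 0.06, 1.0), (0.92, 0.06, 0.9)],
    "RF": [(0.08, 0.06, 1.0), (0.62, 0.05, 0.7)],
    "VAS": [(0.12, 0.08, 1.0)],
    "GAS": [(0.42, 0.09, 1.0)],
    "SOL": [(0.45, 0.10, 1.0)],
}


def emg_template(muscle: str, phi: np.ndarray) -> np.ndarray:
    """Normalized base envelope (max 1) of one muscle over the cycle."""
    if muscle not in _EMG_BUMPS:
        raise SyntheticDataError(f"unknown muscle {muscle!r}")
    out = np.zeros_like(phi)
    for c, w, a in _EMG_BUMPS[muscle]:
        out += a * _wrapped_bump(phi, c, w)
    out += 0.05  # tonic floor
    return out / out.max()


@dataclass
class SubjectRecord:
    subject_id: int
    condition: str
    envelopes: dict[str, ForceTrace]  # per muscle, time domain, a.u.
    grf: ForceTrace
    rate: float  # Hz


@dataclass
class EMGDataset:
    """Per-subject, per-condition envelope + GRF recordings.

    ``ground_truth`` stores the injected multipliers and per-subject
    factors so the analysis stage can be checked for parameter recovery.
    """

    records: list[SubjectRecord]
    ground_truth: dict

    def get(self, subject_id: int, condition: str) -> SubjectRecord:
        for r in self.records:
            if r.subject_id == subject_id and r.condition == condition:
                return r
        raise KeyError((subject_id, condition))

    @property
    def n_subjects(self) -> int:
        return len({r.subject_id for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: subject_id, condition, channel, time_s, value."""
        parts = []
        for r in self.records:
            for muscle, tr in r.envelopes.items():
                parts.append(pd.DataFrame({
                    "subject_id": r.subject_id, "condition": r.condition,
                    "channel": muscle, "time_s": tr.grid, "value": tr.values,
                }))
            parts.append(pd.DataFrame({
                "subject_id": r.subject_id, "condition": r.condition,
                "channel": "GRF", "time_s": r.grf.grid, "value": r.grf.values,
            }))
        return pd.concat(parts, ignore_index=True)


def make_emg_dataset(
    n_subjects: int = 4,
    effects: list[ConditionEffect] | None = None,
    n_steps: int = 12,
    rate: float = 100.0,
    noise_sd: float = 0.0,
    subject_sd: float = 0.2,
    seed: int = 0,
) -> EMGDataset:
    """Generate a full four-condition, five-muscle synthetic sEMG dataset.

    Each subject's envelope for a muscle is::

        base template tiled over steps x condition MAV multiplier
        x subject lognormal factor + Gaussian noise, clamped at 0

    The subject factor is shared across conditions, so relative (percent)
    changes against the NE baseline are unaffected by it — mirroring how
    within-subject normalization works in practice.
    """
    if n_subjects < 1:
        raise SyntheticDataError("n_subjects must be >= 1")
    effects = effects if effects is not None else default_condition_effects()
    by_cond = {e.condition: e for e in effects}
    missing = set(CONDITIONS) - set(by_cond)
    if missing:
        raise SyntheticDataError(f"missing conditions: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    subject_factors = {
        m: np.exp(rng.normal(0.0, subject_sd, size=n_subjects)) for m in MUSCLES
    }
    records: list[SubjectRecord] = []
    for s in range(n_subjects):
        for cond in CONDITIONS:
            e = by_cond[cond]
            grf = make_grf_trace(
                e.step_duration, n_steps, noise_sd=0.0,
                seed=int(rng.integers(2**31)), rate=rate)
            n_per = int(round(e.step_duration * rate))
            t = grf.grid
            phase = (np.arange(len(t)) % n_per) / n_per
            envs = {}
            for m in MUSCLES:
                base = emg_template(m, phase)
                peak_m = e.peak_multipliers.get(m, 1.0)
                mav_m = e.mav_multipliers.get(m, 1.0)
                # peak multiplier reshapes the dominant bump on top of the
                # overall MAV scaling
                c0, w0, _ = _EMG_BUMPS[m][0]
                shaped = base * (1.0 + (peak_m / mav_m - 1.0)
                                 * _wrapped_bump(phase, c0, w0))
                env = shaped * mav_m * subject_factors[m][s]
                if noise_sd > 0:
                    env = env + rng.normal(0.0, noise_sd, size=env.shape)
                envs[m] = ForceTrace(np.clip(env, 0.0, None), t,
                                     domain="time", units="a.u.", label=m)
            records.append(SubjectRecord(s, cond, envs, grf, rate))
    gt = {
        "mav_multipliers": {c: dict(by_cond[c].mav_multipliers) for c in CONDITIONS},
        "peak_multipliers": {c: dict(by_cond[c].peak_multipliers) for c in CONDITIONS},
        "step_durations": {c: by_cond[c].step_duration for c in CONDITIONS},
        "subject_factors": {m: subject_factors[m].tolist() for m in MUSCLES},
        "noise_sd": noise_sd, "subject_sd": subject_sd, "seed": seed,
    }
    return EMGDataset(records=records, ground_truth=gt)


def write_dataset(dataset: EMGDataset, out_dir: str | Path) -> None:
    """Write long-format CSV + JSON ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.to_frame().to_csv(out / "emg_dataset.csv", index=False)
    (out / "ground_truth.json").write_text(
        json.dumps(dataset.ground_truth, indent=1))


@dataclass
class ProtocolSubject:
    """Simulated subject for the treadmill speed protocol.

    ``is_running(speed)`` reports whether the subject has transitioned to
    running at the queried treadmill speed; ``comfort_feedback(speed)``
    returns +1 ("faster is more comfortable") when the speed is below the
    subject's true preferred walking speed and -1 above it, with optional
    noise near the preference.
    """

    true_pws: float
    true_pts: float
    comfort_noise: float = 0.0
    seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.true_pws < self.true_pts):
            raise SyntheticDataError("need 0 < true_pws < true_pts")
        self._rng = np.random.default_rng(self.seed)

    def is_running(self, speed: float) -> bool:
        return speed >= self.true_pts

    def comfort_feedback(self, speed: float) -> int:
        delta = self.true_pws - speed
        if self.comfort_noise > 0:
            delta = delta + self._rng.normal(0.0, self.comfort_noise)
        return 1 if delta > 0 else -1


def make_protocol_subject(
    true_pws: float, true_pts: float, comfort_noise: float = 0.0, seed: int = 0,
) -> ProtocolSubject:
    return ProtocolSubject(true_pws, true_pts, comfort_noise, seed)
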