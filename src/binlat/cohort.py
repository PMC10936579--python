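"""Synthetic control and patient cohorts.

Generates lateralization sessions, tone-in-noise observers with their
adaptive tracks, and audiograms for a control cohort plus patient
archetypes spanning the clinically observed response repertoire: laterally
shifted listeners, side-oriented listeners who hear even small cues at the
ears, high-variability responders, and left-right confusers.  Patient
archetypes carry per-phase severity trajectories (recovering,
deteriorating, stable), so the longitudinal stages of the pipeline are
exercisable end to end without any real data.

Randomness is fully seeded.  Every participant x phase x purpose draws
from its own stream derived from the master seed by hashing the
``participant_id|phase|purpose`` string into a ``numpy`` ``SeedSequence``,
so adding participants never perturbs existing ones.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .schema import (
    DEFAULT_PHASE_ORDER,
    ILD_SPAN_DB,
    ITD_SPAN_US,
    AudiogramRecord,
    LateralizationSession,
    StimulusDescriptor,
    Trial,
    full_design,
)
from .thresholds import (
    PTA3_FREQUENCIES,
    ToneInNoiseObserver,
    TrackRecord,
    run_staircase,
)


@dataclass(frozen=True)
class ListenerModel:
    """Generative parameters of one synthetic listener.

    The latent percept for a cue ``c`` of family span ``S`` (600 µs or
    12 dB) is ``5 + 4 * gain * clamp(c / S, -1, 1) + bias``; extreme
    +-1500 µs ITDs run through the same saturating map.  Side-oriented
    listeners instead push every nonzero cue to ``5 +- 4 * gain``.  With
    probability ``confusion_prob`` a lateralized percept is mirrored about
    key 5 (``extreme_confusion_prob`` applies to the +-1500 µs stimuli).
    The button press is ``clamp(round(percept + noise), 1, 9)``.
    """

    gain_itd: float = 1.0
    gain_ild: float = 1.0
    bias: float = 0.0  # keys; positive = rightward shift
    itd_saturation: float = ITD_SPAN_US  # µs
    response_noise_sd: float = 0.0  # keys
    confusion_prob: float = 0.0
    extreme_confusion_prob: float = 0.0
    side_oriented: bool = False
    mono_left_target: float = 1.0
    mono_right_target: float = 9.0

    def __post_init__(self) -> None:
        if self.gain_itd < 0 or self.gain_ild < 0:
            raise ValueError("gains must be >= 0")
        if not (0 <= self.confusion_prob <= 1 and 0 <= self.extreme_confusion_prob <= 1):
            raise ValueError("confusion probabilities must lie in [0, 1]")
        if self.response_noise_sd < 0:
            raise ValueError("response_noise_sd must be >= 0")

    def mirrored(self) -> "ListenerModel":
        """Model whose generated sessions mirror this one's statistically."""
        return replace(
            self,
            bias=-self.bias,
            mono_left_target=10.0 - self.mono_right_target,
            mono_right_target=10.0 - self.mono_left_target,
        )

    def latent_percept(self, stimulus: StimulusDescriptor) -> float:
        if stimulus.cue_type == "mono_left":
            return self.mono_left_target
        if stimulus.cue_type == "mono_right":
            return self.mono_right_target
        if stimulus.cue_type == "diotic":
            return 5.0 + self.bias
        cue = stimulus.cue_value
        if stimulus.cue_type == "itd":
            gain, span = self.gain_itd, self.itd_saturation
        else:
            gain, span = self.gain_ild, ILD_SPAN_DB
        if self.side_oriented and cue != 0:
            return 5.0 + np.sign(cue) * 4.0 * gain + self.bias
        sat = float(np.clip(cue / span, -1.0, 1.0))
        return 5.0 + 4.0 * gain * sat + self.bias

    def _confusion_prob_for(self, stimulus: StimulusDescriptor) -> float:
        if stimulus.cue_type == "itd" and abs(stimulus.cue_value) > ITD_SPAN_US:
            return max(self.confusion_prob, self.extreme_confusion_prob)
        if stimulus.cue_type in ("itd", "ild") and stimulus.cue_value != 0:
            return self.confusion_prob
        return 0.0

    def respond(self, stimulus: StimulusDescriptor, rng: np.random.Generator) -> int:
        p = self.latent_percept(stimulus)
        if rng.random() < self._confusion_prob_for(stimulus):
            p = 10.0 - p
        if self.response_noise_sd > 0:
            p = p + rng.normal(0.0, self.response_noise_sd)
        return int(np.clip(np.rint(p), 1, 9))


def simulate_session(
    model: ListenerModel,
    rng: np.random.Generator,
    participant_id: str = "SYN",
    group: str = "control",
    phase: str = "control",
) -> LateralizationSession:
    """One complete randomized session (6 per non-diotic stimulus, 8 diotic)."""
    schedule: list[StimulusDescriptor] = []
    for stim, n in full_design():
        schedule.extend([stim] * n)
    order = rng.permutation(len(schedule))
    counts: dict[tuple[str, float | None], int] = {}
    trials: list[Trial] = []
    for i in order:
        stim = schedule[i]
        counts[stim.key] = counts.get(stim.key, 0) + 1
        trials.append(Trial(stim, counts[stim.key], model.respond(stim, rng)))
    return LateralizationSession(participant_id, group, phase, trials)


# --- cohort specification --------------------------------------------------

#: Archetype parameter deltas applied on top of a control-like base model,
#: scaled by the phase's severity.
DEFAULT_ARCHETYPES: dict[str, dict] = {
    "shifted_right": {"bias": 2.0},
    "shifted_left": {"bias": -2.0},
    "side_oriented": {"side_oriented": True, "extreme_confusion_prob": 0.5},
    "high_variability": {"response_noise_sd": 1.5},
    "confuser": {"confusion_prob": 0.3},
}

#: Severity per phase (acute, subacute, chronic).
DEFAULT_TRAJECTORIES: dict[str, tuple[float, ...]] = {
    "recovering": (1.0, 0.5, 0.1),
    "deteriorating": (0.3, 0.65, 1.0),
    "stable": (1.0, 1.0, 1.0),
}

#: Control-listener jitter and observer/audiogram conventions.  Chosen so
#: control metric spreads resemble a healthy cohort; these are synthetic
#: conventions, not measured quantities.
DEFAULT_CONFIG: dict = {
    "control_jitter": {
        "gain_rel": 0.10,
        "bias_sd": 0.3,
        "noise_lo": 0.4,
        "noise_hi": 0.8,
    },
    "observer": {
        "mu_n0s0_mean": 57.0,
        "mu_n0s0_sd": 2.0,
        "control_bmld_lo": 10.0,
        "control_bmld_hi": 16.0,
        "patient_bmld_base": 13.0,
        "patient_bmld_severity_drop": 6.0,
        "sigma_lo": 3.0,
        "sigma_hi": 5.0,
    },
    "audiogram": {
        "control_pta3_mean": 12.0,
        "control_pta3_sd": 4.0,
        "patient_pta3_mean": 18.0,
        "patient_pta3_sd": 5.0,
        "asymmetry_sd": 3.0,
        "within_ear_sd": 4.0,
    },
    "archetypes": DEFAULT_ARCHETYPES,
    "trajectories": DEFAULT_TRAJECTORIES,
}


@dataclass(frozen=True)
class PatientSpec:
    archetype: str
    count: int
    trajectory: str = "recovering"


@dataclass
class CohortSpec:
    n_controls: int = 12
    patients: list[PatientSpec] = field(
        default_factory=lambda: [
            PatientSpec("shifted_right", 1, "recovering"),
            PatientSpec("side_oriented", 1, "recovering"),
            PatientSpec("high_variability", 1, "recovering"),
            PatientSpec("confuser", 1, "deteriorating"),
            PatientSpec("shifted_left", 1, "deteriorating"),
            PatientSpec("side_oriented", 1, "stable"),
        ]
    )
    phases: tuple[str, ...] = DEFAULT_PHASE_ORDER
    seed: int = 0
    config: dict = field(default_factory=lambda: DEFAULT_CONFIG)

    def __post_init__(self) -> None:
        if self.n_controls < 4:
            raise ValueError("n_controls >= 4 required")
        for p in self.patients:
            if p.archetype not in self.config["archetypes"]:
                raise ValueError(f"unknown archetype {p.archetype!r}")
            if p.trajectory not in self.config["trajectories"]:
                raise ValueError(f"unknown trajectory {p.trajectory!r}")


@dataclass
class Cohort:
    """Everything the pipeline consumes, for all participants and phases."""

    sessions: list[LateralizationSession]
    observers: dict[tuple[str, str], ToneInNoiseObserver]
    tracks: dict[tuple[str, str], list[TrackRecord]]
    audiograms: list[AudiogramRecord]
    models: dict[tuple[str, str], ListenerModel]


def derive_rng(seed: int, participant_id: str, phase: str, purpose: str) -> np.random.Generator:
    """Per-participant stream: sha256 of ``pid|phase|purpose`` + master seed."""
    digest = hashlib.sha256(f"{participant_id}|{phase}|{purpose}".encode()).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def _control_model(rng: np.random.Generator, jitter: dict) -> ListenerModel:
    g = jitter["gain_rel"]
    return ListenerModel(
        gain_itd=float(rng.uniform(1 - g, 1 + g)),
        gain_ild=float(rng.uniform(1 - g, 1 + g)),
        bias=float(rng.normal(0.0, jitter["bias_sd"])),
        response_noise_sd=float(rng.uniform(jitter["noise_lo"], jitter["noise_hi"])),
    )


def archetype_model(
    archetype: str, severity: float, base: ListenerModel, config: dict
) -> ListenerModel:
    """Apply an archetype's parameter deltas, scaled by severity, to a base."""
    deltas = config["archetypes"][archetype]
    kwargs: dict = {}
    for name, value in deltas.items():
        if name == "side_oriented":
            kwargs[name] = bool(value) and severity >= 0.5
        elif name == "response_noise_sd":
            kwargs[name] = base.response_noise_sd + (value - base.response_noise_sd) * severity
        elif name == "bias":
            kwargs[name] = base.bias + value * severity
        else:  # probabilities scale linearly with severity
            kwargs[name] = value * severity
    return replace(base, **kwargs)


def _observer_for(
    rng: np.random.Generator, severity: float, is_control: bool, cfg: dict
) -> ToneInNoiseObserver:
    mu0 = float(rng.normal(cfg["mu_n0s0_mean"], cfg["mu_n0s0_sd"]))
    if is_control:
        bmld = float(rng.uniform(cfg["control_bmld_lo"], cfg["control_bmld_hi"]))
    else:
        bmld = max(
            0.0,
            cfg["patient_bmld_base"]
            - cfg["patient_bmld_severity_drop"] * severity
            + float(rng.normal(0.0, 1.5)),
        )
    sigma = float(rng.uniform(cfg["sigma_lo"], cfg["sigma_hi"]))
    return ToneInNoiseObserver(mu_n0s0=mu0, mu_n0spi=mu0 - bmld, sigma=sigma)


def _audiogram_for(
    rng: np.random.Generator, pid: str, phase: str, is_control: bool, cfg: dict
) -> list[AudiogramRecord]:
    mean = cfg["control_pta3_mean"] if is_control else cfg["patient_pta3_mean"]
    sd = cfg["control_pta3_sd"] if is_control else cfg["patient_pta3_sd"]
    pta = float(rng.normal(mean, sd))
    asym = float(rng.normal(0.0, cfg["asymmetry_sd"]))
    records = []
    for ear, ear_mean in (("left", pta + asym / 2), ("right", pta - asym / 2)):
        for f in PTA3_FREQUENCIES:
            thr = round(ear_mean + float(rng.normal(0.0, cfg["within_ear_sd"])))
            records.append(AudiogramRecord(pid, phase, ear, f, max(-10.0, thr)))
    return records


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Generate all sessions, observers, staircase tracks, and audiograms."""
    cfg = spec.config
    sessions: list[LateralizationSession] = []
    observers: dict[tuple[str, str], ToneInNoiseObserver] = {}
    tracks: dict[tuple[str, str], list[TrackRecord]] = {}
    audiograms: list[AudiogramRecord] = []
    models: dict[tuple[str, str], ListenerModel] = {}

    roster: list[tuple[str, str, str | None, str | None]] = []
    for i in range(spec.n_controls):
        roster.append((f"C{i + 1:02d}", "control", None, None))
    idx = 0
    for pspec in spec.patients:
        for _ in range(pspec.count):
            idx += 1
            roster.append((f"P{idx:02d}", "patient", pspec.archetype, pspec.trajectory))

    for pid, group, archetype, trajectory in roster:
        phases = ("control",) if group == "control" else spec.phases
        for k, phase in enumerate(phases):
            if group == "control":
                severity = 0.0
                model = _control_model(
                    derive_rng(spec.seed, pid, phase, "model"), cfg["control_jitter"]
                )
            else:
                severity = cfg["trajectories"][trajectory][k]
                base = _control_model(
                    derive_rng(spec.seed, pid, "base", "model"), cfg["control_jitter"]
                )
                model = archetype_model(archetype, severity, base, cfg)
            models[(pid, phase)] = model
            sessions.append(
                simulate_session(
                    model, derive_rng(spec.seed, pid, phase, "session"), pid, group, phase
                )
            )
            observer = _observer_for(
                derive_rng(spec.seed, pid, phase, "observer"),
                severity,
                group == "control",
                cfg["observer"],
            )
            observers[(pid, phase)] = observer
            stair_rng = derive_rng(spec.seed, pid, phase, "staircase")
            runs = [
                run_staircase(observer, "N0Spi", stair_rng, run_index=1),
                run_staircase(observer, "N0Spi", stair_rng, run_index=2),
                run_staircase(observer, "N0S0", stair_rng, run_index=1),
            ]
            tracks[(pid, phase)] = runs
            audiograms.extend(
                _audiogram_for(
                    derive_rng(spec.seed, pid, phase, "audiogram"),
                    pid,
                    phase,
                    group == "control",
                    cfg["audiogram"],
                )
            )
    return Cohort(sessions, observers, tracks, audiograms, models)


def parameter_recovery_check(model: ListenerModel, metrics) -> dict[str, dict[str, float]]:
    """Compare injected generative parameters with metric-level readouts.

    * bias        ~ diotic percept - 5
    * gain_ild    ~ mean ILD side slope x 3   (full-range slope = 4 g / 12)
    * gain_itd    ~ mean ITD side slope x 150 (full-range slope = 4 g / 600)
    * noise sd    ~ family mean per-stimulus std, corrected for the variance
      added by rounding to integer keys (~ uniform, variance 1/12)
    """
    rec_bias = metrics["diotic_percept"] - 5.0
    rec_gain_ild = (metrics["ild_l_slope"] + metrics["ild_r_slope"]) / 2.0 * 3.0
    rec_gain_itd = (metrics["itd_l_slope"] + metrics["itd_r_slope"]) / 2.0 * 150.0
    mean_std = (metrics["itd_std"] + metrics["ild_std"]) / 2.0
    rec_noise = float(np.sqrt(max(mean_std**2 - 1.0 / 12.0, 0.0)))
    report = {
        "bias": {"injected": model.bias, "recovered": rec_bias},
        "gain_ild": {"injected": model.gain_ild, "recovered": rec_gain_ild},
        "gain_itd": {"injected": model.gain_itd, "recovered": rec_gain_itd},
        "response_noise_sd": {"injected": model.response_noise_sd, "recovered": rec_noise},
    }
    for entry in report.values():
        entry["abs_error"] = abs(entry["recovered"] - entry["injected"])
    return report
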