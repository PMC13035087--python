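"""Synthetic fNIRS cohorts with exported ground truth.

The forward model is the exact inverse of the preprocessing chain: planted
per-channel condition amplitudes (uM HbO) scale the same peak-normalized
HRF-convolved boxcars the GLM uses; shared band-limited components plant
channel-pair coactivation; physiological oscillations (cardiac,
respiratory, Mayer waves), linear drift, and white noise are added in
concentration units; HbR is the scaled hemodynamic counterpart of HbO; the
modified Beer-Lambert law maps concentrations to optical density with the
same extinction table and age-adjusted DPF the pipeline inverts; and raw
intensities are ``baseline * exp(-OD)``. Motion artifacts (spikes and
baseline shifts) are injected in OD units.

With all noise amplitudes and the artifact rate at zero, running the full
pipeline on the output recovers the planted betas to numerical precision —
the round-trip contract every recovery test relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .hemodynamics import HrfParams, condition_regressor
from .optics import DEFAULT_PATHLENGTH_CM, ExtinctionTable, mbll_forward
from .preprocess import N_CHANNELS, RawRecording
from .protocol import (
    CONDITION_DISTRACTION,
    CONDITIONS,
    TaskDesign,
    make_protocol,
)

logger = logging.getLogger(__name__)

HBR_RATIO = -1.0 / 3.0  # canonical HbR counterpart of a planted HbO response


@dataclass(frozen=True)
class SharedComponent:
    """A latent signal mixed into a set of channels to plant coactivation.

    ``condition`` restricts the component to that condition's span
    (state-related coactivation); None means the whole record.
    """

    channels: tuple[int, ...]          # 1-based channel ids
    weight: float                      # mixing amplitude, uM
    condition: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight):
            raise InvalidParameterError("mixing weight must be finite")
        if any(not 1 <= c <= N_CHANNELS for c in self.channels):
            raise InvalidParameterError(f"channels out of range: {self.channels}")


@dataclass
class NeuralTruth:
    """Planted activation amplitudes and coactivation structure."""

    beta: np.ndarray                               # (8, n_conditions), uM
    conditions: tuple[str, ...] = CONDITIONS
    shared_components: list[SharedComponent] = field(default_factory=list)
    hrf_params: HrfParams = field(default_factory=HrfParams)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (N_CHANNELS, len(self.conditions)):
            raise InvalidParameterError(
                f"beta must be ({N_CHANNELS}, {len(self.conditions)}); "
                f"got {self.beta.shape}"
            )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive physiological noise (uM) and OD-domain motion artifacts."""

    cardiac: tuple[float, float] = (1.1, 0.3)      # (Hz, uM)
    respiratory: tuple[float, float] = (0.25, 0.2)
    mayer: tuple[float, float] = (0.1, 0.3)
    drift_slope: float = 0.002                     # uM/s
    white_sd: float = 0.15                         # uM
    artifact_rate: float = 0.5                     # events/minute
    artifact_amplitude: float = 0.3                # OD units
    phase_jitter: float = 0.3                      # rad/sqrt(s): oscillations
                                                   # are quasi-periodic, so
                                                   # their phase random-walks
                                                   # and channels decorrelate

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        for name in ("cardiac", "respiratory", "mayer"):
            f, a = getattr(self, name)
            if a < 0:
                raise InvalidParameterError(f"{name} amplitude must be >= 0")
            if a > 0 and f >= nyq:
                raise InvalidParameterError(
                    f"{name} frequency {f} Hz >= Nyquist {nyq} Hz"
                )
        if self.white_sd < 0 or self.artifact_rate < 0 or self.artifact_amplitude < 0:
            raise InvalidParameterError("noise magnitudes must be >= 0")


QUIET = NoiseSpec(cardiac=(1.1, 0.0), respiratory=(0.25, 0.0), mayer=(0.1, 0.0),
                  drift_slope=0.0, white_sd=0.0, artifact_rate=0.0)


@dataclass(frozen=True)
class InstrumentSpec:
    name: str
    lo: float
    hi: float
    pre_mean: float
    pre_sd: float
    change_mean: float   # planted pre->post mean change, instrument units
    change_sd: float

    def __post_init__(self) -> None:
        if self.hi <= self.lo:
            raise InvalidParameterError(f"{self.name}: bad scale range")


# Default battery: ranges per the validated instruments; planted changes and
# change SDs follow the magnitudes a subacute-pain VR cohort shows (change_sd
# = |MD|/d for the reported paired effect sizes).
DEFAULT_INSTRUMENTS = (
    InstrumentSpec("NRS-rest", 0, 10, 5.5, 1.8, -2.50, 1.12),
    InstrumentSpec("NRS-activity", 0, 10, 7.0, 1.8, -3.40, 1.72),
    InstrumentSpec("DVPRS-activity", 0, 10, 6.5, 1.8, -4.90, 2.13),
    InstrumentSpec("DVPRS-sleep", 0, 10, 5.5, 2.0, -3.90, 2.95),
    InstrumentSpec("DVPRS-mood", 0, 10, 5.5, 2.0, -4.40, 2.40),
    InstrumentSpec("DVPRS-stress", 0, 10, 5.5, 2.0, -4.30, 2.40),
    InstrumentSpec("PCS-13", 0, 52, 30.0, 6.0, -16.40, 7.70),
    InstrumentSpec("PASS-20", 0, 100, 55.0, 10.0, -32.70, 15.28),
    InstrumentSpec("PSEQ", 0, 60, 30.0, 8.0, 15.40, 10.20),
    InstrumentSpec("CAMS-R", 12, 48, 30.0, 4.0, 3.29, 3.50),
    InstrumentSpec("MOCS", 0, 52, 25.0, 5.0, 0.59, 0.58),
)


@dataclass(frozen=True)
class BrainBehaviorLink:
    """Planted correlation between a neural change score and an instrument."""

    condition: str = CONDITION_DISTRACTION
    channel: int = 4                      # right medial PFC
    instrument: str = "NRS-activity"
    r: float = 0.76

    def __post_init__(self) -> None:
        if abs(self.r) > 1:
            raise InvalidParameterError(f"|brain_behavior_r| = {abs(self.r)} > 1")


@dataclass
class BehavioralEffectSpec:
    instruments: tuple[InstrumentSpec, ...] = DEFAULT_INSTRUMENTS
    link: BrainBehaviorLink = field(default_factory=BrainBehaviorLink)


@dataclass
class CohortSubject:
    subject_id: str
    age: float
    time_since_injury_d: float
    injury_type: str
    pre: RawRecording | None
    post: RawRecording | None


@dataclass
class CohortDataset:
    subjects: list[CohortSubject]
    behavioral: pd.DataFrame     # subject, visit, instrument, score
    truth: dict                  # planted quantities for recovery tests
    design: TaskDesign
    seed: int
    session_log: pd.DataFrame | None = None   # subject, visit, condition, status


def default_truth(visit: str = "pre") -> NeuralTruth:
    """Population-mean planted effects mirroring the study's findings:
    post-treatment increases in right-medial activation (channel 4) during
    both VR conditions and stronger right-medial/left-lateral coactivation
    (pair (4,7)) during distraction."""
    beta = np.zeros((N_CHANNELS, len(CONDITIONS)))
    beta[:, 0] = 0.05   # noninjured movement: weak responses
    beta[:, 1] = 0.20   # injured movement: evoked-pain responses
    beta[:, 2] = 0.10   # relaxation
    beta[:, 3] = 0.10   # distraction
    shared = [SharedComponent((4, 7), 0.15, CONDITION_DISTRACTION)]
    if visit == "post":
        beta = beta.copy()
        beta[3, 2] += 0.15  # channel 4, relaxation
        beta[3, 3] += 0.15  # channel 4, distraction
        shared = [SharedComponent((4, 7), 0.45, CONDITION_DISTRACTION)]
    return NeuralTruth(beta=beta, shared_components=shared)


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance latent signal confined to the analysis passband."""
    from .preprocess import FilterParams, filter_timeseries

    x = rng.standard_normal(n)
    y = filter_timeseries(x, FilterParams(), fs)
    sd = y.std()
    return y / sd if sd > 0 else y


def simulate_subject(
    design: TaskDesign,
    truth: NeuralTruth,
    noise: NoiseSpec | None = None,
    age: float = 47.0,
    seed: int = 0,
    pathlength_cm: float = DEFAULT_PATHLENGTH_CM,
    extinction: ExtinctionTable | None = None,
    baseline_intensity: float = 1.0,
    subject_id: str = "S00",
    visit: str = "pre",
    corrupt_spans: list[tuple[float, float]] | None = None,
) -> RawRecording:
    """Synthesize one raw recording from planted truth.

    ``corrupt_spans`` injects dense large OD artifacts over the given spans
    (used to plant recordings that fail quality control).
    """
    ns = noise or NoiseSpec()
    fs = design.sampling_rate
    ns.validate(fs)
    rng = np.random.default_rng(seed)
    n = design.n_samples
    t = np.arange(n) / fs

    # task-evoked HbO: beta x peak-normalized HRF regressor
    hbo = np.zeros((N_CHANNELS, n))
    for k, cond in enumerate(truth.conditions):
        reg = condition_regressor(design, cond, truth.hrf_params)
        hbo += truth.beta[:, [k]] * reg[None, :]

    # planted coactivation
    for comp in truth.shared_components:
        s = _band_limited_noise(rng, n, fs)
        if comp.condition is not None:
            gate = design.sample_mask(comp.condition).astype(float)
            s = s * gate
        for ch in comp.channels:
            hbo[ch - 1] += comp.weight * s

    hbr = HBR_RATIO * hbo

    # quasi-periodic physiological noise: random initial phase per channel
    # plus a phase random walk (pure fixed-phase tones would correlate
    # across channels at cos(dphi) indefinitely, which real physiology
    # does not)
    jit = ns.phase_jitter / np.sqrt(fs)
    for f, a in (ns.cardiac, ns.respiratory, ns.mayer):
        if a > 0:
            for sig, amp in ((hbo, a), (hbr, 0.3 * a)):
                ph0 = rng.uniform(0, 2 * np.pi, N_CHANNELS)
                walk = np.cumsum(rng.normal(0, jit, (N_CHANNELS, n)), axis=1)
                sig += amp * np.sin(
                    2 * np.pi * f * t[None, :] + ph0[:, None] + walk
                )
    if ns.drift_slope != 0:
        slopes = ns.drift_slope * rng.uniform(0.5, 1.5, N_CHANNELS)
        hbo += slopes[:, None] * t[None, :]
        hbr += 0.3 * slopes[:, None] * t[None, :]
    if ns.white_sd > 0:
        hbo += rng.normal(0, ns.white_sd, hbo.shape)
        hbr += rng.normal(0, 0.3 * ns.white_sd, hbr.shape)

    od = mbll_forward(hbo, hbr, age, pathlength_cm, extinction)

    # motion artifacts in OD units: half spikes, half baseline shifts
    if ns.artifact_rate > 0:
        minutes = n / fs / 60.0
        for ch in range(N_CHANNELS):
            n_art = rng.poisson(ns.artifact_rate * minutes)
            for _ in range(n_art):
                i0 = rng.integers(0, n)
                amp = ns.artifact_amplitude * rng.choice([-1.0, 1.0])
                if rng.random() < 0.5:
                    w = int(round(0.3 * fs))
                    od[ch, :, i0 : i0 + w] += amp
                else:
                    w = int(round(rng.uniform(2.0, 5.0) * fs))
                    od[ch, :, i0 : i0 + w] += 0.5 * amp
    if corrupt_spans:
        for start, end in corrupt_spans:
            i0, i1 = int(start * fs), min(int(end * fs), n)
            step = max(int(round(1.5 * fs)), 1)
            for i in range(i0, i1, step):
                od[:, :, i : i + 2] += 1.0 * (1 if (i // step) % 2 == 0 else -1)

    intensity = baseline_intensity * np.exp(-od)
    return RawRecording(
        intensity=intensity, sampling_rate=fs, events=list(design.blocks),
        subject_age=age, subject_id=subject_id, visit=visit,
    )


def draw_cohort_effects(
    n_subjects: int,
    effect_spec: BehavioralEffectSpec,
    pre_truth: NeuralTruth,
    post_truth: NeuralTruth,
    seed: int,
    between_sd: float = 0.08,
    change_sd: float = 0.08,
) -> dict:
    """Per-subject planted betas, behavioral scores, and covariates.

    Subject pre betas vary around the pre population means; each cell's
    pre->post change is the population change plus subject noise. The linked
    behavioral instrument's change score is drawn jointly with the linked
    neural change score as a bivariate normal at the planted correlation,
    then scores are affine-clipped into instrument range (clipping fraction
    logged: clipping attenuates the planted r).
    """
    if n_subjects < 2:
        raise InvalidParameterError("n_subjects must be >= 2")
    link = effect_spec.link
    rng = np.random.default_rng(seed)
    conditions = pre_truth.conditions
    delta_pop = post_truth.beta - pre_truth.beta

    pre_betas = np.empty((n_subjects, N_CHANNELS, len(conditions)))
    post_betas = np.empty_like(pre_betas)
    for s in range(n_subjects):
        pre_betas[s] = pre_truth.beta + rng.normal(0, between_sd, pre_truth.beta.shape)
        post_betas[s] = pre_betas[s] + delta_pop + rng.normal(
            0, change_sd, delta_pop.shape
        )

    cond_idx = conditions.index(link.condition)
    neural_change = post_betas[:, link.channel - 1, cond_idx] - pre_betas[
        :, link.channel - 1, cond_idx
    ]
    mu_n = delta_pop[link.channel - 1, cond_idx]
    z = (neural_change - mu_n) / change_sd

    ages = np.clip(rng.normal(46.8, 11.86, n_subjects), 18.0, 80.0)
    time_since_injury = np.clip(rng.normal(38.4, 36.33, n_subjects), 3.0, None)
    injury_type = rng.choice(["fracture", "other"], size=n_subjects, p=[0.9, 0.1])

    rows = []
    n_clipped = 0
    n_scores = 0
    for spec in effect_spec.instruments:
        pre_scores = rng.normal(spec.pre_mean, spec.pre_sd, n_subjects)
        if spec.name == link.instrument:
            eps = rng.standard_normal(n_subjects)
            change = spec.change_mean + spec.change_sd * (
                link.r * z + np.sqrt(1 - link.r**2) * eps
            )
        else:
            change = rng.normal(spec.change_mean, spec.change_sd, n_subjects)
        post_scores = pre_scores + change
        for arr in (pre_scores, post_scores):
            n_clipped += int(np.sum((arr < spec.lo) | (arr > spec.hi)))
            n_scores += arr.size
        pre_scores = np.clip(pre_scores, spec.lo, spec.hi)
        post_scores = np.clip(post_scores, spec.lo, spec.hi)
        for s in range(n_subjects):
            rows.append((f"S{s:03d}", "pre", spec.name, float(pre_scores[s])))
            rows.append((f"S{s:03d}", "post", spec.name, float(post_scores[s])))
    clip_frac = n_clipped / max(n_scores, 1)
    if clip_frac > 0:
        logger.info("behavioral clipping fraction %.4f (attenuates planted r)",
                    clip_frac)
    behavioral = pd.DataFrame(rows, columns=["subject", "visit", "instrument", "score"])
    return {
        "pre_betas": pre_betas,
        "post_betas": post_betas,
        "neural_change": neural_change,
        "behavioral": behavioral,
        "ages": ages,
        "time_since_injury": time_since_injury,
        "injury_type": injury_type,
        "clip_fraction": clip_frac,
        "link": link,
        "conditions": conditions,
    }


def simulate_cohort(
    n_subjects: int = 10,
    effect_spec: BehavioralEffectSpec | None = None,
    pre_truth: NeuralTruth | None = None,
    post_truth: NeuralTruth | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    design: TaskDesign | None = None,
    signals: bool = True,
    missing: list[tuple[int, str, str]] | None = None,
    invalid: list[tuple[int, str, str]] | None = None,
) -> CohortDataset:
    """Paired pre/post cohort with behavioral table and exported truth.

    ``missing`` / ``invalid`` plant recording-level failures as
    (subject index, visit, condition) triples: missing conditions are logged
    as absent; invalid ones get their span corrupted with dense artifacts so
    quality control rejects them. ``signals=False`` skips raw-signal
    synthesis (betas and behavioral scores only) for statistical
    calibration at scale.
    """
    spec = effect_spec or BehavioralEffectSpec()
    pre_t = pre_truth or default_truth("pre")
    post_t = post_truth or default_truth("post")
    ns = noise or NoiseSpec()
    dsg = design or make_protocol()
    missing = missing or []
    invalid = invalid or []

    eff = draw_cohort_effects(n_subjects, spec, pre_t, post_t, seed)
    rng = np.random.default_rng(seed + 1)

    log_rows = []
    subjects: list[CohortSubject] = []
    for s in range(n_subjects):
        sid = f"S{s:03d}"
        recs: dict[str, RawRecording | None] = {"pre": None, "post": None}
        for visit, base in (("pre", pre_t), ("post", post_t)):
            truth_s = replace(
                base,
                beta=eff["pre_betas"][s] if visit == "pre" else eff["post_betas"][s],
            )
            corrupt = []
            for (si, vi, cond) in invalid:
                if si == s and vi == visit:
                    corrupt.append(dsg.condition_span(cond))
            if signals:
                recs[visit] = simulate_subject(
                    dsg, truth_s, ns, age=float(eff["ages"][s]),
                    seed=int(rng.integers(0, 2**31 - 1)),
                    subject_id=sid, visit=visit, corrupt_spans=corrupt or None,
                )
            for cond in dsg.condition_labels:
                if (s, visit, cond) in missing:
                    status = "missing"
                elif (s, visit, cond) in invalid:
                    status = "invalid"
                else:
                    status = "valid"
                log_rows.append((sid, visit, cond, status))
        subjects.append(CohortSubject(
            subject_id=sid, age=float(eff["ages"][s]),
            time_since_injury_d=float(eff["time_since_injury"][s]),
            injury_type=str(eff["injury_type"][s]),
            pre=recs["pre"], post=recs["post"],
        ))

    truth = {
        "pre_truth": pre_t,
        "post_truth": post_t,
        "pre_betas": eff["pre_betas"],
        "post_betas": eff["post_betas"],
        "neural_change": eff["neural_change"],
        "link": eff["link"],
        "clip_fraction": eff["clip_fraction"],
        "noise": ns,
    }
    session_log = pd.DataFrame(
        log_rows, columns=["subject", "visit", "condition", "status"]
    )
    return CohortDataset(
        subjects=subjects, behavioral=eff["behavioral"], truth=truth,
        design=dsg, seed=seed, session_log=session_log,
    )
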