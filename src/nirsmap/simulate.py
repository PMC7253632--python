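"""Synthetic fNIRS cohorts with controlled group effects.

The generator emulates the statistical structure of a task-based prefrontal
fNIRS study: two groups of subjects (cognitively impaired and healthy
controls) perform blocked cognitive tasks (60 s task, 30 s rest, three
trials per task) while 48 channels are sampled at 8.138 Hz.  Each active
channel carries a haemodynamic response — the canonical double-gamma HRF
convolved with the task boxcar — whose peak amplitude is reduced in the
impaired group by a configurable factor, on top of cardiac (~1 Hz),
respiratory (~0.25 Hz) and Mayer-wave (~0.1 Hz) oscillations, slow linear
drift and white noise.  Ground-truth amplitudes and activation flags are
stored so recovery can be tested downstream.

All randomness derives deterministically from ``CohortSpec.seed`` via
per-(stage, subject, task) seed sequences: identical specs yield
bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hrf import HRFParams, task_response
from .preprocess import HemoSeries, MbllParams, OpticalRecording, forward_mbll

__all__ = [
    "NoiseSpec",
    "CohortSpec",
    "SyntheticDataset",
    "generate_noise",
    "generate_channel_signal",
    "generate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

# Stage codes for deterministic seed derivation.
_STAGE_AMPLITUDE = 1
_STAGE_RECORDING = 2


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model for a single channel (amplitudes in uM)."""

    cardiac_hz: float = 1.0
    cardiac_amp: float = 0.3
    respiration_hz: float = 0.25
    respiration_amp: float = 0.2
    mayer_hz: float = 0.1
    mayer_amp: float = 0.15
    drift_slope: float = 0.002  # uM per second
    white_sd: float = 0.1
    random_phase: bool = True

    def __post_init__(self) -> None:
        for name in ("cardiac_amp", "respiration_amp", "mayer_amp", "white_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("cardiac_hz", "respiration_hz", "mayer_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def max_frequency(self) -> float:
        return max(self.cardiac_hz, self.respiration_hz, self.mayer_hz)

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(cardiac_amp=0.0, respiration_amp=0.0, mayer_amp=0.0,
                   drift_slope=0.0, white_sd=0.0)

    @classmethod
    def low(cls) -> "NoiseSpec":
        """Weak noise: residual in-band power after the 0.001-0.1 Hz
        band-pass sits well below the response-induced signal, so every
        temporal feature of an active channel is signal-dominated.  (The
        white-noise floor matters most here: band-pass filtering folds it
        entirely into the analysis band.)"""
        return cls(cardiac_amp=0.01, respiration_amp=0.008, mayer_amp=0.004,
                   drift_slope=0.0002, white_sd=0.005)


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    The defaults mirror the clinical protocol the package targets:
    15 impaired subjects and 9 controls, three tasks of three 60 s + 30 s
    trials each, 48 channels at 8.138 Hz, and a control-group peak dHbO of
    0.5 uM.  ``amplitude_ratio_impaired`` scales the impaired group's
    response amplitude (1.0 makes the two groups generatively identical);
    its 0.6 default is a free effect-size parameter, not an estimate.
    Per-(subject, channel) amplitudes are jittered log-normally with
    ``amplitude_jitter_sigma`` so that GLM thresholding on noisy data
    yields partial activation tables rather than all-or-nothing ones.
    """

    n_impaired: int = 15
    n_control: int = 9
    n_trials_per_task: int = 3
    tasks: tuple[str, ...] = ("n_back", "stroop", "vft")
    n_channels: int = 48
    fs: float = 8.138
    task_duration_s: float = 60.0
    rest_duration_s: float = 30.0
    lead_in_s: float = 5.0
    amplitude_control: float = 0.5
    amplitude_ratio_impaired: float = 0.6
    amplitude_jitter_sigma: float = 0.4
    hbr_anticorrelation: float = 0.3
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    hrf: HRFParams = field(default_factory=HRFParams)
    simulate_od: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_impaired < 0 or self.n_control < 0:
            raise ValueError("group sizes must be nonnegative")
        if self.n_impaired + self.n_control < 1:
            raise ValueError("cohort must contain at least one subject")
        if not 0.0 <= self.amplitude_ratio_impaired <= 1.0:
            raise ValueError("amplitude_ratio_impaired must lie in [0, 1]")
        if self.fs <= 2 * self.noise.max_frequency():
            raise ValueError("fs must exceed twice the highest noise frequency")
        if self.n_trials_per_task < 1 or self.n_channels < 1:
            raise ValueError("need at least one trial and one channel")

    @property
    def trial_duration_s(self) -> float:
        return self.task_duration_s + self.rest_duration_s

    @property
    def epoch_samples(self) -> int:
        return int(np.floor(self.trial_duration_s * self.fs))

    def recording_duration_s(self) -> float:
        return self.lead_in_s + self.n_trials_per_task * self.trial_duration_s

    def onsets_s(self) -> list[float]:
        return [self.lead_in_s + i * self.trial_duration_s
                for i in range(self.n_trials_per_task)]


@dataclass
class SyntheticDataset:
    """A generated cohort: recordings plus ground truth.

    ``recordings`` maps (subject, task) to a continuous :class:`HemoSeries`
    (and optionally an :class:`OpticalRecording` in ``optical``);
    ``amplitudes`` holds the per-(subject, channel) ground-truth response
    amplitudes and ``active`` the activation flags used to build them.
    """

    spec: CohortSpec
    subjects: list[str]
    groups: dict[str, str]
    channel_ids: list[str]
    recordings: dict[tuple[str, str], HemoSeries]
    amplitudes: dict[str, np.ndarray]
    active: dict[str, np.ndarray]
    optical: dict[tuple[str, str], OpticalRecording] = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        """Group label per subject, 1 = impaired, 0 = control."""
        return np.array([1 if self.groups[s] == "impaired" else 0 for s in self.subjects])


def _rng(seed: int, *codes: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *codes)))


def generate_noise(n_samples: int, fs: float, noise: NoiseSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """One channel's additive noise: three sinusoids + drift + white noise."""
    t = np.arange(n_samples) / fs
    out = np.zeros(n_samples)
    for freq, amp in ((noise.cardiac_hz, noise.cardiac_amp),
                      (noise.respiration_hz, noise.respiration_amp),
                      (noise.mayer_hz, noise.mayer_amp)):
        phase = rng.uniform(0, 2 * np.pi) if noise.random_phase else 0.0
        if amp > 0:
            out += amp * np.sin(2 * np.pi * freq * t + phase)
        # phase is always drawn so the stream layout does not depend on amp
    out += noise.drift_slope * t
    if noise.white_sd > 0:
        out += noise.white_sd * rng.standard_normal(n_samples)
    return out


def generate_channel_signal(
    spec: CohortSpec,
    amplitude: float,
    active: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One channel's (dHbO, dHbR) series for a single trial epoch.

    Active channels carry ``amplitude`` times the unit-peak task response;
    dHbR mirrors the response component with opposite sign scaled by
    ``spec.hbr_anticorrelation``, plus its own independent noise draw.
    """
    n = spec.epoch_samples
    resp = task_response(spec.fs, spec.task_duration_s, spec.rest_duration_s, spec.hrf)
    component = amplitude * resp if active else np.zeros(n)
    dhbo = component + generate_noise(n, spec.fs, spec.noise, rng)
    dhbr = -spec.hbr_anticorrelation * component + \
        spec.hbr_anticorrelation * generate_noise(n, spec.fs, spec.noise, rng)
    return dhbo, dhbr


def generate_cohort(spec: CohortSpec, active_mask: np.ndarray | None = None) -> SyntheticDataset:
    """Generate the full synthetic dataset described by ``spec``.

    ``active_mask`` (n_channels boolean) restricts which channels carry a
    response; by default all channels are active with per-(subject, channel)
    log-normal amplitude jitter.  Impaired subjects receive
    ``amplitude_control * amplitude_ratio_impaired`` as their base amplitude.
    """
    if active_mask is None:
        active_mask = np.ones(spec.n_channels, dtype=bool)
    active_mask = np.asarray(active_mask, dtype=bool)
    if active_mask.shape != (spec.n_channels,):
        raise ValueError("active_mask must have one flag per channel")

    subjects = [f"S{i + 1:02d}" for i in range(spec.n_impaired + spec.n_control)]
    groups = {s: ("impaired" if i < spec.n_impaired else "control")
              for i, s in enumerate(subjects)}
    channel_ids = [f"CH{j + 1:02d}" for j in range(spec.n_channels)]

    resp = task_response(spec.fs, spec.task_duration_s, spec.rest_duration_s, spec.hrf)
    n_epoch = spec.epoch_samples
    onsets = spec.onsets_s()
    onset_idx = [int(round(o * spec.fs)) for o in onsets]
    # rounding the onsets can push the last epoch one sample past the
    # floored duration; extend the recording so every epoch fits
    n_total = max(int(np.floor(spec.recording_duration_s() * spec.fs)),
                  onset_idx[-1] + n_epoch)

    amplitudes: dict[str, np.ndarray] = {}
    active: dict[str, np.ndarray] = {}
    recordings: dict[tuple[str, str], HemoSeries] = {}
    optical: dict[tuple[str, str], OpticalRecording] = {}
    mbll = MbllParams() if spec.simulate_od else None

    for si, subject in enumerate(subjects):
        base = spec.amplitude_control
        if groups[subject] == "impaired":
            base = base * spec.amplitude_ratio_impaired
        amp_rng = _rng(spec.seed, _STAGE_AMPLITUDE, si)
        jitter = np.exp(spec.amplitude_jitter_sigma * amp_rng.standard_normal(spec.n_channels))
        amps = base * jitter * active_mask
        amplitudes[subject] = amps
        active[subject] = active_mask.copy()

        for ti, task in enumerate(spec.tasks):
            rec_rng = _rng(spec.seed, _STAGE_RECORDING, si, ti)
            dhbo = np.empty((spec.n_channels, n_total))
            dhbr = np.empty((spec.n_channels, n_total))
            for ci in range(spec.n_channels):
                component = np.zeros(n_total)
                if active_mask[ci]:
                    for i0 in onset_idx:
                        seg = min(n_epoch, n_total - i0)
                        component[i0 : i0 + seg] += amps[ci] * resp[:seg]
                dhbo[ci] = component + generate_noise(n_total, spec.fs, spec.noise, rec_rng)
                dhbr[ci] = -spec.hbr_anticorrelation * component + \
                    spec.hbr_anticorrelation * generate_noise(n_total, spec.fs, spec.noise, rec_rng)
            hemo = HemoSeries(dhbo=dhbo, dhbr=dhbr, fs=spec.fs,
                              channel_ids=channel_ids, onsets_s=onsets)
            recordings[(subject, task)] = hemo
            if mbll is not None:
                od = forward_mbll(dhbo, dhbr, mbll)
                optical[(subject, task)] = OpticalRecording(
                    od=od, fs=spec.fs, channel_ids=channel_ids,
                    wavelengths_nm=mbll.wavelengths_nm, onsets_s=onsets)

    return SyntheticDataset(
        spec=spec, subjects=subjects, groups=groups, channel_ids=channel_ids,
        recordings=recordings, amplitudes=amplitudes, active=active, optical=optical)


def write_cohort_csv(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Persist a cohort as plain CSV: one file per subject/task/trial
    (rows = samples, columns = channels) plus one JSON sidecar per subject
    with group label, sampling rate and ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = dataset.spec
    n_epoch = spec.epoch_samples
    for subject in dataset.subjects:
        sidecar = {
            "subject": subject,
            "group": dataset.groups[subject],
            "fs": spec.fs,
            "tasks": list(spec.tasks),
            "n_trials": spec.n_trials_per_task,
            "channel_ids": dataset.channel_ids,
            "ground_truth": {
                "amplitudes_uM": dataset.amplitudes[subject].tolist(),
                "active": dataset.active[subject].astype(int).tolist(),
            },
        }
        (out / f"{subject}.json").write_text(json.dumps(sidecar, indent=1))
        for task in spec.tasks:
            hemo = dataset.recordings[(subject, task)]
            for trial, onset in enumerate(spec.onsets_s(), start=1):
                i0 = int(round(onset * spec.fs))
                frame = pd.DataFrame(
                    hemo.dhbo[:, i0 : i0 + n_epoch].T, columns=dataset.channel_ids)
                frame.to_csv(out / f"{subject}_{task}_trial{trial}.csv", index=False)


def read_cohort_csv(in_dir: str | Path):
    """Load a CSV cohort written by :func:`write_cohort_csv`.

    Returns ``(epochs, groups, fs)`` where ``epochs`` maps
    (subject, task, trial) to an (n_channels, n_samples) dHbO array.
    """
    in_dir = Path(in_dir)
    sidecars = sorted(in_dir.glob("*.json"))
    if not sidecars:
        raise FileNotFoundError(f"no subject sidecars found in {in_dir}")
    epochs: dict[tuple[str, str, int], np.ndarray] = {}
    groups: dict[str, str] = {}
    fs = None
    for path in sidecars:
        meta = json.loads(path.read_text())
        subject = meta["subject"]
        groups[subject] = meta["group"]
        fs = meta["fs"]
        for task in meta["tasks"]:
            for trial in range(1, meta["n_trials"] + 1):
                csv_path = in_dir / f"{subject}_{task}_trial{trial}.csv"
                frame = pd.read_csv(csv_path)
                epochs[(subject, task, trial)] = frame.to_numpy().T
    return epochs, groups, fs
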