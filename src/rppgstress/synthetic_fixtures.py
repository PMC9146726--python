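"""Synthetic pulsatile videos and stress cohorts for end-to-end testing.

No real face recordings ship with this package; instead two generators
produce data with known ground truth:

``make_synthetic_video`` renders a skin-toned "face" patch whose
per-channel means oscillate at a planted pulse frequency, on top of slow
illumination drift and per-pixel sensor noise — the minimal photometric
structure the chrominance method needs.  The pulse modulates the channels
with relative weights (R, G, B) = (0.5, 1.0, 0.4), mimicking the dominance
of the green channel in blood-volume absorption and guaranteeing that the
chrominance projections carry the pulse.  It does not attempt photorealism,
pulse-waveform morphology, or motion beyond optional patch jitter.

``make_synthetic_cohort`` emulates the study cohort: 45 subjects at 50%
stress prevalence, 16 heart-rate intervals each (~720 instances).  Each
subject has a resting heart-rate baseline (between-subject sd ~10 bpm)
shifted upward for the stressed group, around which the 3.3 s intervals
fluctuate with a small within-subject sd (~3 bpm, consistent with the
<10 bpm resting fluctuation that motivates the 10% cleaning rule); Boolean
demographics couple to the label through per-feature log-odds.  State-
anxiety scores are drawn strictly above/below the gender cutoffs so that
the planted label always agrees with the score-derived label.  Raw series
carry the leading sentinel zero and occasional spike outliers so that the
cleaning stage has real work to do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .cohort_features import DEMOGRAPHIC_FEATURES, SubjectRecord
from .errors import InputError

#: Relative per-channel amplitude of the planted pulse.
PULSE_CHANNEL_WEIGHTS = (0.5, 1.0, 0.4)


@dataclass
class SyntheticVideoSpec:
    """Parameters of a rendered pulsatile face video.

    Amplitudes are relative to the channel mean; ``noise_sd`` is in 8-bit
    intensity units.  Defaults mirror a 30 fps, 480x640 webcam recording;
    tests typically use smaller frames.
    """

    duration_s: float = 60.0
    fps: float = 30.0
    pulse_bpm: float = 72.0
    pulse_amplitude: float = 0.01
    skin_rgb: Tuple[float, float, float] = (180.0, 120.0, 100.0)
    illumination_drift_amplitude: float = 0.02
    illumination_drift_period_s: float = 20.0
    noise_sd: float = 1.0
    motion_jitter_px: int = 0
    frame_height: int = 480
    frame_width: int = 640
    face_mode: str = "patch"       # patch | ellipse
    seed: int = 0

    def __post_init__(self) -> None:
        if not 40.0 <= self.pulse_bpm <= 220.0:
            raise InputError(
                f"pulse_bpm must lie in [40, 220], got {self.pulse_bpm}")
        if self.fps < 20:
            raise InputError(f"fps must be >= 20, got {self.fps}")
        if self.face_mode not in ("patch", "ellipse"):
            raise InputError(f"unknown face_mode {self.face_mode!r}")


class SyntheticVideo:
    """Lazy frame stream with planted ground truth.

    Iterating regenerates identical frames (a fresh seeded generator per
    pass).  ``face_box`` is the half-open box of the skin patch, usable as
    an injected detection.
    """

    def __init__(self, spec: SyntheticVideoSpec):
        self.spec = spec
        self.fps = spec.fps
        self.n_frames = int(round(spec.duration_s * spec.fps))
        h, w = spec.frame_height, spec.frame_width
        self.face_box = (int(0.30 * w), int(0.25 * h),
                         int(0.70 * w), int(0.75 * h))
        self.pulse_bpm = spec.pulse_bpm

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[np.ndarray]:
        s = self.spec
        rng = np.random.default_rng(s.seed)
        h, w = s.frame_height, s.frame_width
        x0, y0, x1, y1 = self.face_box
        base = np.asarray(s.skin_rgb, dtype=float)
        weights = np.asarray(PULSE_CHANNEL_WEIGHTS) * s.pulse_amplitude
        f_pulse = s.pulse_bpm / 60.0
        f_drift = (0.0 if s.illumination_drift_period_s <= 0
                   else 1.0 / s.illumination_drift_period_s)
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (y0 + y1) / 2.0, (x0 + x1) / 2.0
        ellipse = (((xx - cx) / max(1.0, (x1 - x0) / 2.0)) ** 2
                   + ((yy - cy) / max(1.0, (y1 - y0) / 2.0)) ** 2) <= 1.0
        for i in range(self.n_frames):
            t = i / s.fps
            drift = 1.0 + s.illumination_drift_amplitude * np.sin(
                2 * np.pi * f_drift * t)
            pulse = np.sin(2 * np.pi * f_pulse * t)
            colour = base * drift * (1.0 + weights * pulse)
            frame = np.full((h, w, 3), 60.0)
            jx = jy = 0
            if s.motion_jitter_px:
                jx = int(rng.integers(-s.motion_jitter_px,
                                      s.motion_jitter_px + 1))
                jy = int(rng.integers(-s.motion_jitter_px,
                                      s.motion_jitter_px + 1))
            if s.face_mode == "patch":
                frame[max(0, y0 + jy):y1 + jy,
                      max(0, x0 + jx):x1 + jx] = colour
            else:
                frame[ellipse] = colour
            if s.noise_sd > 0:
                frame = frame + rng.normal(0.0, s.noise_sd, frame.shape)
            yield np.clip(np.round(frame), 0, 255).astype(np.uint8)

    def to_array(self) -> np.ndarray:
        return np.stack(list(self))

    def save_npz(self, path: str) -> None:
        """Write the frame bundle plus a JSON sidecar with spec and seed."""
        np.savez_compressed(path, frames=self.to_array(), fps=self.fps)
        with open(str(path) + ".json", "w") as fh:
            json.dump({"spec": asdict(self.spec),
                       "face_box": list(self.face_box)}, fh, indent=2)


def make_synthetic_video(spec: Optional[SyntheticVideoSpec] = None,
                         **overrides) -> SyntheticVideo:
    """Render a deterministic pulsatile face video (see module docstring)."""
    if spec is None:
        spec = SyntheticVideoSpec(**overrides)
    elif overrides:
        raise InputError("pass either a spec or keyword overrides, not both")
    return SyntheticVideo(spec)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohortSpec:
    """Parameters of a simulated study cohort.

    ``hr_shift_bpm`` is the mean heart-rate elevation of stressed subjects;
    ``hr_subject_sd`` the between-subject spread of resting baselines and
    ``hr_sd`` the within-subject interval-to-interval fluctuation;
    ``demographic_effects`` maps Boolean demographic feature names to the
    log-odds separation between the stressed and non-stressed groups.
    Defaults emulate the 45-subject, ~720-instance structure of the study
    cohort with a moderate acute-stress tachycardia (+10 bpm) and
    label-correlated background features.
    """

    n_subjects: int = 45
    stress_prevalence: float = 0.5
    hr_shift_bpm: float = 10.0
    hr_sd: float = 3.0
    hr_subject_sd: float = 10.0
    intervals_per_subject: int = 16
    demographic_effects: Dict[str, float] = field(default_factory=lambda: {
        "public_school": 1.0, "sports": -1.0, "extracurricular": 0.5,
        "family_issues": 1.5, "failed_classes": 1.5})
    hr_base_bpm: float = 72.0
    female_fraction: float = 22.0 / 56.0
    outlier_rate: float = 0.08
    outlier_factor: float = 1.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.stress_prevalence < 1.0:
            raise InputError("stress_prevalence must lie in (0, 1)")
        if self.intervals_per_subject < 3:
            raise InputError("intervals_per_subject must be >= 3")
        unknown = set(self.demographic_effects) - set(DEMOGRAPHIC_FEATURES)
        if unknown:
            raise InputError(f"unknown demographic features: {unknown}")


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def make_synthetic_cohort(spec: Optional[SyntheticCohortSpec] = None,
                          **overrides
                          ) -> Tuple[List[SubjectRecord],
                                     Dict[str, np.ndarray]]:
    """Simulate a cohort with planted stress structure.

    Returns the subject records and a map subject_id -> raw per-window HR
    series (leading sentinel 0, occasional spike outliers), ready for the
    post-processing stage.  Every subject's planted label equals the label
    derived from their state-anxiety score and gender.
    """
    if spec is None:
        spec = SyntheticCohortSpec(**overrides)
    elif overrides:
        raise InputError("pass either a spec or keyword overrides, not both")
    rng = np.random.default_rng(spec.seed)
    records: List[SubjectRecord] = []
    series: Dict[str, np.ndarray] = {}
    for i in range(spec.n_subjects):
        sid = f"S{i:03d}"
        label = int(rng.random() < spec.stress_prevalence)
        gender = int(rng.random() < spec.female_fraction)
        sxe = (int(rng.integers(44, 81)) if label
               else int(rng.integers(20, 44)))
        booleans = {}
        for feat in DEMOGRAPHIC_FEATURES[2:]:
            effect = spec.demographic_effects.get(feat, 0.0)
            p = _sigmoid(effect * (label - 0.5))
            booleans[feat] = int(rng.random() < p)
        rec = SubjectRecord(subject_id=sid,
                            age=float(rng.integers(18, 25)),
                            gender=gender, sxe_score=sxe,
                            sxr_score=int(np.clip(sxe + rng.integers(-5, 6),
                                                  20, 80)),
                            **booleans)
        assert rec.label == label
        records.append(rec)
        mu = rng.normal(spec.hr_base_bpm + spec.hr_shift_bpm * label,
                        spec.hr_subject_sd)
        hr = rng.normal(mu, spec.hr_sd, size=spec.intervals_per_subject)
        spikes = rng.random(hr.size) < spec.outlier_rate
        hr[spikes] *= spec.outlier_factor
        hr = np.clip(hr, 40.0, 220.0)
        hr[0] = 0.0                       # leading sentinel window
        series[sid] = hr
    return records, series
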