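"""Synthetic eye-movement cohort generator.

Produces the two stimulus trajectories used in the eye-tracking protocol
(a horizontal optokinetic sweep and a two-way zigzag smooth-pursuit track),
class-conditional gaze traces for three subject classes (healthy controls,
brain-injury patients, vertigo patients), optional rendered grayscale eye
frames for exercising the pupil-morphometry stage, and full cohorts with the
fixed three-group structure (12/8/12 subjects of C1/C2/C3 per group).

Screen coordinates are normalized to the unit square [0, 1] x [0, 1];
conversion to pixels happens only when rendering frames.  All randomness is
driven by :class:`numpy.random.Generator` streams derived from explicit
seeds, so (inputs, seed) fully determine every trace and image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

CLASS_LABELS = ("C1", "C2", "C3")
SCHEME_IDS = ("horizontal_sweep", "zigzag")

#: Fraction of the horizontal nystagmus amplitude applied vertically.
#: Vestibular nystagmus is rarely purely horizontal.
NYSTAGMUS_VERTICAL_FRACTION = 0.35

#: Pupil-area coupling to gaze eccentricity: the camera sees the pupil
#: foreshortened as the eye rotates away from primary position, so apparent
#: area shrinks toward the screen edges.
AREA_GAZE_COUPLING = 0.3

#: Exponential decay of a saccadic offset per frame (gaze drifts back onto
#: the target after a jump).
SACCADE_DECAY = 0.8


@dataclass(frozen=True)
class StimulusScheme:
    """A moving-light-spot stimulus presented on a normalized screen.

    Parameters
    ----------
    scheme_id
        Either ``"horizontal_sweep"`` (spot moves left to right along the
        horizontal midline, snaps back to the left edge and repeats) or
        ``"zigzag"`` (spot sweeps rightward while the ordinate zigzags
        between two apex rows, restarting after the right endpoint).
    n_frames
        Trace length in frames (default 250).
    frame_rate
        Acquisition rate in frames per second (default 30).
    sweep_period
        Frames per full left-to-right sweep.  Defaults to 100 frames for the
        horizontal sweep and to ``n_frames`` (a single sweep) for the zigzag.
    zigzag_apexes
        Low/high ordinate rows of the zigzag (default 0.25 / 0.75).
    zigzag_teeth
        Number of zigzag teeth per sweep (default 5).
    """

    scheme_id: str
    n_frames: int = 250
    frame_rate: float = 30.0
    sweep_period: int | None = None
    zigzag_apexes: tuple[float, float] = (0.25, 0.75)
    zigzag_teeth: int = 5

    def __post_init__(self) -> None:
        if self.scheme_id not in SCHEME_IDS:
            raise ValueError(f"unknown scheme_id {self.scheme_id!r}; "
                             f"expected one of {SCHEME_IDS}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        lo, hi = self.zigzag_apexes
        if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
            raise ValueError("zigzag apex ordinates must lie in [0, 1]")

    @property
    def period(self) -> int:
        if self.sweep_period is not None:
            return int(self.sweep_period)
        return 100 if self.scheme_id == "horizontal_sweep" else self.n_frames


@dataclass(frozen=True)
class TraceModel:
    """Class-conditional oculomotor signal model for one subject class.

    The defaults for the three classes live in :data:`DEFAULT_TRACE_MODELS`.
    These are plainly-distinguishable stand-ins for class-specific
    oculomotor pathology, not claims about the diseases themselves.
    """

    class_label: str
    tracking_gain: float = 1.0          # dimensionless, in (0, 1.5]
    latency: int = 0                    # frames
    noise_sd: float = 0.0               # normalized screen units
    saccade_rate: float = 0.0           # events / frame
    saccade_amplitude_sd: float = 0.0   # normalized units
    nystagmus_amplitude: float = 0.0    # normalized units
    nystagmus_freq: float = 0.0         # Hz
    pupil_area_mean: float = 1200.0     # px^2
    pupil_area_jitter_sd: float = 10.0  # px^2

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        if not (0.0 < self.tracking_gain <= 1.5):
            raise ValueError("tracking_gain must be in (0, 1.5]")
        if self.latency < 0:
            raise ValueError("latency must be >= 0")
        for name in ("noise_sd", "saccade_rate", "saccade_amplitude_sd",
                     "nystagmus_amplitude", "nystagmus_freq",
                     "pupil_area_mean", "pupil_area_jitter_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")


DEFAULT_TRACE_MODELS: dict[str, TraceModel] = {
    "C1": TraceModel("C1", tracking_gain=1.0, latency=2, noise_sd=0.01),
    "C2": TraceModel("C2", tracking_gain=0.85, latency=6, noise_sd=0.02,
                     saccade_rate=0.04, saccade_amplitude_sd=0.08),
    "C3": TraceModel("C3", tracking_gain=1.0, latency=3, noise_sd=0.015,
                     nystagmus_amplitude=0.05, nystagmus_freq=3.0,
                     pupil_area_jitter_sd=40.0),
}


@dataclass
class EyeTrace:
    """Per-frame raw pupil parameters for one subject under one scheme."""

    subject_id: str
    scheme_id: str
    class_label: str
    data: pd.DataFrame  # columns: frame, x, y, area (+ optional extras)

    def __post_init__(self) -> None:
        required = {"frame", "x", "y", "area"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"trace missing columns {sorted(missing)}")
        if (self.data["area"] <= 0).any():
            raise ValueError("pupil area values must be > 0")

    def __len__(self) -> int:
        return len(self.data)

    def parameter(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


@dataclass
class Subject:
    subject_id: str
    class_label: str
    group: int  # 1-based group index
    traces: dict[str, EyeTrace] = field(default_factory=dict)


@dataclass
class Cohort:
    """A full study cohort: disjoint groups with identical class makeup."""

    subjects: list[Subject]

    def group(self, g: int) -> list[Subject]:
        return [s for s in self.subjects if s.group == g]

    @property
    def n_groups(self) -> int:
        return max(s.group for s in self.subjects)


def generate_stimulus(scheme: StimulusScheme) -> np.ndarray:
    """Return the target trajectory as an (n_frames, 2) array of (x, y).

    The horizontal sweep has a periodic sawtooth abscissa and a constant
    ordinate of 0.5; the zigzag sweeps the abscissa while the ordinate
    follows a triangle wave between the apex rows.
    """
    frames = np.arange(scheme.n_frames)
    phase = (frames % scheme.period) / scheme.period  # in [0, 1)
    x = phase
    if scheme.scheme_id == "horizontal_sweep":
        y = np.full(scheme.n_frames, 0.5)
    else:
        lo, hi = scheme.zigzag_apexes
        tooth = (phase * scheme.zigzag_teeth) % 1.0
        tri = 1.0 - np.abs(2.0 * tooth - 1.0)  # triangle wave in [0, 1]
        y = lo + (hi - lo) * tri
    out = np.column_stack([x, y])
    return np.clip(out, 0.0, 1.0)


def simulate_trace(
    stimulus: np.ndarray,
    model: TraceModel,
    seed: int | np.random.SeedSequence,
    subject_id: str = "S000",
    scheme_id: str = "horizontal_sweep",
    frame_rate: float = 30.0,
) -> EyeTrace:
    """Simulate one gaze trace following ``stimulus`` under ``model``.

    Gaze is the stimulus delayed by ``latency`` frames, scaled about the
    screen center by ``tracking_gain``, with additive Gaussian noise.  Class
    events are superimposed: Poisson-rate saccadic jumps with exponentially
    decaying offsets, and a sawtooth nystagmus oscillation (slow drift, fast
    reset) with a small vertical component.  Pupil area is the model mean,
    attenuated by gaze eccentricity (camera foreshortening), plus jitter.
    """
    stim = np.asarray(stimulus, dtype=float)
    if stim.ndim != 2 or stim.shape[1] != 2:
        raise ValueError("stimulus must be an (n_frames, 2) array")
    n = stim.shape[0]
    rng = np.random.default_rng(seed)

    # latency: hold the first target position during the delay
    idx = np.clip(np.arange(n) - model.latency, 0, None)
    gaze = stim[idx].copy()
    if model.tracking_gain != 1.0:  # keep unit gain bit-exact
        gaze = 0.5 + model.tracking_gain * (gaze - 0.5)

    if model.noise_sd > 0:
        gaze += rng.normal(0.0, model.noise_sd, size=(n, 2))

    if model.saccade_rate > 0 and model.saccade_amplitude_sd > 0:
        events = rng.random(n) < model.saccade_rate
        jumps = rng.normal(0.0, model.saccade_amplitude_sd, size=(n, 2))
        offset = np.zeros(2)
        for i in range(n):
            offset *= SACCADE_DECAY
            if events[i]:
                offset = offset + jumps[i]
            gaze[i] += offset

    if model.nystagmus_amplitude > 0 and model.nystagmus_freq > 0:
        phase = (model.nystagmus_freq * np.arange(n) / frame_rate) % 1.0
        saw = model.nystagmus_amplitude * (2.0 * phase - 1.0)
        gaze[:, 0] += saw
        gaze[:, 1] += NYSTAGMUS_VERTICAL_FRACTION * saw

    ecc2 = ((2.0 * gaze[:, 0] - 1.0) ** 2 + (2.0 * gaze[:, 1] - 1.0) ** 2) / 2.0
    area = model.pupil_area_mean * (1.0 - AREA_GAZE_COUPLING * np.clip(ecc2, 0, 1))
    if model.pupil_area_jitter_sd > 0:
        area = area + rng.normal(0.0, model.pupil_area_jitter_sd, size=n)
    area = np.maximum(area, 1.0)

    data = pd.DataFrame({
        "frame": np.arange(n),
        "x": gaze[:, 0],
        "y": gaze[:, 1],
        "area": area,
    })
    return EyeTrace(subject_id=subject_id, scheme_id=scheme_id,
                    class_label=model.class_label, data=data)


def render_frame(
    pupil_center: tuple[float, float],
    pupil_axes: tuple[float, float],
    pupil_angle: float = 0.0,
    image_size: tuple[int, int] = (240, 320),
    background: int = 220,
    pupil_intensity: int = 20,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a dark pupil ellipse on a bright background.

    ``pupil_center`` is (row, col) in pixels, ``pupil_axes`` the semi-axes
    (a, b), ``pupil_angle`` the CCW rotation of the a-axis from the column
    axis in degrees.  Pixel membership is exact (a pixel belongs to the
    pupil iff its integer center satisfies the ellipse inequality); there is
    no anti-aliasing, so rendered regions can serve as segmentation ground
    truth.  Optional additive Gaussian noise is clipped to [0, 255].
    """
    a, b = float(pupil_axes[0]), float(pupil_axes[1])
    if a <= 0 or b <= 0:
        raise ValueError("pupil semi-axes must be > 0")
    h, w = image_size
    r0, c0 = pupil_center
    half_extent = max(a, b)
    if (r0 - half_extent < 0 or r0 + half_extent > h - 1
            or c0 - half_extent < 0 or c0 + half_extent > w - 1):
        raise ValueError("ellipse exceeds image bounds")

    rows, cols = np.mgrid[0:h, 0:w]
    dc = cols - c0
    dr = rows - r0
    if a == b:
        # circle: skip the rotation so membership is rotation-invariant
        # even for boundary pixels
        mask = dc ** 2 + dr ** 2 <= a ** 2
    else:
        theta = np.deg2rad(pupil_angle)
        # rotate into the ellipse frame (angle measured from the column
        # axis toward the row axis)
        u = dc * np.cos(theta) + dr * np.sin(theta)
        v = -dc * np.sin(theta) + dr * np.cos(theta)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    img = np.full((h, w), float(background))
    img[mask] = float(pupil_intensity)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def render_trace_frames(
    trace: EyeTrace,
    image_size: tuple[int, int] = (240, 320),
    margin: float = 0.15,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Render a trace as a sequence of eye frames.

    Normalized gaze (x, y) maps to pixel (col, row) inside the image with a
    border ``margin`` so the ellipse stays in bounds; the pupil is drawn as
    a circle whose area matches the trace's ``area`` column.
    """
    h, w = image_size
    rng = np.random.default_rng(seed)
    frames = []
    for _, rec in trace.data.iterrows():
        radius = float(np.sqrt(rec["area"] / np.pi))
        row = (margin + (1 - 2 * margin) * rec["y"]) * (h - 1)
        col = (margin + (1 - 2 * margin) * rec["x"]) * (w - 1)
        frames.append(render_frame((row, col), (radius, radius), 0.0,
                                   image_size, noise_sd=noise_sd, rng=rng))
    return frames


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout: groups x (C1, C2, C3) subject counts."""

    n_groups: int = 3
    class_counts: tuple[int, int, int] = (12, 8, 12)
    schemes: tuple[StimulusScheme, ...] = (
        StimulusScheme("horizontal_sweep"),
        StimulusScheme("zigzag"),
    )
    trace_models: dict[str, TraceModel] | None = None

    def models(self) -> dict[str, TraceModel]:
        return dict(DEFAULT_TRACE_MODELS if self.trace_models is None
                    else self.trace_models)


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | np.random.SeedSequence = 0) -> Cohort:
    """Generate a full cohort with identical class composition per group.

    Group membership and class labels are a deterministic function of the
    configuration alone; the seed only drives trace values.  Each subject
    gets one independent random substream per stimulus scheme.
    """
    config = config or CohortConfig()
    models = config.models()
    counts = config.class_counts
    if len(counts) != len(CLASS_LABELS):
        raise ValueError("class_counts must have one entry per class")
    if any(c < 1 for c in counts):
        raise ValueError("each group needs at least one subject per class")

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    n_per_group = sum(counts)
    n_subjects = n_per_group * config.n_groups
    subject_seeds = ss.spawn(n_subjects)

    subjects: list[Subject] = []
    sid = 0
    for g in range(1, config.n_groups + 1):
        for label, count in zip(CLASS_LABELS, counts):
            for _ in range(count):
                subject_id = f"S{sid + 1:03d}"
                scheme_seeds = subject_seeds[sid].spawn(len(config.schemes))
                traces = {}
                for scheme, sch_seed in zip(config.schemes, scheme_seeds):
                    stim = generate_stimulus(scheme)
                    traces[scheme.scheme_id] = simulate_trace(
                        stim, models[label], sch_seed,
                        subject_id=subject_id, scheme_id=scheme.scheme_id,
                        frame_rate=scheme.frame_rate)
                subjects.append(Subject(subject_id, label, g, traces))
                sid += 1
    return Cohort(subjects)


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Long-format export: one row per subject/scheme/frame."""
    parts = []
    for s in cohort.subjects:
        for scheme_id, trace in s.traces.items():
            df = trace.data.copy()
            df.insert(0, "subject_id", s.subject_id)
            df.insert(1, "scheme", scheme_id)
            parts.append(df)
    return pd.concat(parts, ignore_index=True)


def cohort_labels(cohort: Cohort) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject_id": s.subject_id, "class_label": s.class_label,
          "group": s.group} for s in cohort.subjects])


def cohort_from_frames(traces: pd.DataFrame, labels: pd.DataFrame) -> Cohort:
    """Rebuild a :class:`Cohort` from the CSV export schema."""
    meta = labels.set_index("subject_id")
    subjects = []
    for subject_id, sub_df in traces.groupby("subject_id", sort=True):
        label = str(meta.loc[subject_id, "class_label"])
        group = int(meta.loc[subject_id, "group"])
        tr = {}
        for scheme_id, sch_df in sub_df.groupby("scheme", sort=True):
            data = sch_df.drop(columns=["subject_id", "scheme"]) \
                         .sort_values("frame").reset_index(drop=True)
            tr[scheme_id] = EyeTrace(subject_id, scheme_id, label, data)
        subjects.append(Subject(subject_id, label, group, tr))
    return Cohort(subjects)
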