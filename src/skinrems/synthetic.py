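"""Synthetic niacin-flush cohorts with known ground truth.

The generator emulates the closed-chamber acquisition output the pipeline
expects: per subject, a 15-frame time-lapse of a forearm bearing three
reaction patches (one per niacin molarity, vertical column) over uniform
skin of a subject-specific baseline tone. A patch's colour shift is

    shift(t) = amplitude(group, concentration) * subject_factor * kernel(t)

with a log-normal-shaped rise-and-decay kernel peaking (by default) at
4 min — inside the 2.5-5.5-min window that carries the diagnostic signal —
plus i.i.d. Gaussian pixel noise, rounding and clipping to 0-255. Group
membership drives amplitude (healthy controls flush fully, patient groups
are blunted), so the downstream screening/tree stages have real signal to
find; optional confounding couples amplitudes to metadata covariates so the
exclusion stages have true positives.

Feature-level simulators (``simulate_screening_matrix`` and friends) skip
rendering and draw feature matrices directly; they are used where the
quantity under test is statistical calibration rather than image handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import GROUPS, PATIENT_GROUPS, CohortConfig, KernelParams
from .errors import ConfigurationError, InputError
from .pipeline import Frame, FrameSequence, RoiSet

logger = logging.getLogger(__name__)

SOCIODEMOGRAPHIC_FACTORS = (
    "age",
    "gender",
    "chronic_disease",
    "family_history",
    "bmi",
    "physical_activity",
    "smoking",
)
DISEASE_FACTORS = (
    "duration_of_illness",
    "hospitalizations",
    "olanzapine_equiv",
    "panss_total",
)
BINARY_FACTORS = ("gender", "smoking", "chronic_disease", "family_history")


@dataclass
class SubjectMetadata:
    """Group label plus sociodemographic/lifestyle and disease covariates.

    Disease-related fields are NaN for healthy controls.
    """

    subject_id: str
    group: str
    age: float
    gender: int
    bmi: float
    smoking: int
    physical_activity: float
    chronic_disease: int
    family_history: int
    duration_of_illness: float = float("nan")
    hospitalizations: float = float("nan")
    olanzapine_equiv: float = float("nan")
    panss_total: float = float("nan")

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.group == "HC":
            for f in DISEASE_FACTORS:
                if not np.isnan(getattr(self, f)):
                    raise ConfigurationError(f"HC subject with disease field {f}")


@dataclass
class GroundTruth:
    """Oracle for segmentation and recovery tests."""

    subject_id: str
    baseline_color: np.ndarray
    patch_masks: List[np.ndarray]  # ordered by descending molarity
    control_mask: np.ndarray
    #: concentration -> (n_frames, 3) true additive (dR, dG, dB) trajectory
    amplitude_trajectories: Dict[float, np.ndarray] = field(default_factory=dict)

    def roi_set(self) -> RoiSet:
        return RoiSet(
            patch_masks=[m.copy() for m in self.patch_masks],
            control_mask=self.control_mask.copy(),
        )


def flush_kernel(t, params: KernelParams):
    """Unitless flush intensity multiplier in [0, 1].

    Log-normal bump: 0 at t = 0, rising to exactly 1 at ``peak_time`` and
    decaying toward 0; continuous on t >= 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InputError("kernel is defined for t >= 0 only")
    with np.errstate(divide="ignore"):
        logratio = np.where(t > 0, np.log(np.where(t > 0, t, 1.0) / params.peak_time), 0.0)
    value = np.where(t > 0, np.exp(-(logratio**2) / (2 * params.width**2)), 0.0)
    if value.ndim == 0:
        return float(value)
    return value


def render_frame(
    baseline_color: Sequence[float],
    masks: Sequence[np.ndarray],
    amplitudes: Sequence[Sequence[float]],
    noise_sd: float,
    rng: np.random.Generator,
    timestamp: float = 0.0,
) -> Frame:
    """Render one 8-bit frame: baseline skin + per-patch colour shifts + noise.

    ``amplitudes`` holds one effective (dR, dG, dB) triple per mask — the
    kernel-scaled shift at this frame's time. Pixels are rounded and
    clipped to 0-255 after noise is added.
    """
    masks = list(masks)
    amplitudes = list(amplitudes)
    if len(masks) != len(amplitudes):
        raise InputError("need one amplitude triple per patch mask")
    shape = masks[0].shape
    for m in masks:
        if m.shape != shape:
            raise InputError("mask shape mismatch")
    img = np.empty((*shape, 3), dtype=float)
    img[:] = np.asarray(baseline_color, dtype=float)
    for mask, amp in zip(masks, amplitudes):
        img[mask] += np.asarray(amp, dtype=float)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return Frame(pixels=img, timestamp=timestamp)


def _sample_metadata(sid: str, group: str, rng: np.random.Generator) -> SubjectMetadata:
    patient = group != "HC"
    meta = dict(
        subject_id=sid,
        group=group,
        age=float(rng.integers(18, 51)),
        gender=int(rng.random() < (0.51 if patient else 0.64)),
        bmi=float(np.clip(rng.normal(24.6 if patient else 21.3, 3.5 if patient else 2.2), 16, 45)),
        smoking=int(rng.random() < (0.30 if patient else 0.18)),
        physical_activity=float(
            0.0 if (patient and rng.random() < 0.5) else rng.exponential(90.0 if patient else 80.0)
        ),
        chronic_disease=int(rng.random() < (0.22 if patient else 0.28)),
        family_history=int(rng.random() < (0.25 if patient else 0.10)),
    )
    if patient:
        meta.update(
            duration_of_illness=float(np.clip(rng.lognormal(np.log(5.0), 0.8), 1, 31)),
            hospitalizations=float(rng.poisson(2.5)),
            olanzapine_equiv=float(np.clip(rng.lognormal(np.log(25.0), 0.9), 0.6, 135)),
            panss_total=float(np.clip(rng.normal(74, 20), 36, 145)),
        )
    return SubjectMetadata(**meta)


def metadata_frame(metadata: Sequence[SubjectMetadata]) -> pd.DataFrame:
    rows = [vars(m).copy() for m in metadata]
    df = pd.DataFrame(rows).set_index("subject_id")
    return df


def generate_cohort(
    config: CohortConfig,
) -> Tuple[List[SubjectMetadata], List[FrameSequence], List[GroundTruth]]:
    """Generate a full synthetic cohort.

    Returns one SubjectMetadata and one GroundTruth per subject, and one
    FrameSequence per subject per concentration. The three per-subject
    sequences share the same rendered frames (each frame shows all three
    patches); the GroundTruth maps each concentration to its patch mask.
    Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    times = config.frame_times
    kernel_values = flush_kernel(times, config.kernel)
    layout = config.layout
    patch_masks = layout.patch_masks()
    control_mask = layout.control_mask()
    conc_order = sorted(config.concentrations, reverse=True)

    subjects: List[Tuple[str, str]] = []
    i = 1
    for group in GROUPS:
        for _ in range(int(config.group_sizes.get(group, 0))):
            subjects.append((f"S{i:03d}", group))
            i += 1

    metadata = [_sample_metadata(sid, grp, rng) for sid, grp in subjects]
    meta_df = metadata_frame(metadata)

    # Confounding: additive amplitude shift proportional to the subject's
    # standardized covariate, applied to all channels before the kernel.
    confound_shift = np.zeros(len(subjects))
    for cov, beta in config.confound_spec.items():
        col = pd.to_numeric(meta_df[cov], errors="coerce")
        sd = col.std(ddof=0)
        z = (col - col.mean()) / (sd if sd > 0 else 1.0)
        confound_shift = confound_shift + beta * z.fillna(0.0).to_numpy()

    sequences: List[FrameSequence] = []
    truths: List[GroundTruth] = []
    clipping_warned = False
    for idx, (sid, group) in enumerate(subjects):
        baseline = np.clip(
            rng.normal(config.baseline_mean, config.baseline_sd), 0, 255
        )
        subj_factor = float(rng.lognormal(0.0, config.amplitude_cv)) if config.amplitude_cv > 0 else 1.0
        peak_amp = {}
        for conc in conc_order:
            base = np.asarray(config.amplitude_map[group][conc], dtype=float)
            peak_amp[conc] = base * subj_factor + confound_shift[idx]
            if np.any(baseline + peak_amp[conc] > 255) or np.any(baseline + peak_amp[conc] < 0):
                if not clipping_warned:
                    logger.warning("amplitudes exceed the 8-bit range; clipping applied")
                    clipping_warned = True
        trajectories = {conc: np.outer(kernel_values, peak_amp[conc]) for conc in conc_order}
        frames = [
            render_frame(
                baseline,
                patch_masks,
                [trajectories[conc][k] for conc in conc_order],
                config.noise_sd,
                rng,
                timestamp=float(times[k]),
            )
            for k in range(config.n_frames)
        ]
        for conc in conc_order:
            sequences.append(FrameSequence(subject_id=sid, concentration=conc, frames=frames))
        truths.append(
            GroundTruth(
                subject_id=sid,
                baseline_color=baseline,
                patch_masks=[m.copy() for m in patch_masks],
                control_mask=control_mask.copy(),
                amplitude_trajectories=trajectories,
            )
        )
    return metadata, sequences, truths


# ---------------------------------------------------------------------------
# Feature-level simulators (no rendering): statistical test beds.
# ---------------------------------------------------------------------------


def simulate_screening_matrix(
    n_hc: int = 20,
    n_patients: int = 20,
    n_null: int = 1000,
    n_signal: int = 0,
    effect: float = 2.0,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Gaussian feature matrix for screening calibration/power checks.

    Null features are N(0, 1) in both groups; signal features are shifted
    by ``effect`` (in SD units) in the patient group. Returns (features,
    labels) with labels 'HC'/'PAT'.
    """
    rng = np.random.default_rng(seed)
    n = n_hc + n_patients
    labels = pd.Series(["HC"] * n_hc + ["PAT"] * n_patients, name="group")
    X = rng.normal(size=(n, n_null + n_signal))
    X[n_hc:, n_null:] += effect
    cols = [f"null_{i}" for i in range(n_null)] + [f"signal_{i}" for i in range(n_signal)]
    df = pd.DataFrame(X, columns=cols)
    df.index = [f"S{i:04d}" for i in range(n)]
    labels.index = df.index
    return df, labels


def simulate_confounded_matrix(
    metadata: pd.DataFrame,
    covariate: str,
    n_confounded: int = 50,
    n_clean: int = 50,
    beta: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Features either tracking a metadata covariate or independent of all.

    Confounded columns are ``beta * z(covariate) + noise``; clean columns
    are pure noise. Used to measure the exclusion stage's sensitivity and
    specificity against known ground truth.
    """
    rng = np.random.default_rng(seed)
    col = pd.to_numeric(metadata[covariate], errors="coerce")
    z = ((col - col.mean()) / col.std(ddof=0)).fillna(0.0).to_numpy()
    n = len(metadata)
    data = {}
    for i in range(n_confounded):
        data[f"conf_{i}"] = beta * z + rng.normal(0, noise_sd, n)
    for i in range(n_clean):
        data[f"clean_{i}"] = rng.normal(0, 1, n)
    return pd.DataFrame(data, index=metadata.index)


def simulate_tree_cohort(
    n_per_class: int = 200,
    root_feature: str = "Gmean_3_A",
    root_threshold: float = 50.0,
    child_feature: str = "Bmean_6_A",
    child_threshold: float = 80.0,
    margin: float = 2.0,
    n_noise_features: int = 3,
    label_noise: float = 0.02,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.Series, dict]:
    """Cohort with a planted two-level decision structure.

    The informative features are uniform on [0, 100] with an empty margin
    of width 2*``margin`` around their thresholds, so the best achievable
    split midpoint sits within one inter-point gap of the planted value.
    Labels follow the conjunctive rule (root <= t1) AND (child <= t2) —
    the blunted-response side is the positive class — flipped independently
    with probability ``label_noise``. Returns (features, labels, truth).
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class

    def sample_with_gap(threshold):
        u = rng.uniform(0, 100 - 2 * margin, n)
        return np.where(u < threshold - margin, u, u + 2 * margin)

    a = sample_with_gap(root_threshold)
    b = sample_with_gap(child_threshold)
    y = ((a <= root_threshold) & (b <= child_threshold)).astype(int)
    flips = rng.random(n) < label_noise
    y = np.where(flips, 1 - y, y)
    data = {root_feature: a, child_feature: b}
    for i in range(n_noise_features):
        data[f"Rmean_{i + 1}_C"] = rng.uniform(0, 100, n)
    df = pd.DataFrame(data, index=[f"S{i:04d}" for i in range(n)])
    labels = pd.Series(y, index=df.index, name="label")
    truth = {
        "root": (root_feature, root_threshold),
        "child": (child_feature, child_threshold),
    }
    return df, labels, truth
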