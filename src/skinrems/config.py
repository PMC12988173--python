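"""Cohort, acquisition-geometry and run configuration.

The defaults encode the acquisition protocol the analysis assumes: three
niacin concentrations (0.1, 0.01, 0.001 M) applied as a vertical column of
square patches on the forearm, one frame every 60 s for 15 min, and the
five diagnostic groups (FEP, BD, SA, CS, HC) with the cohort sizes of the
original study design (33/22/13/13/39).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError

GROUPS = ("FEP", "BD", "SA", "CS", "HC")
PATIENT_GROUPS = ("FEP", "BD", "SA", "CS")

DEFAULT_GROUP_SIZES = {"FEP": 33, "BD": 22, "SA": 13, "CS": 13, "HC": 39}
DEFAULT_CONCENTRATIONS = (0.1, 0.01, 0.001)

#: Peak additive colour shift (dR, dG, dB) of a fully-developed flush for a
#: healthy control at 0.1 M, in 8-bit intensity units. Patient groups are
#: scaled-down (blunted) versions of this response.
DEFAULT_BASE_AMPLITUDE = (45.0, 30.0, 22.0)

#: Relative flush strength per diagnostic group. Healthy controls flush
#: fully; chronic schizophrenia is the most blunted, first-episode psychosis
#: and the affective groups sit in between.
DEFAULT_GROUP_SCALE = {"HC": 1.0, "BD": 0.6, "FEP": 0.45, "SA": 0.3, "CS": 0.15}

#: Relative flush strength per niacin molarity; only 0.1 M produces a strong
#: response, mirroring the concentration dependence the analysis exploits.
DEFAULT_CONCENTRATION_SCALE = {0.1: 1.0, 0.01: 0.35, 0.001: 0.1}


def concentration_codes(concentrations: Sequence[float]) -> dict:
    """Letter code per molarity: 'A' for the highest, then descending."""
    ordered = sorted(set(concentrations), reverse=True)
    return {c: chr(ord("A") + i) for i, c in enumerate(ordered)}


def default_amplitude_map() -> dict:
    amp = {}
    for g in GROUPS:
        amp[g] = {}
        for c in DEFAULT_CONCENTRATIONS:
            s = DEFAULT_GROUP_SCALE[g] * DEFAULT_CONCENTRATION_SCALE[c]
            amp[g][c] = tuple(s * a for a in DEFAULT_BASE_AMPLITUDE)
    return amp


@dataclass(frozen=True)
class KernelParams:
    """Shape of the flush time course: log-normal rise-and-decay.

    ``peak_time`` is the time (s) of maximal erythema; ``width`` is the
    log-domain standard deviation controlling how sharply the reaction
    develops and fades. The kernel is normalised to 1 at the peak.
    """

    peak_time: float = 240.0
    width: float = 0.6

    def __post_init__(self):
        if self.peak_time <= 0:
            raise ConfigurationError("kernel peak_time must be positive")
        if self.width <= 0:
            raise ConfigurationError("kernel width must be positive")


@dataclass(frozen=True)
class PatchLayout:
    """Pixel geometry of the three reaction patches and the control area.

    Patches are squares in a vertical column (ordered by descending
    molarity, top to bottom); the control region is a square of unexposed
    skin offset to the side. The physical 2x2-cm papers have no fixed pixel
    scale, so sizes are configurable.
    """

    frame_shape: tuple = (480, 640)  # (rows, cols)
    patch_size: int = 40
    n_patches: int = 3
    control_size: int = 60

    def __post_init__(self):
        h, w = self.frame_shape
        needed = self.n_patches * self.patch_size * 2
        if h < needed or w < self.patch_size * 3:
            raise ConfigurationError(
                f"frame {self.frame_shape} too small for {self.n_patches} "
                f"patches of {self.patch_size} px"
            )

    def patch_centers(self) -> list:
        h, w = self.frame_shape
        col = int(w * 0.35)
        rows = np.linspace(h * 0.2, h * 0.8, self.n_patches)
        return [(int(r), col) for r in rows]

    def control_center(self) -> tuple:
        h, w = self.frame_shape
        return (int(h * 0.5), int(w * 0.75))

    def _square_mask(self, center, size) -> np.ndarray:
        mask = np.zeros(self.frame_shape, dtype=bool)
        r, c = center
        half = size // 2
        mask[max(r - half, 0) : r - half + size, max(c - half, 0) : c - half + size] = True
        return mask

    def patch_masks(self) -> list:
        return [self._square_mask(c, self.patch_size) for c in self.patch_centers()]

    def control_mask(self) -> np.ndarray:
        return self._square_mask(self.control_center(), self.control_size)


@dataclass
class CohortConfig:
    """Everything the synthetic cohort generator needs."""

    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS
    frame_interval: float = 60.0
    duration: float = 900.0
    amplitude_map: Mapping = field(default_factory=default_amplitude_map)
    kernel: KernelParams = field(default_factory=KernelParams)
    noise_sd: float = 2.0
    baseline_mean: tuple = (150.0, 115.0, 95.0)
    baseline_sd: float = 10.0
    #: log-normal sigma of the per-subject multiplicative amplitude factor.
    amplitude_cv: float = 0.15
    #: covariate name -> additive amplitude shift (intensity units per SD of
    #: the covariate), applied to all channels; used to plant confounding.
    confound_spec: Mapping[str, float] = field(default_factory=dict)
    layout: PatchLayout = field(default_factory=PatchLayout)
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group {g!r}")
            if n < 0:
                raise ConfigurationError("group sizes must be >= 0")
        if self.frame_interval <= 0 or self.duration <= 0:
            raise ConfigurationError("frame_interval and duration must be positive")
        n_frames = self.duration / self.frame_interval
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ConfigurationError(
                f"duration {self.duration} is not an integral number of "
                f"{self.frame_interval}-s intervals"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if len(set(self.concentrations)) != len(self.concentrations):
            raise ConfigurationError("duplicate concentrations")
        if self.layout.n_patches != len(self.concentrations):
            raise ConfigurationError("layout must provide one patch per concentration")
        for g in self.group_sizes:
            for c in self.concentrations:
                if g not in self.amplitude_map or c not in self.amplitude_map[g]:
                    raise ConfigurationError(f"amplitude_map missing ({g}, {c})")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))

    @property
    def frame_times(self) -> np.ndarray:
        """Timestamp of frame k (1-based) is (k - 0.5) * interval: index 3
        corresponds to 2.5 min, index 6 to 5.5 min."""
        k = np.arange(1, self.n_frames + 1)
        return (k - 0.5) * self.frame_interval

    @property
    def codes(self) -> dict:
        return concentration_codes(self.concentrations)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["concentrations"] = list(self.concentrations)
        d["amplitude_map"] = {
            g: {float(c): list(a) for c, a in m.items()} for g, m in self.amplitude_map.items()
        }
        return d


def small_demo_config(seed: int = 0, n_per_group: Optional[Mapping[str, int]] = None) -> CohortConfig:
    """A fast, low-resolution configuration for demos and tests."""
    sizes = dict(n_per_group) if n_per_group else {"FEP": 8, "BD": 0, "SA": 0, "CS": 0, "HC": 8}
    return CohortConfig(
        group_sizes=sizes,
        layout=PatchLayout(frame_shape=(160, 200), patch_size=20, control_size=30),
        seed=seed,
    )


def load_config(path) -> CohortConfig:
    """Read a CohortConfig from YAML (inverse of ``save_config``)."""
    raw = yaml.safe_load(Path(path).read_text())
    if "kernel" in raw:
        raw["kernel"] = KernelParams(**raw["kernel"])
    if "layout" in raw:
        lay = dict(raw["layout"])
        if "frame_shape" in lay:
            lay["frame_shape"] = tuple(lay["frame_shape"])
        raw["layout"] = PatchLayout(**lay)
    if "amplitude_map" in raw:
        raw["amplitude_map"] = {
            g: {float(c): tuple(a) for c, a in m.items()} for g, m in raw["amplitude_map"].items()
        }
    if "concentrations" in raw:
        raw["concentrations"] = tuple(raw["concentrations"])
    if "baseline_mean" in raw:
        raw["baseline_mean"] = tuple(raw["baseline_mean"])
    return CohortConfig(**raw)


def save_config(config: CohortConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
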