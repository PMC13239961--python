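"""Domain types for rotational dose-QA simulation and analysis.

The geometric convention is a patient-like right-handed frame:

* axis 0 (``x``) — left-right; **UP** (upward pitch) rotates about it,
* axis 1 (``y``) — anterior-posterior; **RO** (roll) rotates about it,
* axis 2 (``z``) — superior-inferior; **CW** (clockwise yaw, viewed from
  above) rotates about it with a negative mathematical sign.

All lengths are millimetres, doses are Gy, angles are degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ValidationError",
    "InvalidSpecError",
    "InvalidRotationError",
    "OutOfBoundsError",
    "DegenerateInputError",
    "DIRECTION_AXES",
    "DIRECTION_SIGNS",
    "RotationError",
    "DoseVolume",
    "StructureMask",
    "DosePlane",
    "DetectorSpec",
    "PlanSpec",
    "CohortProtocol",
    "MeasurementRecord",
]


class ValidationError(ValueError):
    """Invalid user input (CLI exit code 2)."""


class InvalidSpecError(ValidationError):
    """Degenerate or inconsistent generator specification."""


class InvalidRotationError(ValidationError):
    """Rotation angles outside the supported range."""


class OutOfBoundsError(ValidationError):
    """Requested sampling geometry does not intersect the grid."""


class DegenerateInputError(ValidationError):
    """Input too degenerate for the requested computation (empty mask, all-zero plane, ...)."""


#: direction label -> rotation axis index
DIRECTION_AXES = {"UP": 0, "RO": 1, "CW": 2}
#: direction label -> sign of the mathematical (right-handed) rotation angle
DIRECTION_SIGNS = {"UP": +1.0, "RO": +1.0, "CW": -1.0}

_MAX_ANGLE_DEG = 10.0


@dataclass(frozen=True)
class RotationError:
    """Rigid rotational setup error about the isocenter.

    Angles are stored as magnitudes along their labelled direction; the
    sign convention of ``DIRECTION_SIGNS`` is applied when the rotation
    matrix is built.
    """

    pitch_deg: float = 0.0
    roll_deg: float = 0.0
    yaw_deg: float = 0.0

    def __post_init__(self) -> None:
        for name, a in (("pitch", self.pitch_deg), ("roll", self.roll_deg), ("yaw", self.yaw_deg)):
            if not np.isfinite(a) or abs(a) > _MAX_ANGLE_DEG:
                raise InvalidRotationError(
                    f"{name} angle {a!r} outside supported range +/-{_MAX_ANGLE_DEG} deg"
                )

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([self.pitch_deg, self.roll_deg, self.yaw_deg], dtype=float)

    @property
    def direction_labels(self) -> frozenset[str]:
        """A label is present iff its angle is nonzero."""
        labels = []
        for label, axis in DIRECTION_AXES.items():
            if self.angles_deg[axis] != 0.0:
                labels.append(label)
        return frozenset(labels)

    @property
    def total_deg(self) -> float:
        """Sum of absolute angles over the three axes."""
        return float(np.sum(np.abs(self.angles_deg)))

    @property
    def n_directions(self) -> int:
        return len(self.direction_labels)

    @property
    def is_identity(self) -> bool:
        return self.total_deg == 0.0


def _as_vec3(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).reshape(-1)
    if arr.size != 3 or not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} must be a finite 3-vector, got {v!r}")
    return arr


@dataclass
class DoseVolume:
    """A 3D dose grid with physical geometry.

    ``grid`` holds dose in Gy on a regular grid; the physical position of
    voxel ``(i, j, k)`` is ``origin + spacing * (i, j, k)``.
    """

    grid: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    isocenter: np.ndarray
    prescription_dose: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValidationError(f"dose grid must be 3D with >=2 voxels per axis, got {self.grid.shape}")
        if not np.all(np.isfinite(self.grid)) or self.grid.min() < 0:
            raise ValidationError("dose values must be finite and non-negative")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValidationError("spacing must be strictly positive")
        self.origin = _as_vec3(self.origin, "origin")
        self.isocenter = _as_vec3(self.isocenter, "isocenter")
        lo, hi = self.bounds
        if np.any(self.isocenter < lo - 1e-9) or np.any(self.isocenter > hi + 1e-9):
            raise ValidationError("isocenter lies outside the grid bounding box")
        if self.prescription_dose < 0:
            raise ValidationError("prescription_dose must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (lower, upper) corners of the voxel-center bounding box."""
        upper = self.origin + self.spacing * (np.array(self.shape) - 1)
        return self.origin.copy(), upper

    def index_of(self, point_mm) -> np.ndarray:
        """Fractional voxel index of a physical point."""
        return (_as_vec3(point_mm, "point") - self.origin) / self.spacing

    def copy_with(self, grid: np.ndarray) -> "DoseVolume":
        return replace(self, grid=np.asarray(grid, dtype=float))


@dataclass
class StructureMask:
    """Binary structure (target) mask aligned to a :class:`DoseVolume`."""

    grid: np.ndarray
    label: str = "target"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise ValidationError("mask must be 3D")
        if not self.grid.any():
            raise ValidationError("mask must be nonempty")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


@dataclass
class DosePlane:
    """A square 2D dose matrix sampled at uniform pitch.

    ``mode`` records whether values are absolute Gy or a fraction of a
    reference maximum.
    """

    matrix: np.ndarray
    spacing_mm: float
    mode: str = "absolute"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or min(self.matrix.shape) < 2:
            raise ValidationError(f"plane must be 2D with >=2 samples per axis, got {self.matrix.shape}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("plane values must be finite")
        if self.matrix.min() < 0:
            raise ValidationError("plane values must be non-negative")
        if self.spacing_mm <= 0:
            raise ValidationError("plane spacing must be positive")
        if self.mode not in ("absolute", "relative"):
            raise ValidationError(f"unknown dose mode {self.mode!r}")

    @property
    def max_dose(self) -> float:
        return float(self.matrix.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape  # type: ignore[return-value]

    def copy_with(self, matrix: np.ndarray, mode: Optional[str] = None) -> "DosePlane":
        return DosePlane(np.asarray(matrix, dtype=float), self.spacing_mm, mode or self.mode)


_AXIS_IDS = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


@dataclass(frozen=True)
class DetectorSpec:
    """Planar diode-array emulation: a regular square sampling grid.

    Defaults mirror a 77.00 x 77.00 mm effective detection area
    interpolated to 45 x 45 samples, with additive Gaussian noise whose SD
    is a fraction of the plane maximum (diode-array repeatability is at
    the percent level).
    """

    plane_normal: str | int = "z"
    plane_offset_mm: float = 0.0
    extent_mm: float = 77.0
    n_samples: int = 45
    noise_sd_frac: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plane_normal not in _AXIS_IDS:
            raise ValidationError(f"unknown plane normal {self.plane_normal!r}")
        if self.extent_mm <= 0:
            raise ValidationError("extent_mm must be > 0")
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if self.noise_sd_frac < 0:
            raise ValidationError("noise_sd_frac must be >= 0")

    @property
    def normal_axis(self) -> int:
        return _AXIS_IDS[self.plane_normal]

    @property
    def pitch_mm(self) -> float:
        return self.extent_mm / (self.n_samples - 1)


@dataclass(frozen=True)
class PlanSpec:
    """Parameters of a synthetic SBRT-like plan.

    The dose field is a superposition of anisotropic Gaussian lobes with
    steep fall-off, rescaled so the global maximum equals ``peak_dose_gy``.
    When ``lobes`` is None the lobe geometry is drawn from the stated
    ranges using the generator seed.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: float = 2.0
    n_lobes_range: tuple[int, int] = (4, 5)
    sigma_range_mm: tuple[float, float] = (4.0, 10.0)
    peak_range_gy: tuple[float, float] = (40.0, 70.0)
    offset_range_mm: tuple[float, float] = (15.0, 30.0)
    secondary_spread_mm: float = 20.0
    prescription_fraction: float = 0.8
    #: multiplicative beam-modulation texture: relative amplitude and
    #: correlation length of the fine-scale ripple superimposed on the
    #: lobes (emulates beamlet-interference structure in measured planes)
    ripple_amplitude: float = 0.05
    ripple_corr_mm: float = 2.5
    #: explicit (center_mm_rel_iso, sigma_mm_vec3, weight) triples; overrides sampling
    lobes: Optional[tuple] = None
    peak_dose_gy: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 4:
            raise InvalidSpecError("grid too small")
        if self.spacing_mm <= 0:
            raise InvalidSpecError("spacing must be positive")
        if self.n_lobes_range[0] < 1 or self.n_lobes_range[0] > self.n_lobes_range[1]:
            raise InvalidSpecError("invalid lobe count range")
        if self.sigma_range_mm[0] <= 0:
            raise InvalidSpecError("lobe sigma must be positive")
        if self.peak_range_gy[0] <= 0 or (self.peak_dose_gy is not None and self.peak_dose_gy <= 0):
            raise InvalidSpecError("peak dose must be positive")
        if not (0 < self.prescription_fraction <= 1):
            raise InvalidSpecError("prescription_fraction must lie in (0, 1]")


DEFAULT_STAGE1_ANGLES = (1.5, 2.25, 3.0, 3.75, 4.5)


@dataclass(frozen=True)
class CohortProtocol:
    """Two-stage acquisition protocol.

    Stage 1: per plan, one measurement per (angle magnitude x single
    direction) on a discrete grid — by default 5 magnitudes spanning
    1.5-4.5 deg in each of UP/RO/CW, i.e. 15 measurements per plan plus
    the 0 deg reference.  Stage 2: one measurement per plan with
    continuous angles drawn uniformly from ``stage2_angle_range_deg`` in
    2-3 randomly chosen axes.
    """

    n_plans: int = 40
    stage1_angles_deg: tuple[float, ...] = DEFAULT_STAGE1_ANGLES
    stage1_directions: tuple[str, ...] = ("UP", "RO", "CW")
    stage2_angle_range_deg: tuple[float, float] = (1.5, 4.5)
    stage2_n_directions: tuple[int, ...] = (2, 3)
    stage2_enabled: bool = True
    seed: int = 0
    plan_spec: PlanSpec = field(default_factory=PlanSpec)
    detector: DetectorSpec = field(default_factory=DetectorSpec)
    compute_dvh: bool = False
    keep_volumes: bool = False

    def __post_init__(self) -> None:
        if self.n_plans < 1:
            raise ValidationError("n_plans must be >= 1")
        for a in self.stage1_angles_deg:
            if not 0 <= a <= _MAX_ANGLE_DEG:
                raise ValidationError(f"stage-1 angle {a} outside [0, {_MAX_ANGLE_DEG}]")
        for d in self.stage1_directions:
            if d not in DIRECTION_AXES:
                raise ValidationError(f"unknown direction label {d!r}")
        lo, hi = self.stage2_angle_range_deg
        if not (0 <= lo <= hi <= _MAX_ANGLE_DEG):
            raise ValidationError("stage-2 angle range invalid")
        for k in self.stage2_n_directions:
            if k not in (1, 2, 3):
                raise ValidationError("stage-2 direction counts must be in {1,2,3}")


@dataclass
class MeasurementRecord:
    """One (reference, perturbed) plane pair from a simulated delivery."""

    plan_id: str
    stage: int
    rotation: RotationError
    reference_plane: DosePlane
    perturbed_plane: DosePlane
    delta_v100: Optional[float] = None
    volume_ref: Optional[DoseVolume] = None
    volume_rot: Optional[DoseVolume] = None

    def __post_init__(self) -> None:
        if self.stage not in (1, 2):
            raise ValidationError("stage must be 1 or 2")
        if self.reference_plane.shape != self.perturbed_plane.shape:
            raise ValidationError("reference and perturbed planes must share shape")
        if self.reference_plane.spacing_mm != self.perturbed_plane.spacing_mm:
            raise ValidationError("reference and perturbed planes must share spacing")
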