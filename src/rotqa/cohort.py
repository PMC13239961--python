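"""Synthetic SBRT-like cohorts: plan generation, rigid rotation, detector sampling.

Emulates a two-stage phantom campaign: per plan an error-free reference
plane plus perturbed planes acquired after rigidly rotating the dose
field about the isocenter (equivalent to rotating the phantom under a
fixed detector).  Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage

from .types import (
    DIRECTION_AXES,
    DIRECTION_SIGNS,
    CohortProtocol,
    DetectorSpec,
    DoseVolume,
    InvalidSpecError,
    MeasurementRecord,
    OutOfBoundsError,
    PlanSpec,
    RotationError,
    StructureMask,
)

__all__ = [
    "generate_plan",
    "synthesize_image",
    "rotation_matrix",
    "apply_rigid_rotation",
    "extract_plane",
    "simulate_cohort",
]


def _grid_coords(shape, spacing, origin):
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def generate_plan(spec: Optional[PlanSpec] = None, seed: int = 0) -> tuple[DoseVolume, StructureMask]:
    """Generate a synthetic plan: multi-lobe Gaussian dose field + target mask.

    The grid is centered on the isocenter (isocenter = geometric center of
    the voxel lattice).  Lobe centers, anisotropic sigmas, weights and the
    peak dose are drawn from the spec's ranges unless given explicitly.
    The field is rescaled so its maximum equals the peak dose exactly, and
    the target mask is the prescription isodose region
    (dose >= prescription_fraction * peak).
    """
    spec = spec or PlanSpec()
    rng = np.random.default_rng(seed)
    shape = np.array(spec.grid_shape)
    spacing = np.full(3, float(spec.spacing_mm))
    iso = np.zeros(3)
    origin = iso - spacing * (shape - 1) / 2.0

    if spec.lobes is not None:
        lobes = [(np.asarray(c, float), np.asarray(s, float), float(w)) for c, s, w in spec.lobes]
        if not lobes:
            raise InvalidSpecError("lobe list is empty")
        peak = spec.peak_dose_gy if spec.peak_dose_gy is not None else float(np.mean(spec.peak_range_gy))
    else:
        n_lobes = int(rng.integers(spec.n_lobes_range[0], spec.n_lobes_range[1] + 1))
        peak = spec.peak_dose_gy if spec.peak_dose_gy is not None else float(rng.uniform(*spec.peak_range_gy))
        interior = spacing * (shape - 1) / 2.0 - 2.0  # keep lobe centers inside the grid
        # Lobes are strung along a smooth arc around the isocenter,
        # forming one large irregular target (spine-like / horseshoe
        # geometries typical of SBRT) rather than isolated point blobs:
        # the high-dose structure then spans azimuth continuously, so
        # every rotation axis engages a comparable share of it.
        arc_span = rng.uniform(np.deg2rad(150), np.deg2rad(330))
        arc_start = rng.uniform(0, 2 * np.pi)
        # the target's distance from the isocenter is a plan-level
        # property; the arc sits at one radius with mild eccentricity
        r_plan = rng.uniform(*spec.offset_range_mm)
        r0 = r_plan + rng.uniform(-2.0, 2.0)
        r1 = r_plan + rng.uniform(-2.0, 2.0)
        # the longitudinal penumbra is a plan-level property (beam
        # geometry and collimation), so sigma_z is drawn once per plan
        # (upper half of the range: longitudinal falloff is shallower
        # than the lateral penumbra) with small per-lobe jitter
        sigma_z_plan = rng.uniform(0.5 * sum(spec.sigma_range_mm), spec.sigma_range_mm[1])
        lobes = []
        for lobe_idx in range(n_lobes):
            t = lobe_idx / max(n_lobes - 1, 1)
            phi = arc_start + t * arc_span + rng.uniform(-0.1, 0.1)
            radius = r0 + t * (r1 - r0) + rng.uniform(-2.0, 2.0)
            sigma = rng.uniform(*spec.sigma_range_mm, size=3)
            sigma[2] = np.clip(
                sigma_z_plan + rng.uniform(-0.5, 0.5),
                spec.sigma_range_mm[0],
                spec.sigma_range_mm[1],
            )
            z_off = rng.choice([-1.0, 1.0]) * rng.uniform(0.9, 1.1) * sigma[2]
            center = np.clip(
                np.array([radius * np.cos(phi), radius * np.sin(phi), z_off]),
                -interior,
                interior,
            )
            lobes.append((center, sigma, 1.0))

    half_extent = spacing * (shape - 1) / 2.0
    for center, sigma, _ in lobes:
        if np.any(np.abs(center) > half_extent):
            raise InvalidSpecError(f"lobe center {center} lies outside the grid")
        if np.any(np.asarray(sigma) <= 0):
            raise InvalidSpecError("lobe sigma must be positive")

    X, Y, Z = _grid_coords(shape, spacing, origin)
    dose = np.zeros(tuple(shape), dtype=float)
    for center, sigma, weight in lobes:
        c = iso + np.asarray(center, float)
        s = np.asarray(sigma, float)
        dose += weight * np.exp(
            -0.5 * (((X - c[0]) / s[0]) ** 2 + ((Y - c[1]) / s[1]) ** 2 + ((Z - c[2]) / s[2]) ** 2)
        )
    if spec.ripple_amplitude > 0:
        # beam-modulation texture: many crossing beams imprint fine-scale
        # interference structure on clinical dose fields; a smoothed,
        # unit-SD random field rotating rigidly with the plan emulates it
        ripple = ndimage.gaussian_filter(
            rng.normal(size=tuple(shape)), sigma=spec.ripple_corr_mm / spacing
        )
        sd = ripple.std()
        if sd > 0:
            dose *= np.clip(1.0 + spec.ripple_amplitude * ripple / sd, 0.1, None)
    m = dose.max()
    if m <= 0:
        raise InvalidSpecError("degenerate dose field")
    dose *= peak / m

    prescription = spec.prescription_fraction * peak
    mask = dose >= prescription
    volume = DoseVolume(dose, spacing, origin, iso, prescription_dose=prescription)
    return volume, StructureMask(mask, label="target")


def synthesize_image(mask: StructureMask, spacing, seed: int = 0) -> np.ndarray:
    """Synthetic phantom-CT-like image aligned to a plan's target mask.

    The target appears as a smoothed high-intensity region (~1000 above a
    ~100 background) with mild Gaussian texture noise, so first-order and
    shape descriptors carry the plan's geometry.  Values are clipped
    non-negative.
    """
    rng = np.random.default_rng(seed)
    spacing = np.asarray(spacing, float)
    img = 1000.0 * ndimage.gaussian_filter(mask.grid.astype(float), sigma=2.0 / spacing)
    img += 100.0 + 20.0 * ndimage.gaussian_filter(rng.normal(size=mask.grid.shape), sigma=1.0)
    return np.clip(img, 0.0, None)


def rotation_matrix(rotation: RotationError) -> np.ndarray:
    """Right-handed rotation matrix R = Rz(yaw) @ Ry(roll) @ Rx(pitch).

    Signed angles follow the direction convention: UP = +pitch about the
    left-right axis, RO = +roll about the anterior-posterior axis, CW =
    clockwise yaw viewed from above = negative mathematical angle about
    the superior-inferior axis.
    """
    p = np.deg2rad(DIRECTION_SIGNS["UP"] * rotation.pitch_deg)
    r = np.deg2rad(DIRECTION_SIGNS["RO"] * rotation.roll_deg)
    y = np.deg2rad(DIRECTION_SIGNS["CW"] * rotation.yaw_deg)
    cp, sp = np.cos(p), np.sin(p)
    cr, sr = np.cos(r), np.sin(r)
    cy, sy = np.cos(y), np.sin(y)
    Rx = np.array([[1, 0, 0], [0, cp, -sp], [0, sp, cp]])
    Ry = np.array([[cr, 0, sr], [0, 1, 0], [-sr, 0, cr]])
    Rz = np.array([[cy, -sy, 0], [sy, cy, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def apply_rigid_rotation(
    volume: DoseVolume, rotation: RotationError, center=None
) -> DoseVolume:
    """Resample the dose field under a rigid rotation about ``center``.

    Inverse-mapping trilinear interpolation on the unchanged grid
    geometry; voxels mapped from outside the field are set to 0.  A zero
    rotation returns an exact copy.
    """
    center = np.asarray(center, float) if center is not None else volume.isocenter
    lo, hi = volume.bounds
    if np.any(center < lo) or np.any(center > hi):
        raise OutOfBoundsError("rotation center outside grid")
    if rotation.is_identity:
        return volume.copy_with(volume.grid.copy())

    R = rotation_matrix(rotation)
    Rinv = R.T
    S = np.diag(volume.spacing)
    Sinv = np.diag(1.0 / volume.spacing)
    A = Sinv @ Rinv @ S
    b = Sinv @ ((np.eye(3) - Rinv) @ (center - volume.origin))
    out = ndimage.affine_transform(volume.grid, A, offset=b, order=1, mode="constant", cval=0.0)
    return volume.copy_with(np.clip(out, 0.0, None))


def extract_plane(volume: DoseVolume, spec: Optional[DetectorSpec] = None):
    """Sample a square detector plane from a dose volume.

    The plane is normal to ``spec.plane_normal``, offset from the
    isocenter by ``plane_offset_mm``, and covers ``extent_mm`` centered on
    the isocenter projection with ``n_samples`` per side (bilinear /
    trilinear sampling).  Seeded Gaussian noise (SD = ``noise_sd_frac`` x
    plane max) is added when requested; doses are clipped non-negative.
    """
    from .types import DosePlane

    spec = spec or DetectorSpec()
    axis = spec.normal_axis
    in_plane = [a for a in range(3) if a != axis]
    lo, hi = volume.bounds
    coord_n = volume.isocenter[axis] + spec.plane_offset_mm
    if coord_n < lo[axis] - 1e-9 or coord_n > hi[axis] + 1e-9:
        raise OutOfBoundsError("sampling plane lies outside the grid")

    n = spec.n_samples
    offsets = -spec.extent_mm / 2.0 + spec.extent_mm * np.arange(n) / (n - 1)
    pts = np.empty((3, n, n), dtype=float)
    pts[axis] = coord_n
    u = volume.isocenter[in_plane[0]] + offsets
    v = volume.isocenter[in_plane[1]] + offsets
    U, V = np.meshgrid(u, v, indexing="ij")
    pts[in_plane[0]] = U
    pts[in_plane[1]] = V

    idx = [(pts[a] - volume.origin[a]) / volume.spacing[a] for a in range(3)]
    matrix = ndimage.map_coordinates(volume.grid, np.stack(idx), order=1, mode="constant", cval=0.0)
    if spec.noise_sd_frac > 0:
        rng = np.random.default_rng(spec.seed)
        matrix = matrix + rng.normal(scale=spec.noise_sd_frac * max(matrix.max(), 1e-12), size=matrix.shape)
    matrix = np.clip(matrix, 0.0, None)
    return DosePlane(matrix, spacing_mm=spec.pitch_mm, mode="absolute")


def _v100_pair(ref: DoseVolume, rot: DoseVolume, mask: StructureMask) -> float:
    from .metrics import delta_v100

    return delta_v100(ref, rot, mask, ref.prescription_dose)


def simulate_cohort(protocol: Optional[CohortProtocol] = None) -> list[MeasurementRecord]:
    """Simulate the two-stage acquisition for a cohort of synthetic plans.

    Per plan: one 0 deg reference plane; stage 1 emits one record per
    (angle magnitude x single direction); stage 2 (when enabled) one
    record with continuous uniform angles in 2-3 randomly chosen axes.
    All records of a plan share the same reference plane object, so
    plan-grouped splitting is leakage-free by construction.
    """
    protocol = protocol or CohortProtocol()
    master = np.random.default_rng(protocol.seed)
    records: list[MeasurementRecord] = []

    for p in range(protocol.n_plans):
        # all per-plan randomness derives from plan_seed so that other
        # stages (e.g. feature extraction) can regenerate the same plans
        plan_seed = int(master.integers(2**31 - 1))
        noise_rng = np.random.default_rng(plan_seed + 1)
        stage2_rng = np.random.default_rng(plan_seed + 2)
        plan_id = f"plan{p:03d}"
        volume, mask = generate_plan(protocol.plan_spec, seed=plan_seed)

        def measure(vol: DoseVolume):
            det = DetectorSpec(
                plane_normal=protocol.detector.plane_normal,
                plane_offset_mm=protocol.detector.plane_offset_mm,
                extent_mm=protocol.detector.extent_mm,
                n_samples=protocol.detector.n_samples,
                noise_sd_frac=protocol.detector.noise_sd_frac,
                seed=int(noise_rng.integers(2**31 - 1)),
            )
            return extract_plane(vol, det)

        reference = measure(volume)

        rotations: list[tuple[int, RotationError]] = []
        for mag in protocol.stage1_angles_deg:
            for d in protocol.stage1_directions:
                kwargs = {"pitch_deg": 0.0, "roll_deg": 0.0, "yaw_deg": 0.0}
                kwargs[("pitch_deg", "roll_deg", "yaw_deg")[DIRECTION_AXES[d]]] = mag
                rotations.append((1, RotationError(**kwargs)))
        if protocol.stage2_enabled:
            k = int(stage2_rng.choice(np.asarray(protocol.stage2_n_directions)))
            axes = stage2_rng.choice(3, size=k, replace=False)
            mags = stage2_rng.uniform(*protocol.stage2_angle_range_deg, size=k)
            kwargs = {"pitch_deg": 0.0, "roll_deg": 0.0, "yaw_deg": 0.0}
            for a, m in zip(axes, mags):
                kwargs[("pitch_deg", "roll_deg", "yaw_deg")[int(a)]] = float(m)
            rotations.append((2, RotationError(**kwargs)))

        for stage, rot in rotations:
            rotated = apply_rigid_rotation(volume, rot)
            perturbed = measure(rotated)
            dv100 = _v100_pair(volume, rotated, mask) if protocol.compute_dvh else None
            records.append(
                MeasurementRecord(
                    plan_id=plan_id,
                    stage=stage,
                    rotation=rot,
                    reference_plane=reference,
                    perturbed_plane=perturbed,
                    delta_v100=dv100,
                    volume_ref=volume if protocol.keep_volumes else None,
                    volume_rot=rotated if protocol.keep_volumes else None,
                )
            )
    return records
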