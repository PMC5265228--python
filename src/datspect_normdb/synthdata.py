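"""Synthetic striatal SPECT data with known ground truth.

Generates digital striatal phantoms and subject cohorts whose true
structure-to-background uptake ratios (SBRs) are known exactly, and applies
an image-space surrogate of tomographic reconstruction: Gaussian point-spread
blurring, a diffuse scatter/septal-penetration background, a depth-independent
attenuation loss, Poisson counting noise and a Butterworth post-filter.

Reconstruction is modelled in image space on purpose: the downstream analysis
only sees reconstruction through its effect on measured SBR, which is linear
in true SBR under this model — the same linearity the scanner calibration
assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ValidationError

SIDES = ("left", "right")
STRUCTURES = ("caudate", "putamen")

#: Full width at half maximum of a Gaussian in units of its sigma.
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

RECON_MODES = ("ACSC", "IRNC", "FBP")


@dataclass(frozen=True)
class CountVolume:
    """A 3D grid of reconstructed emission counts with isotropic voxels."""

    data: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError("count volume must be 3-dimensional")
        if self.voxel_size_mm <= 0:
            raise ValidationError("voxel size must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size_mm**3 / 1000.0

    def total_counts(self) -> float:
        return float(self.data.sum())


@dataclass(frozen=True)
class StriatalGeometry:
    """Ellipsoidal striatal geometry on an isotropic voxel grid.

    All coordinates are millimetres in grid space (voxel index * voxel size).
    Left/right structures must be mirror images about the mid-sagittal plane
    x = brain_center[0]; left is the +x half-space.
    """

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    brain_center: tuple[float, float, float]
    brain_radii: tuple[float, float, float]
    caudate_centers: tuple[tuple[float, float, float], tuple[float, float, float]]  # (left, right)
    caudate_radii: tuple[float, float, float]
    putamen_centers: tuple[tuple[float, float, float], tuple[float, float, float]]
    putamen_radii: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(n < 8 for n in self.grid_shape):
            raise GeometryError("grid_shape must be three axes of at least 8 voxels")
        if self.voxel_size_mm <= 0:
            raise GeometryError("voxel size must be positive")
        for radii in (self.brain_radii, self.caudate_radii, self.putamen_radii):
            if any(r <= 0 for r in radii):
                raise GeometryError("all ellipsoid radii must be positive")
        x0 = self.brain_center[0]
        for left, right in (self.caudate_centers, self.putamen_centers):
            mirrored = (2 * x0 - left[0], left[1], left[2])
            if any(abs(a - b) > 1e-9 for a, b in zip(mirrored, right)):
                raise GeometryError(
                    "left/right structures must mirror about the mid-sagittal plane"
                )
            if left[0] <= x0:
                raise GeometryError("left-side structures must lie in the +x half-space")
        masks = _geometry_masks(self)
        brain = masks["brain"]
        occupied = np.zeros_like(brain)
        for side in SIDES:
            for structure in STRUCTURES:
                m = masks[side, structure]
                if not m.any():
                    raise GeometryError(f"{side} {structure} contains no voxels")
                if (m & ~brain).any():
                    raise GeometryError(f"{side} {structure} extends outside the brain")
                if (m & occupied).any():
                    raise GeometryError("striatal structures overlap")
                occupied |= m
        if brain[0, :, :].any() or brain[-1, :, :].any() or brain[:, 0, :].any() \
                or brain[:, -1, :].any() or brain[:, :, 0].any() or brain[:, :, -1].any():
            raise GeometryError("brain ellipsoid touches the grid boundary")

    # -- mask accessors -----------------------------------------------------

    def brain_mask(self) -> np.ndarray:
        return _geometry_masks(self)["brain"]

    def structure_mask(self, side: str, structure: str) -> np.ndarray:
        """Boolean mask for caudate, putamen or their union (striatum)."""
        masks = _geometry_masks(self)
        if structure == "striatum":
            return masks[side, "caudate"] | masks[side, "putamen"]
        try:
            return masks[side, structure]
        except KeyError:
            raise ValidationError(f"unknown structure {side!r}/{structure!r}") from None

    def structure_volume_ml(self, side: str, structure: str) -> float:
        """Voxelised structure volume in millilitres."""
        n = int(self.structure_mask(side, structure).sum())
        return n * self.voxel_size_mm**3 / 1000.0

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return _coordinate_grids(self.grid_shape, self.voxel_size_mm)


@lru_cache(maxsize=16)
def _coordinate_grids(
    grid_shape: tuple[int, int, int], voxel_size_mm: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [np.arange(n) * voxel_size_mm for n in grid_shape]
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    return tuple(grids)  # type: ignore[return-value]


def _ellipsoid_mask(
    geometry_shape: tuple[int, int, int],
    voxel_size_mm: float,
    center: tuple[float, float, float],
    radii: tuple[float, float, float],
) -> np.ndarray:
    xs, ys, zs = _coordinate_grids(geometry_shape, voxel_size_mm)
    q = (
        ((xs - center[0]) / radii[0]) ** 2
        + ((ys - center[1]) / radii[1]) ** 2
        + ((zs - center[2]) / radii[2]) ** 2
    )
    return q <= 1.0


@lru_cache(maxsize=16)
def _geometry_masks(geom: StriatalGeometry) -> dict:
    masks: dict = {
        "brain": _ellipsoid_mask(
            geom.grid_shape, geom.voxel_size_mm, geom.brain_center, geom.brain_radii
        )
    }
    for structure, centers, radii in (
        ("caudate", geom.caudate_centers, geom.caudate_radii),
        ("putamen", geom.putamen_centers, geom.putamen_radii),
    ):
        for side, center in zip(SIDES, centers):
            masks[side, structure] = _ellipsoid_mask(
                geom.grid_shape, geom.voxel_size_mm, center, radii
            )
    for m in masks.values():
        m.setflags(write=False)
    return masks


def default_geometry(
    grid_shape: tuple[int, int, int] = (128, 128, 128),
    voxel_size_mm: float = 2.0,
) -> StriatalGeometry:
    """Literature-typical striatal geometry centred in the grid.

    Per-side caudate/putamen volumes are ~5 and ~6 mL; positions are offsets
    from the brain centre so the geometry scales to any sufficiently large
    grid.
    """
    c = tuple(n * voxel_size_mm / 2.0 for n in grid_shape)

    def off(dx: float, dy: float, dz: float) -> tuple[float, float, float]:
        return (c[0] + dx, c[1] + dy, c[2] + dz)

    return StriatalGeometry(
        grid_shape=grid_shape,
        voxel_size_mm=voxel_size_mm,
        brain_center=c,  # type: ignore[arg-type]
        brain_radii=(65.0, 75.0, 55.0),
        caudate_centers=(off(13.0, 14.0, 4.0), off(-13.0, 14.0, 4.0)),
        caudate_radii=(6.5, 14.0, 13.0),
        putamen_centers=(off(29.0, -6.0, 0.0), off(-29.0, -6.0, 0.0)),
        putamen_radii=(8.5, 14.0, 12.0),
    )


@dataclass(frozen=True)
class ReconstructionModel:
    """Image-space surrogate of a tomographic reconstruction strategy.

    ACSC: iterative reconstruction with attenuation/scatter corrections —
    no residual scatter, no attenuation loss, non-negative. IRNC/FBP leave
    a scatter background and attenuation loss uncorrected; only FBP may
    produce negative voxel values.
    """

    mode: str
    psf_fwhm: float
    scatter_fraction: float = 0.0
    attenuation_scale: float = 1.0
    allow_negative: bool = False
    butterworth_cutoff: float | None = 0.55  # cycles/cm
    butterworth_power: float = 10.0
    fbp_noise_scale: float = 0.2  # streak-noise surrogate, FBP only

    def __post_init__(self) -> None:
        if self.mode not in RECON_MODES:
            raise ValidationError(f"unknown reconstruction mode {self.mode!r}")
        if self.psf_fwhm < 0:
            raise ValidationError("psf_fwhm must be >= 0")
        if self.scatter_fraction < 0 or self.scatter_fraction >= 1:
            raise ValidationError("scatter_fraction must be in [0, 1)")
        if not 0 < self.attenuation_scale <= 1:
            raise ValidationError("attenuation_scale must be in (0, 1]")
        if self.mode == "ACSC":
            if self.scatter_fraction != 0 or self.attenuation_scale != 1:
                raise ValidationError(
                    "ACSC applies corrections: scatter_fraction must be 0 and "
                    "attenuation_scale 1"
                )
        else:
            if self.scatter_fraction <= 0 or self.attenuation_scale >= 1:
                raise ValidationError(
                    f"{self.mode} is uncorrected: requires scatter_fraction > 0 "
                    "and attenuation_scale < 1"
                )
        if self.allow_negative and self.mode != "FBP":
            raise ValidationError("only FBP may allow negative voxel values")
        if self.butterworth_cutoff is not None and self.butterworth_cutoff <= 0:
            raise ValidationError("butterworth_cutoff must be positive or None")
        if self.butterworth_power <= 0:
            raise ValidationError("butterworth_power must be positive")

    @classmethod
    def preset(cls, mode: str, **overrides) -> "ReconstructionModel":
        defaults = {
            "ACSC": dict(psf_fwhm=9.0, scatter_fraction=0.0, attenuation_scale=1.0,
                         allow_negative=False),
            "IRNC": dict(psf_fwhm=10.0, scatter_fraction=0.25, attenuation_scale=0.75,
                         allow_negative=False),
            "FBP": dict(psf_fwhm=11.0, scatter_fraction=0.30, attenuation_scale=0.70,
                        allow_negative=True),
        }
        if mode not in defaults:
            raise ValidationError(f"unknown reconstruction mode {mode!r}")
        params = {**defaults[mode], **overrides}
        return cls(mode=mode, **params)


@dataclass(frozen=True)
class PhantomSpec:
    """Piecewise-constant striatal phantom with known true SBRs.

    ``true_sbr`` maps (side, structure) -> SBR for caudate and putamen;
    structure activity is background * (1 + true_sbr).
    """

    true_sbr: Mapping[tuple[str, str], float]
    background_concentration: float
    geometry: StriatalGeometry

    def __post_init__(self) -> None:
        if self.background_concentration <= 0:
            raise ValidationError("background_concentration must be positive")
        for key in _sbr_keys():
            if key not in self.true_sbr:
                raise ValidationError(f"true_sbr missing entry for {key}")
            if self.true_sbr[key] < 0:
                raise ValidationError(f"true_sbr for {key} must be >= 0")


def _sbr_keys() -> list[tuple[str, str]]:
    return [(side, structure) for side in SIDES for structure in STRUCTURES]


def uniform_true_sbr(value: float) -> dict[tuple[str, str], float]:
    """Same true SBR in every striatal structure (phantom-style filling)."""
    return {key: float(value) for key in _sbr_keys()}


def true_striatal_sbr(spec_sbr: Mapping[tuple[str, str], float],
                      geometry: StriatalGeometry, side: str) -> float:
    """Volume-weighted whole-striatum true SBR for one side."""
    vc = geometry.structure_volume_ml(side, "caudate")
    vp = geometry.structure_volume_ml(side, "putamen")
    return (vc * spec_sbr[side, "caudate"] + vp * spec_sbr[side, "putamen"]) / (vc + vp)


@dataclass(frozen=True)
class SubjectSpec:
    subject_id: str
    age: float
    disease_status: str  # "normal" | "abnormal"
    true_sbr: Mapping[tuple[str, str], float]
    scanner_id: str

    def __post_init__(self) -> None:
        if self.disease_status not in ("normal", "abnormal"):
            raise ValidationError("disease_status must be 'normal' or 'abnormal'")
        if not 0 < self.age < 120:
            raise ValidationError("age must be a plausible human age")
        for key in _sbr_keys():
            if key not in self.true_sbr:
                raise ValidationError(f"true_sbr missing entry for {key}")


@dataclass(frozen=True)
class CohortParams:
    n_normal: int
    n_abnormal: int
    age_range: tuple[float, float]
    healthy_intercept: float
    healthy_slope: float
    between_subject_sd: float
    putamen_loss_range: tuple[float, float] = (0.35, 0.75)
    caudate_loss_range: tuple[float, float] = (0.7, 1.0)
    asymmetry_range: tuple[float, float] = (0.0, 0.3)
    random_seed: int = 0
    scanner_ids: tuple[str, ...] = ("scanner-1",)

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_abnormal < 0:
            raise ValidationError("cohort sizes must be non-negative")
        if not self.age_range[0] < self.age_range[1]:
            raise ValidationError("age_range must be a non-empty interval")
        if self.healthy_slope >= 0:
            raise ValidationError("healthy_slope must be negative (age-related decline)")
        if self.between_subject_sd < 0:
            raise ValidationError("between_subject_sd must be >= 0")
        for lo, hi in (self.putamen_loss_range, self.caudate_loss_range):
            if not (0 < lo <= hi <= 1):
                raise ValidationError("loss factor ranges must lie in (0, 1]")
        if not (0 <= self.asymmetry_range[0] <= self.asymmetry_range[1]):
            raise ValidationError("asymmetry_range must be ordered and non-negative")
        if not self.scanner_ids:
            raise ValidationError("at least one scanner_id is required")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size_mm: float) -> float:
    return fwhm_mm / (FWHM_PER_SIGMA * voxel_size_mm)


def butterworth_gain(freq_cycles_per_cm: np.ndarray, cutoff: float, power: float) -> np.ndarray:
    """Low-pass gain 1 / (1 + (f/fc)^(2n)); gain at the cutoff is 0.5."""
    return 1.0 / (1.0 + (np.asarray(freq_cycles_per_cm, dtype=float) / cutoff) ** (2.0 * power))


def apply_butterworth(data: np.ndarray, voxel_size_mm: float,
                      cutoff: float, power: float) -> np.ndarray:
    """Apply the radial Butterworth filter in the 3D frequency domain."""
    shape = data.shape
    d_cm = voxel_size_mm / 10.0
    fx = np.fft.fftfreq(shape[0], d=d_cm)[:, None, None]
    fy = np.fft.fftfreq(shape[1], d=d_cm)[None, :, None]
    fz = np.fft.rfftfreq(shape[2], d=d_cm)[None, None, :]
    radial = np.sqrt(fx**2 + fy**2 + fz**2)
    spectrum = np.fft.rfftn(data)
    spectrum *= butterworth_gain(radial, cutoff, power)
    return np.fft.irfftn(spectrum, s=shape, axes=(0, 1, 2))


def _check_margin(geom: StriatalGeometry, fwhm_mm: float) -> None:
    # precondition: brain + 2*FWHM fits the grid
    for axis in range(3):
        lo = geom.brain_center[axis] - geom.brain_radii[axis]
        hi = geom.brain_center[axis] + geom.brain_radii[axis]
        extent = geom.grid_shape[axis] * geom.voxel_size_mm
        if lo - 2 * fwhm_mm < 0 or hi + 2 * fwhm_mm > extent:
            raise GeometryError(
                f"grid too small on axis {axis}: brain plus 2x FWHM margin "
                f"({2 * fwhm_mm:.1f} mm) exceeds the field of view"
            )


def activity_map(spec: PhantomSpec) -> np.ndarray:
    """Noise-free piecewise-constant activity distribution."""
    geom = spec.geometry
    act = np.zeros(geom.grid_shape, dtype=float)
    act[geom.brain_mask()] = spec.background_concentration
    for (side, structure), sbr in spec.true_sbr.items():
        act[geom.structure_mask(side, structure)] = (
            spec.background_concentration * (1.0 + sbr)
        )
    return act


def render_phantom(
    spec: PhantomSpec,
    recon: ReconstructionModel,
    seed: int,
    *,
    poisson: bool = True,
) -> CountVolume:
    """Render a striatal phantom through the reconstruction surrogate.

    Pipeline: piecewise-constant activity -> attenuation scale -> Gaussian
    PSF blur -> scatter redistribution (uniform over the brain, blurred at
    twice the PSF) -> Poisson noise (optional) -> Butterworth post-filter ->
    clip negatives unless the mode allows them.

    Blurs use circular boundary handling so that total counts are conserved
    exactly by the blur and scatter steps; the margin precondition keeps
    wrap-around leakage out of the brain.
    """
    geom = spec.geometry
    _check_margin(geom, recon.psf_fwhm)
    rng = np.random.default_rng(seed)

    img = activity_map(spec) * recon.attenuation_scale

    sigma = _fwhm_to_sigma_voxels(recon.psf_fwhm, geom.voxel_size_mm)
    if sigma > 0:
        img = ndimage.gaussian_filter(img, sigma, mode="wrap")

    if recon.scatter_fraction > 0:
        brain = geom.brain_mask()
        total = img.sum()
        scatter = np.zeros_like(img)
        scatter[brain] = total * recon.scatter_fraction / brain.sum()
        if sigma > 0:
            scatter = ndimage.gaussian_filter(scatter, 2 * sigma, mode="wrap")
        img = (1.0 - recon.scatter_fraction) * img + scatter

    if poisson:
        img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
        if recon.allow_negative and recon.fbp_noise_scale > 0:
            # white-noise surrogate for FBP streak noise; survives the
            # low-pass filter partially and can drive voxels negative
            img = img + rng.normal(
                0.0, recon.fbp_noise_scale * np.sqrt(np.clip(img, 0.0, None) + 1.0)
            )

    if recon.butterworth_cutoff is not None:
        img = apply_butterworth(
            img, geom.voxel_size_mm, recon.butterworth_cutoff, recon.butterworth_power
        )

    if not recon.allow_negative:
        img = np.clip(img, 0.0, None)

    return CountVolume(data=img, voxel_size_mm=geom.voxel_size_mm)


def render_subject(
    spec: SubjectSpec,
    recon: ReconstructionModel,
    phantom_geometry: StriatalGeometry,
    seed: int,
    *,
    background_concentration: float = 60.0,
    poisson: bool = True,
) -> CountVolume:
    """Render a subject volume: a phantom with the subject's true SBRs."""
    phantom = PhantomSpec(
        true_sbr=dict(spec.true_sbr),
        background_concentration=background_concentration,
        geometry=phantom_geometry,
    )
    return render_phantom(phantom, recon, seed, poisson=poisson)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def _healthy_line(params: CohortParams, age: float) -> float:
    return params.healthy_intercept + params.healthy_slope * age


def _draw_loss_factors(
    rng: np.random.Generator, params: CohortParams
) -> dict[tuple[str, str], float]:
    """Left/right loss factors: putamen-first, asymmetric degeneration."""
    affected, spared = rng.permutation(np.array(SIDES))
    factors: dict[tuple[str, str], float] = {}
    for structure, (lo, hi) in (
        ("putamen", params.putamen_loss_range),
        ("caudate", params.caudate_loss_range),
    ):
        base = rng.uniform(lo, hi)
        asym = rng.uniform(*params.asymmetry_range)
        factors[str(affected), structure] = base
        factors[str(spared), structure] = min(1.0, base * (1.0 + asym))
    return factors


def generate_cohort(params: CohortParams) -> list[SubjectSpec]:
    """Draw a cohort of subject specifications.

    Normal subjects sit on the healthy age line plus between-subject noise
    (identical in all structures); abnormal subjects additionally lose
    putaminal (and mildly caudate) uptake with left/right asymmetry, with the
    more-affected putamen guaranteed below the healthy age line.
    """
    rng = np.random.default_rng(params.random_seed)
    specs: list[SubjectSpec] = []
    statuses = ["normal"] * params.n_normal + ["abnormal"] * params.n_abnormal
    for i, status in enumerate(statuses):
        age = float(rng.uniform(*params.age_range))
        line = _healthy_line(params, age)
        base = line + float(rng.normal(0.0, params.between_subject_sd))
        base = max(base, 0.05)
        true_sbr = {key: base for key in _sbr_keys()}
        if status == "abnormal":
            factors = _draw_loss_factors(rng, params)
            for _ in range(100):
                true_sbr = {key: base * factors[key] for key in _sbr_keys()}
                worst_putamen = min(
                    true_sbr["left", "putamen"], true_sbr["right", "putamen"]
                )
                if worst_putamen < line:
                    break
                factors = _draw_loss_factors(rng, params)
            else:  # pragma: no cover - extreme parameterisations only
                scale = 0.95 * line / worst_putamen
                true_sbr = {k: v * scale for k, v in true_sbr.items()}
        prefix = "norm" if status == "normal" else "abn"
        specs.append(
            SubjectSpec(
                subject_id=f"{prefix}-{i:03d}",
                age=age,
                disease_status=status,
                true_sbr=true_sbr,
                scanner_id=params.scanner_ids[i % len(params.scanner_ids)],
            )
        )
    return specs


def closed_form_measured_sbr(
    true_sbr: float,
    recon: ReconstructionModel | None = None,
    bias: tuple[float, float] = (1.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> float:
    """Image-free surrogate measurement: ``a * true + b + Normal(0, sd)``.

    If a reconstruction model is supplied, the uncorrected scatter background
    shrinks the effective gain by attenuation / (attenuation + scatter) —
    attenuation itself cancels in a ratio, residual scatter dilutes it.
    """
    a, b = bias
    if a <= 0:
        raise ValidationError("quantifier bias slope must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    gain = 1.0
    if recon is not None:
        gain = recon.attenuation_scale / (recon.attenuation_scale + recon.scatter_fraction)
    value = a * gain * true_sbr + b
    if noise_sd > 0:
        value += float(np.random.default_rng(seed).normal(0.0, noise_sd))
    return float(value)


def subject_specs_to_rows(specs: list[SubjectSpec]) -> list[dict]:
    """Flatten specs to one row per subject-side-structure (CSV layout)."""
    rows = []
    for spec in specs:
        for (side, structure), value in sorted(spec.true_sbr.items()):
            rows.append(
                dict(
                    subject_id=spec.subject_id,
                    age=spec.age,
                    disease_status=spec.disease_status,
                    scanner_id=spec.scanner_id,
                    side=side,
                    structure=structure,
                    true_sbr=value,
                )
            )
    return rows
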