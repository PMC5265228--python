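"""SBR quantification from count volumes.

Two quantification philosophies:

* ``small_voi_sbr`` — tight volumes of interest over caudate/putamen with an
  occipital-like reference region; SBR is the count-density ratio
  (target mean - reference mean) / reference mean. Deliberately susceptible
  to partial-volume losses.
* ``large_voi_sbr`` — a generous per-side VOI that captures the whole blurred
  striatal signal; specific counts above background are normalised by a
  nominal striatal volume, making the result robust to the point-spread
  function at the cost of sensitivity to reference-region inhomogeneity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

from .errors import QuantificationError, ValidationError
from .synthdata import SIDES, CountVolume, StriatalGeometry

TARGET_STRUCTURES = ("caudate", "putamen", "striatum")


@dataclass(frozen=True)
class VOICode:
    side: str | None  # None for reference regions
    structure: str  # caudate | putamen | large_striatal | reference
    role: str  # target | reference


@dataclass
class VOISet:
    """Integer label volume plus a code table describing each label."""

    labels: np.ndarray
    codes: dict[int, VOICode]
    voxel_size_mm: float
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValidationError("VOI label volume must be 3-dimensional")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.codes)
        if missing:
            raise ValidationError(f"labels without code table entry: {sorted(missing)}")
        for code, entry in self.codes.items():
            if entry.role not in ("target", "reference"):
                raise ValidationError(f"code {code}: role must be target or reference")
        if self.brain_mask is not None and ((self.labels > 0) & ~self.brain_mask).any():
            raise ValidationError("labelled voxels must lie inside the brain mask")

    def mask(self, side: str | None, structure: str) -> np.ndarray:
        out = np.zeros(self.labels.shape, dtype=bool)
        found = False
        for code, entry in self.codes.items():
            if entry.structure == structure and (side is None or entry.side == side):
                out |= self.labels == code
                found = True
        if structure == "striatum":
            # striatum is the union of the caudate and putamen labels
            return self.mask(side, "caudate") | self.mask(side, "putamen")
        if not found:
            raise ValidationError(f"no VOI labelled {side!r}/{structure!r}")
        return out

    def reference_mask(self) -> np.ndarray:
        out = np.zeros(self.labels.shape, dtype=bool)
        for code, entry in self.codes.items():
            if entry.role == "reference":
                out |= self.labels == code
        return out


@dataclass
class SBRRecord:
    """One subject-side-structure SBR measurement."""

    subject_id: str
    side: str
    structure: str
    measured_sbr: float
    quantifier: str = ""  # small_voi | large_voi
    age: float = math.nan
    scanner_id: str = ""
    mode: str = ""  # reconstruction mode
    calibrated_sbr: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.measured_sbr):
            raise ValidationError("measured_sbr must be finite")

    @property
    def value(self) -> float:
        """Calibrated SBR when available, else the raw measurement."""
        return self.measured_sbr if self.calibrated_sbr is None else self.calibrated_sbr


# ---------------------------------------------------------------------------
# VOI construction from known geometry
# ---------------------------------------------------------------------------

SMALL_VOI_CODES = {
    1: VOICode("left", "caudate", "target"),
    2: VOICode("right", "caudate", "target"),
    3: VOICode("left", "putamen", "target"),
    4: VOICode("right", "putamen", "target"),
    9: VOICode(None, "reference", "reference"),
}

LARGE_VOI_CODES = {
    1: VOICode("left", "large_striatal", "target"),
    2: VOICode("right", "large_striatal", "target"),
    9: VOICode(None, "reference", "reference"),
}


def _distance_from(mask: np.ndarray, voxel_size_mm: float) -> np.ndarray:
    return ndimage.distance_transform_edt(~mask, sampling=voxel_size_mm)


def build_small_voi_set(
    geometry: StriatalGeometry,
    erosion_voxels: int = 1,
    reference_margin_mm: float = 14.0,
) -> VOISet:
    """Tight caudate/putamen VOIs plus a posterior (occipital-like) reference.

    Target masks are the true structure ellipsoids eroded by
    ``erosion_voxels``; the reference is the posterior part of the brain,
    pulled away from both the brain edge and the striatum by
    ``reference_margin_mm`` so it samples clean background.
    """
    if erosion_voxels < 0:
        raise ValidationError("erosion_voxels must be >= 0")
    labels = np.zeros(geometry.grid_shape, dtype=np.int16)
    striatum_all = np.zeros(geometry.grid_shape, dtype=bool)
    for code, entry in SMALL_VOI_CODES.items():
        if entry.role != "target":
            continue
        mask = geometry.structure_mask(entry.side, entry.structure)
        striatum_all |= mask
        if erosion_voxels:
            mask = ndimage.binary_erosion(mask, iterations=erosion_voxels)
        if not mask.any():
            raise ValidationError(
                f"erosion removed all voxels of {entry.side} {entry.structure}"
            )
        labels[mask] = code

    brain = geometry.brain_mask()
    _, ys, _ = geometry.coordinate_grids()
    posterior = np.broadcast_to(
        ys < geometry.brain_center[1] - 0.35 * geometry.brain_radii[1], brain.shape
    )
    interior = _distance_from(~brain, geometry.voxel_size_mm) >= reference_margin_mm
    clear_of_striatum = _distance_from(striatum_all, geometry.voxel_size_mm) >= reference_margin_mm
    reference = brain & posterior & interior & clear_of_striatum
    if not reference.any():
        raise ValidationError("reference margin leaves no reference voxels")
    labels[reference] = 9
    return VOISet(labels=labels, codes=dict(SMALL_VOI_CODES),
                  voxel_size_mm=geometry.voxel_size_mm, brain_mask=brain)


def build_large_voi_set(
    geometry: StriatalGeometry,
    margin_mm: float = 20.0,
    edge_margin_mm: float = 12.0,
) -> VOISet:
    """Per-side large striatal VOIs plus an all-remaining-brain reference.

    Each large VOI is the striatum dilated by ``margin_mm``, split at the
    mid-sagittal plane, and extruded into a prism over its axial slab so the
    summed-slices computation is exactly equivalent to the 3D one. The
    reference region is every brain voxel outside both large VOIs, excluding
    a band of ``edge_margin_mm`` at the brain surface where blur spill-out
    depresses the apparent background concentration.
    """
    if margin_mm <= 0:
        raise ValidationError("margin_mm must be positive")
    if edge_margin_mm < 0:
        raise ValidationError("edge_margin_mm must be >= 0")
    labels = np.zeros(geometry.grid_shape, dtype=np.int16)
    xs, _, _ = geometry.coordinate_grids()
    mid_x = geometry.brain_center[0]
    half = {
        "left": np.broadcast_to(xs > mid_x, geometry.grid_shape),
        "right": np.broadcast_to(xs <= mid_x, geometry.grid_shape),
    }
    vois = {}
    for code, side in ((1, "left"), (2, "right")):
        striatum = geometry.structure_mask(side, "striatum")
        dilated = _distance_from(striatum, geometry.voxel_size_mm) <= margin_mm
        dilated &= half[side]
        # extrude to a prism over the axial slab
        z_any = dilated.any(axis=(0, 1))
        footprint = dilated.any(axis=2)
        prism = footprint[:, :, None] & z_any[None, None, :]
        vois[code] = prism
        labels[prism] = code
    if (vois[1] & vois[2]).any():  # pragma: no cover - split makes this impossible
        raise ValidationError("left/right large VOIs overlap")
    brain = geometry.brain_mask()
    interior = brain
    if edge_margin_mm > 0:
        interior = _distance_from(~brain, geometry.voxel_size_mm) >= edge_margin_mm
    reference = interior & ~(vois[1] | vois[2])
    if not reference.any():
        raise ValidationError("large VOIs leave no reference voxels")
    labels[reference] = 9
    # brain_mask deliberately not attached: the prism VOIs may include a
    # small out-of-brain fringe, as 2D regions drawn on summed slices do
    return VOISet(labels=labels, codes=dict(LARGE_VOI_CODES),
                  voxel_size_mm=geometry.voxel_size_mm, brain_mask=None)


# ---------------------------------------------------------------------------
# quantifiers
# ---------------------------------------------------------------------------


def _check_alignment(volume: CountVolume, vois: VOISet) -> None:
    if volume.data.shape != vois.labels.shape:
        raise ValidationError("VOI set is not aligned to the count volume")
    if not math.isclose(volume.voxel_size_mm, vois.voxel_size_mm, rel_tol=1e-9):
        raise ValidationError("VOI set voxel size differs from the count volume")


def small_voi_sbr(
    volume: CountVolume,
    vois: VOISet,
    meta: Mapping[str, object] | None = None,
) -> list[SBRRecord]:
    """Count-density-ratio SBR per side for caudate, putamen and striatum.

    SBR = (target mean - reference mean) / reference mean; the striatum VOI
    is the union of the caudate and putamen voxels.
    """
    _check_alignment(volume, vois)
    reference = vois.reference_mask()
    if not reference.any():
        raise ValidationError("empty reference VOI")
    ref_mean = float(volume.data[reference].mean())
    if ref_mean <= 0:
        raise QuantificationError(f"non-positive reference mean ({ref_mean:.4g})")
    records = []
    meta = dict(meta or {})
    for side in SIDES:
        for structure in TARGET_STRUCTURES:
            mask = vois.mask(side, structure)
            if not mask.any():
                raise ValidationError(f"empty VOI for {side} {structure}")
            target_mean = float(volume.data[mask].mean())
            sbr = (target_mean - ref_mean) / ref_mean
            records.append(
                SBRRecord(
                    subject_id=str(meta.get("subject_id", "")),
                    side=side,
                    structure=structure,
                    measured_sbr=sbr,
                    quantifier="small_voi",
                    age=float(meta.get("age", math.nan)),
                    scanner_id=str(meta.get("scanner_id", "")),
                    mode=str(meta.get("mode", "")),
                )
            )
    return records


def large_voi_sbr(
    volume: CountVolume,
    vois: VOISet,
    nominal_striatal_volume_ml: float | Mapping[str, float],
    meta: Mapping[str, object] | None = None,
    use_slab: bool = True,
) -> list[SBRRecord]:
    """Total-count SBR over a large per-side VOI, normalised by nominal volume.

    Per side: specific counts = VOI total - reference concentration * VOI
    voxel count; SBR = specific counts / (reference concentration * voxel
    equivalent of the nominal striatal volume). Computed on the summed axial
    slab spanning the VOI (identical to the 3D computation for prism VOIs).
    """
    _check_alignment(volume, vois)
    if nominal_striatal_volume_ml is None:
        raise ValidationError("nominal striatal volume is required")
    meta = dict(meta or {})
    records = []
    brain_ref = vois.reference_mask()
    if not brain_ref.any():
        raise ValidationError("empty reference region")
    voxel_ml = volume.voxel_volume_ml
    for side in SIDES:
        voi = vois.mask(side, "large_striatal")
        if not voi.any():
            raise ValidationError(f"empty large VOI for side {side}")
        if _touches_boundary(voi):
            warnings.warn(
                f"large VOI ({side}) touches the volume boundary; "
                "spill-out counts are not captured",
                stacklevel=2,
            )
        nominal_ml = (
            float(nominal_striatal_volume_ml[side])
            if isinstance(nominal_striatal_volume_ml, Mapping)
            else float(nominal_striatal_volume_ml)
        )
        if nominal_ml <= 0:
            raise ValidationError("nominal striatal volume must be positive")
        nominal_voxels = nominal_ml / voxel_ml

        if use_slab:
            sbr = _slab_sbr(volume.data, voi, brain_ref, nominal_voxels)
        else:
            n_voi = voi.sum()
            ref_conc = float(volume.data[brain_ref].mean())
            if ref_conc <= 0:
                raise QuantificationError("non-positive reference concentration")
            specific = float(volume.data[voi].sum()) - ref_conc * n_voi
            sbr = specific / (ref_conc * nominal_voxels)

        records.append(
            SBRRecord(
                subject_id=str(meta.get("subject_id", "")),
                side=side,
                structure="striatum",
                measured_sbr=sbr,
                quantifier="large_voi",
                age=float(meta.get("age", math.nan)),
                scanner_id=str(meta.get("scanner_id", "")),
                mode=str(meta.get("mode", "")),
            )
        )
    return records


def _touches_boundary(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )


def _slab_sbr(
    data: np.ndarray,
    voi: np.ndarray,
    reference: np.ndarray,
    nominal_voxels: float,
) -> float:
    """Summed-axial-slab large-VOI SBR.

    The slab is the minimal set of axial (z) slices covering the VOI. The
    reference concentration per voxel is estimated from columns of the
    reference region that are present throughout the slab, so partially
    covered edge columns do not bias it.
    """
    z_any = voi.any(axis=(0, 1))
    z_idx = np.nonzero(z_any)[0]
    z0, z1 = int(z_idx[0]), int(z_idx[-1]) + 1
    n_slices = z1 - z0
    summed = data[:, :, z0:z1].sum(axis=2)
    voi_cols = voi[:, :, z0:z1].any(axis=2)
    ref_cols = reference[:, :, z0:z1].all(axis=2) & ~voi_cols
    if not ref_cols.any():
        raise QuantificationError("no complete reference columns inside the slab")
    ref_per_voxel = float(summed[ref_cols].mean()) / n_slices
    if ref_per_voxel <= 0:
        raise QuantificationError(
            f"non-positive reference concentration ({ref_per_voxel:.4g})"
        )
    n_voi_voxels = int(voi_cols.sum()) * n_slices
    specific = float(summed[voi_cols].sum()) - ref_per_voxel * n_voi_voxels
    return specific / (ref_per_voxel * nominal_voxels)


def records_by_region(records: Iterable[SBRRecord]) -> dict[tuple[str, str], SBRRecord]:
    return {(r.side, r.structure): r for r in records}
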