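import numpy as np
import pytest

from datspect_normdb import (
    PhantomSpec,
    ReconstructionModel,
    StriatalGeometry,
    default_geometry,
)
from datspect_normdb.synthdata import uniform_true_sbr


def make_geometry(
    grid=(48, 48, 48),
    voxel=3.0,
    brain_radii=(50.0, 55.0, 45.0),
    caudate_offset=(10.0, 10.0, 3.0),
    caudate_radii=(5.0, 10.0, 9.0),
    putamen_offset=(22.0, -5.0, 0.0),
    putamen_radii=(6.5, 10.5, 9.0),
) -> StriatalGeometry:
    center = tuple(n * voxel / 2.0 for n in grid)

    def off(sign, d):
        return (center[0] + sign * d[0], center[1] + d[1], center[2] + d[2])

    return StriatalGeometry(
        grid_shape=grid,
        voxel_size_mm=voxel,
        brain_center=center,
        brain_radii=brain_radii,
        caudate_centers=(off(+1, caudate_offset), off(-1, caudate_offset)),
        caudate_radii=caudate_radii,
        putamen_centers=(off(+1, putamen_offset), off(-1, putamen_offset)),
        putamen_radii=putamen_radii,
    )


@pytest.fixture(scope="session")
def tiny_geometry() -> StriatalGeometry:
    """Small, fast grid; supports PSF FWHM up to ~8 mm."""
    return make_geometry()


@pytest.fixture(scope="session")
def big_geometry() -> StriatalGeometry:
    """Roomy brain for large-VOI margin experiments (margins up to ~40 mm)."""
    return make_geometry(
        grid=(96, 96, 96),
        brain_radii=(95.0, 105.0, 85.0),
        caudate_offset=(13.0, 14.0, 4.0),
        caudate_radii=(6.5, 14.0, 13.0),
        putamen_offset=(29.0, -6.0, 0.0),
        putamen_radii=(8.5, 14.0, 12.0),
    )


@pytest.fixture(scope="session")
def study_geometry() -> StriatalGeometry:
    """The default study geometry at desk scale."""
    return default_geometry((64, 72, 64), 3.0)


def identity_recon() -> ReconstructionModel:
    """ACSC with no blur and no post-filter: the identity pipeline."""
    return ReconstructionModel(mode="ACSC", psf_fwhm=0.0, butterworth_cutoff=None)


def acsc(fwhm: float, butterworth: bool = True) -> ReconstructionModel:
    return ReconstructionModel(
        mode="ACSC",
        psf_fwhm=fwhm,
        butterworth_cutoff=0.55 if butterworth else None,
    )


def uniform_phantom(geometry, sbr=5.0, background=100.0) -> PhantomSpec:
    return PhantomSpec(
        true_sbr=uniform_true_sbr(sbr),
        background_concentration=background,
        geometry=geometry,
    )


def auc_pair_count(scores, labels) -> float:
    """Brute-force Mann-Whitney AUC; lower score = abnormal, ties 1/2."""
    pos = [s for s, is_abn in zip(scores, labels) if is_abn]
    neg = [s for s, is_abn in zip(scores, labels) if not is_abn]
    total = 0.0
    for p in pos:
        for q in neg:
            if p < q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
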