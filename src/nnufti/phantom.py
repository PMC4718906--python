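"""Seeded digital liver phantoms for end-to-end testing of the pipeline.

A phantom emulates the statistical structure the nNUFTI method relies
on: an ellipsoidal liver VOI filled with spatially non-uniform hepatic
uptake (a smooth gain field over a mean background concentration),
independent Poisson count noise per voxel, Gaussian PSF blur standing in
for camera resolution, and optional hot spherical lesions at a given
tumour-to-normal concentration ratio (TNC).

Lesion counts are drawn as an *additive* independent Poisson stream
(valid because Poisson(lambda*tnc) = Poisson(lambda) + Poisson(lambda*(tnc-1))),
so a lesioned phantom shares byte-identical background noise with the
tumour-free phantom generated from the same seed.  Paired comparisons
between a liver and its tumour-free twin are therefore true
common-random-number experiments.

The PSF is applied as mask-normalized Gaussian convolution (blurred
counts divided by the blurred VOI indicator, inside the VOI).  Plain
convolution would bleed counts across the liver boundary and bias the
mean VOI concentration low by several percent; the normalized form
keeps the realized mean concentration tracking ``lambda_bg``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import PhantomSpecError
from .volume_io import LiverVOI, SpectVolume


@dataclass(frozen=True)
class Lesion:
    """A hot sphere: centre in mm (grid coordinates * spacing), radius, TNC."""

    centre_mm: tuple[float, float, float]
    radius_mm: float
    tnc: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise PhantomSpecError(f"lesion radius must be > 0, got {self.radius_mm}")
        if self.tnc < 1:
            raise PhantomSpecError(f"TNC must be >= 1, got {self.tnc}")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic liver volume.

    Defaults give a 64x64x48 grid of 4 mm voxels holding an ellipsoidal
    liver of ~32k voxels at a mean background concentration of
    60 counts/voxel, a +/-20% linear uptake gradient along the first
    axis (highest in the right lobe, as seen clinically), and a 2 mm
    PSF sigma.  The sub-voxel sigma reflects that the analysed volumes
    are deliberately *unfiltered*: their noise texture stays close to
    voxel scale, while the blur still produces partial-volume edges on
    lesions.  Identical specs (including seed) generate identical
    volumes.
    """

    shape: tuple[int, int, int] = (64, 64, 48)
    voxel_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    centre_mm: tuple[float, float, float] | None = None
    semi_axes_mm: tuple[float, float, float] = (88.0, 76.0, 60.0)
    lambda_bg: float = 60.0
    nonuniformity: float = 0.2
    psf_sigma_mm: float = 2.0
    lesions: tuple[Lesion, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_bg <= 0:
            raise PhantomSpecError(f"lambda_bg must be > 0, got {self.lambda_bg}")
        if not 0 <= self.nonuniformity < 1:
            raise PhantomSpecError(
                f"nonuniformity amplitude must be in [0, 1), got {self.nonuniformity}"
            )
        if self.psf_sigma_mm < 0:
            raise PhantomSpecError("psf_sigma_mm must be >= 0")
        object.__setattr__(self, "lesions", tuple(self.lesions))

    @property
    def resolved_centre_mm(self) -> tuple[float, float, float]:
        if self.centre_mm is not None:
            return self.centre_mm
        return tuple((n - 1) / 2 * v for n, v in zip(self.shape, self.voxel_mm))


def _coordinate_grids(spec: PhantomSpec) -> list[np.ndarray]:
    axes = [np.arange(n) * v for n, v in zip(spec.shape, spec.voxel_mm)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    grids = _coordinate_grids(spec)
    centre = spec.resolved_centre_mm
    q = sum(((g - c) / a) ** 2
            for g, c, a in zip(grids, centre, spec.semi_axes_mm))
    return q <= 1.0


def _lesion_mask(spec: PhantomSpec, lesion: Lesion) -> np.ndarray:
    grids = _coordinate_grids(spec)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, lesion.centre_mm))
    return d2 <= lesion.radius_mm**2


def _gain_field(spec: PhantomSpec) -> np.ndarray:
    # linear gradient along axis 0, spanning 1 +/- a over the ellipsoid
    grids = _coordinate_grids(spec)
    c0 = spec.resolved_centre_mm[0]
    gain = 1.0 + spec.nonuniformity * (grids[0] - c0) / spec.semi_axes_mm[0]
    return np.broadcast_to(gain, spec.shape).copy()


def generate_phantom(spec: PhantomSpec) -> tuple[SpectVolume, LiverVOI, np.ndarray]:
    """Generate (volume, liver VOI, lesion truth mask) from a spec.

    The intensity field is lambda_bg * gain(x) inside the VOI, scaled by
    TNC inside each lesion, and zero outside; counts are Poisson per
    voxel, then PSF-blurred.  Deterministic given the spec (incl. seed).
    """
    voi_mask = _ellipsoid_mask(spec)
    if not voi_mask.any():
        raise PhantomSpecError("ellipsoid VOI selects no voxels")
    lam = spec.lambda_bg * _gain_field(spec) * voi_mask

    truth = np.zeros(spec.shape, dtype=bool)
    lesion_masks = []
    for lesion in spec.lesions:
        mask = _lesion_mask(spec, lesion)
        if not mask.any():
            raise PhantomSpecError(f"lesion at {lesion.centre_mm} covers no voxel")
        if (mask & ~voi_mask).any():
            raise PhantomSpecError(
                f"lesion at {lesion.centre_mm} extends outside the liver VOI"
            )
        lesion_masks.append((lesion, mask))
        truth |= mask

    ss_bg, ss_les = np.random.SeedSequence(spec.seed).spawn(2)
    counts = np.random.default_rng(ss_bg).poisson(lam).astype(np.float64)
    if lesion_masks:
        rng_les = np.random.default_rng(ss_les)
        for lesion, mask in lesion_masks:
            extra_lam = lam * (lesion.tnc - 1.0) * mask
            counts += rng_les.poisson(extra_lam)

    if spec.psf_sigma_mm > 0:
        sigma_vox = [spec.psf_sigma_mm / v for v in spec.voxel_mm]
        blurred = ndi.gaussian_filter(counts, sigma_vox)
        support = ndi.gaussian_filter(voi_mask.astype(np.float64), sigma_vox)
        with np.errstate(divide="ignore", invalid="ignore"):
            counts = np.where(voi_mask, blurred / support, 0.0)

    volume = SpectVolume(values=counts, spacing=spec.voxel_mm)
    return volume, LiverVOI(mask=voi_mask), truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

LesionSampler = Callable[[np.random.Generator, PhantomSpec], Sequence[Lesion]]


@dataclass(frozen=True)
class DefaultLesionSampler:
    """Samples 1-3 hot spheres of 8-16 mm radius at TNC 3-6.

    Centres are uniform within 70% of each semi-axis minus the lesion
    radius, which keeps every lesion strictly inside the VOI.
    """

    n_min: int = 1
    n_max: int = 3
    radius_mm: tuple[float, float] = (8.0, 16.0)
    tnc: tuple[float, float] = (3.0, 6.0)

    def __call__(self, rng: np.random.Generator, spec: PhantomSpec) -> list[Lesion]:
        n = int(rng.integers(self.n_min, self.n_max + 1))
        centre = spec.resolved_centre_mm
        lesions = []
        for _ in range(n):
            radius = float(rng.uniform(*self.radius_mm))
            tnc = float(rng.uniform(*self.tnc))
            # rejection-free placement: uniform in a shrunken ellipsoid
            while True:
                u = rng.uniform(-1, 1, size=3)
                if (u**2).sum() <= 1:
                    break
            pos = tuple(
                c + ui * max(0.7 * a - radius, 0.0)
                for c, ui, a in zip(centre, u, spec.semi_axes_mm)
            )
            lesions.append(Lesion(centre_mm=pos, radius_mm=radius, tnc=tnc))
        return lesions


class StudyBurdenSampler:
    """Mixed-burden lesion sampler emulating a benchmark scan-positive cohort.

    Alternates between *minor* burden — a single small lesion at low
    tumour-to-normal ratio (TNC 1.3-1.8), placed in the low-uptake half
    of the liver so its peak intensity competes with, rather than
    dominates, the hottest normal segment — and *high* burden (1-3
    lesions at TNC 3-6 anywhere in the VOI).  Minor-burden livers
    compress only the right branch of the nNUFTI curve; high-burden
    livers shift both branches.  A cohort mixing the two therefore
    separates from tumour-free livers most consistently on the right
    branch, which is what makes the right-side crossing the preferred
    operating point.

    The instance is stateful (an internal counter alternates burden);
    use a fresh instance per cohort for reproducible output.
    """

    def __init__(self) -> None:
        self._index = 0
        self._high = DefaultLesionSampler(
            n_min=1, n_max=3, radius_mm=(8.0, 16.0), tnc=(3.0, 6.0))

    def __call__(self, rng: np.random.Generator, spec: PhantomSpec) -> list[Lesion]:
        minor = self._index % 2 == 0
        self._index += 1
        if not minor:
            return self._high(rng, spec)
        radius = float(rng.uniform(8.0, 12.0))
        tnc = float(rng.uniform(1.3, 1.8))
        centre = spec.resolved_centre_mm
        while True:
            u = rng.uniform(-1, 1, size=3)
            u[0] = -abs(u[0])  # low-gain half of axis 0
            if (u**2).sum() <= 1:
                break
        pos = tuple(
            c + ui * max(0.7 * a - radius, 0.0)
            for c, ui, a in zip(centre, u, spec.semi_axes_mm)
        )
        return [Lesion(centre_mm=pos, radius_mm=radius, tnc=tnc)]


@dataclass(frozen=True)
class CohortMember:
    spec: PhantomSpec
    volume: SpectVolume
    voi: LiverVOI
    truth: np.ndarray
    label: str  # "neg" | "pos"


def member_seed(master_seed: int, index: int) -> int:
    """Deterministic per-member seed derived from the cohort master seed."""
    child = np.random.SeedSequence(master_seed).spawn(index + 1)[index]
    return int(child.generate_state(1)[0] & 0x7FFFFFFF)


def generate_cohort(
    n_neg: int,
    n_pos: int,
    base_spec: PhantomSpec = PhantomSpec(),
    lesion_sampler: LesionSampler | None = None,
    seed: int = 0,
) -> list[CohortMember]:
    """Generate a labelled cohort: n_neg tumour-free, n_pos lesioned livers.

    Member seeds derive deterministically from ``seed``; the lesion
    sampler for member i uses an RNG independent of the member's voxel
    noise, so negatives and positives at the same index share nothing
    but the base spec.
    """
    if n_neg < 0 or n_pos < 0:
        raise PhantomSpecError("cohort sizes must be >= 0")
    sampler = lesion_sampler or DefaultLesionSampler()
    members: list[CohortMember] = []
    for i in range(n_neg + n_pos):
        mseed = member_seed(seed, i)
        label = "neg" if i < n_neg else "pos"
        spec = replace(base_spec, seed=mseed, lesions=())
        if label == "pos":
            lesion_rng = np.random.default_rng(
                np.random.SeedSequence([seed, i, 0x1E510]).generate_state(1)[0]
            )
            spec = replace(spec, lesions=tuple(sampler(lesion_rng, base_spec)))
        volume, voi, truth = generate_phantom(spec)
        members.append(CohortMember(spec=spec, volume=volume, voi=voi,
                                    truth=truth, label=label))
    return members
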