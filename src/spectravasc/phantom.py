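"""Synthetic intravital phantoms with ground truth.

Stands in for the camera: grows stochastic branching vessel trees in a 2-D
field of view, rasterizes them to a ground-truth mask plus a per-pixel blood
path-length (thickness) map, renders each excitation/emission channel through
the Beer-Lambert model over a uniform autofluorescent background, and derives
a histology-style microvessel-density (MVD) analog by counting distinct vessel
objects in randomly placed subfields.

Geometry is 2-D with an analytic thickness map: the imaging method only probes
superficial tissue, so depth is collapsed into the per-pixel optical path
2*sqrt(r^2 - d^2) through a cylindrical vessel of radius r at lateral
distance d from the centerline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

from .imaging_io import SpectralLibrary
from .spectral_model import (
    DEFAULT_CHANNELS,
    AbsorptionSpectrum,
    ChannelSpec,
    TissueOptics,
    WHOLE_BLOOD,
    effective_attenuation,
)

__all__ = [
    "VesselSegment",
    "VesselNetwork",
    "PhantomSpec",
    "GroundTruth",
    "CohortSpec",
    "generate_vessel_network",
    "rasterize_network",
    "make_ground_truth",
    "render_channel",
    "render_library",
    "mvd_analog_count",
    "generate_cohort",
]


@dataclass(frozen=True)
class VesselSegment:
    """A straight capsule: centerline from p0 to p1 (mm), constant radius."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.p0 == self.p1:
            raise ValueError("segment endpoints must differ")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")


@dataclass(frozen=True)
class VesselNetwork:
    segments: tuple[VesselSegment, ...] = ()

    def __len__(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class PhantomSpec:
    """Field-of-view geometry plus vessel-growth and noise parameters.

    Defaults emulate wide-field intravital imaging of a mammary fat pad at
    7.5 um/pixel: a ~2.9 mm field holding many short vessels of 30-50 um
    calibre (each tree has a bounded footprint, so a denser vasculature means
    more vessels, as in neoangiogenesis), a vessel area fraction of a few
    percent in controls, and mild additive sensor noise on the normalized
    0-1 intensity scale.
    """

    width_px: int = 384
    height_px: int = 384
    pixel_pitch_mm: float = 0.0075
    n_trees: int = 4
    branch_prob: float = 0.08
    branch_angle_sd: float = 0.5
    step_mm: float = 0.06
    initial_radius_mm: float = 0.025
    radius_decay: float = 0.9
    min_radius_mm: float = 0.015
    max_tip_steps: int = 8
    vessel_area_target: Optional[float] = None
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("field dimensions must be positive")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be > 0")
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        if self.vessel_area_target is not None and not (
            0.0 <= self.vessel_area_target < 0.5
        ):
            raise ValueError("vessel_area_target must lie in [0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def field_mm(self) -> tuple[float, float]:
        return (self.width_px * self.pixel_pitch_mm, self.height_px * self.pixel_pitch_mm)


@dataclass
class GroundTruth:
    """Rasterized truth for one phantom: mask, blood path map, area, MVD analog."""

    mask: np.ndarray  # bool, 1 = vessel
    thickness_map: np.ndarray  # mm of blood traversed per pixel
    pixel_pitch_mm: float
    true_area_mm2: float
    mvd_analog: Optional[int] = None


@dataclass(frozen=True)
class CohortSpec:
    """Tumor-vs-control study layout mirroring the validation cohort design.

    Tumor subjects grow vasculature to ``tumor_area_multiplier`` times the
    control area target.  ``area_jitter_sd`` is the log-scale SD of the
    per-subject multiplicative spread of the area target (biological
    variability between animals).
    """

    n_control: int = 3
    n_tumor: int = 13
    tumor_area_multiplier: float = 3.0
    template: PhantomSpec = field(
        default_factory=lambda: PhantomSpec(vessel_area_target=0.06)
    )
    area_jitter_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_tumor < 1:
            raise ValueError("each group needs at least one subject")
        if self.tumor_area_multiplier <= 1.0:
            raise ValueError("tumor_area_multiplier must be > 1")
        if self.template.vessel_area_target is None:
            raise ValueError("cohort template must set vessel_area_target")


# ---------------------------------------------------------------------------
# growth


def _seed_tip(rng: np.random.Generator, spec: PhantomSpec) -> dict:
    """Start a tree at a uniform field position with a uniform heading."""
    w_mm, h_mm = spec.field_mm
    pos = (rng.uniform(0, w_mm), rng.uniform(0, h_mm))
    angle = rng.uniform(0.0, 2.0 * math.pi)
    return {"pos": pos, "angle": angle, "radius": spec.initial_radius_mm, "steps": 0}


def generate_vessel_network(
    spec: PhantomSpec, seed: Optional[int] = None
) -> VesselNetwork:
    """Grow a branching vessel network by a biased random walk.

    Trees start on the field edges and meander inward; each step extends the
    tip by ``step_mm`` with angular jitter, and with probability
    ``branch_prob`` spawns a child whose radius is the parent's times
    ``radius_decay``.  Tips die when they leave the field or fall below
    ``min_radius_mm``.  When ``vessel_area_target`` is set, growth stops the
    first time the rasterized vessel fraction reaches the target (new roots
    are seeded if all tips die before that).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if spec.n_trees == 0:
        return VesselNetwork()

    w_mm, h_mm = spec.field_mm
    target = spec.vessel_area_target
    total_px = spec.width_px * spec.height_px
    mask = np.zeros((spec.height_px, spec.width_px), dtype=bool)
    segments: list[VesselSegment] = []
    clearance_iter = 2  # px of open tissue kept between distinct trees

    def fraction() -> float:
        return float(mask.sum()) / total_px

    def grow_tree() -> list[VesselSegment]:
        """Propose one bounded tree as a segment list (no global mutation)."""
        tree: list[VesselSegment] = []
        tips = [_seed_tip(rng, spec)]
        while tips:
            tip = tips.pop()
            x, y = tip["pos"]
            angle = tip["angle"] + rng.normal(0.0, spec.branch_angle_sd / 2)
            nx = x + spec.step_mm * math.cos(angle)
            ny = y + spec.step_mm * math.sin(angle)
            tree.append(VesselSegment((x, y), (nx, ny), tip["radius"]))
            tip.update(pos=(nx, ny), angle=angle, steps=tip["steps"] + 1)
            alive = (
                0.0 <= nx <= w_mm
                and 0.0 <= ny <= h_mm
                and tip["steps"] < spec.max_tip_steps
            )
            if alive:
                tips.append(tip)
                if rng.random() < spec.branch_prob:
                    child_r = tip["radius"] * spec.radius_decay
                    if child_r >= spec.min_radius_mm:
                        sign = 1.0 if rng.random() < 0.5 else -1.0
                        tips.append(
                            {
                                "pos": (nx, ny),
                                "angle": angle
                                + sign * abs(rng.normal(0.0, spec.branch_angle_sd)),
                                "radius": child_r,
                                "steps": 0,
                            }
                        )
        return tree

    # Rejection placement: a proposed tree is committed only if, after a
    # small clearance dilation, it touches no previously placed vessel.
    # Vessels therefore stay spatially distinct (as perfusion spacing keeps
    # them in tissue) and a denser vasculature means more vessel objects.
    accepted = 0
    proposals = 0
    max_proposals = 20_000
    while proposals < max_proposals:
        if target is not None:
            if fraction() >= target:
                break
        elif accepted >= spec.n_trees:
            break
        proposals += 1
        tree = grow_tree()
        scratch = np.zeros_like(mask)
        for seg in tree:
            _rasterize_into(
                seg, spec.width_px, spec.height_px, spec.pixel_pitch_mm, mask=scratch
            )
        if not scratch.any():
            continue
        inflated = ndi.binary_dilation(
            scratch, structure=np.ones((3, 3), dtype=bool), iterations=clearance_iter
        )
        if (inflated & mask).any():
            continue
        mask |= scratch
        segments.extend(tree)
        accepted += 1
    return VesselNetwork(tuple(segments))


# ---------------------------------------------------------------------------
# rasterization

def _rasterize_into(
    seg: VesselSegment,
    width_px: int,
    height_px: int,
    pitch: float,
    mask: Optional[np.ndarray] = None,
    dist: Optional[np.ndarray] = None,
    radius: Optional[np.ndarray] = None,
) -> None:
    """Capsule test for one segment over its bounding box of pixel centers.

    Updates ``mask`` in place; when ``dist``/``radius`` arrays are given,
    keeps per-pixel the nearest covering segment (for the thickness map).
    """
    (x0, y0), (x1, y1), r = seg.p0, seg.p1, seg.radius_mm
    cmin = max(0, int((min(x0, x1) - r) / pitch - 1))
    cmax = min(width_px - 1, int((max(x0, x1) + r) / pitch + 1))
    rmin = max(0, int((min(y0, y1) - r) / pitch - 1))
    rmax = min(height_px - 1, int((max(y0, y1) + r) / pitch + 1))
    if cmin > cmax or rmin > rmax:
        return
    cols = np.arange(cmin, cmax + 1)
    rows = np.arange(rmin, rmax + 1)
    px = (cols + 0.5) * pitch
    py = (rows + 0.5) * pitch
    X, Y = np.meshgrid(px, py)
    dx, dy = x1 - x0, y1 - y0
    seg_len2 = dx * dx + dy * dy
    t = ((X - x0) * dx + (Y - y0) * dy) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    d = np.hypot(X - (x0 + t * dx), Y - (y0 + t * dy))
    cover = d <= r
    if mask is not None:
        mask[rmin : rmax + 1, cmin : cmax + 1] |= cover
    if dist is not None and radius is not None:
        sub_d = dist[rmin : rmax + 1, cmin : cmax + 1]
        sub_r = radius[rmin : rmax + 1, cmin : cmax + 1]
        take = cover & (d < sub_d)
        sub_d[take] = d[take]
        sub_r[take] = r


def rasterize_network(
    net: VesselNetwork, width_px: int, height_px: int, pixel_pitch_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize to a (mask, thickness_map) pair on the pixel-center grid.

    A pixel is vessel iff its center lies within one segment radius of a
    centerline; the thickness map holds the chord 2*sqrt(r^2 - d^2) of the
    nearest covering segment (mm of blood traversed at that pixel).
    """
    if width_px <= 0 or height_px <= 0 or pixel_pitch_mm <= 0:
        raise ValueError("dimensions and pitch must be positive")
    mask = np.zeros((height_px, width_px), dtype=bool)
    dist = np.full((height_px, width_px), np.inf)
    radius = np.zeros((height_px, width_px))
    for seg in net.segments:
        _rasterize_into(
            seg, width_px, height_px, pixel_pitch_mm, mask=mask, dist=dist, radius=radius
        )
    thickness = np.zeros_like(radius)
    covered = np.isfinite(dist) & mask
    thickness[covered] = 2.0 * np.sqrt(
        np.maximum(radius[covered] ** 2 - dist[covered] ** 2, 0.0)
    )
    return mask, thickness


def make_ground_truth(net: VesselNetwork, spec: PhantomSpec) -> GroundTruth:
    mask, thickness = rasterize_network(
        net, spec.width_px, spec.height_px, spec.pixel_pitch_mm
    )
    area = float(mask.sum()) * spec.pixel_pitch_mm**2
    return GroundTruth(mask, thickness, spec.pixel_pitch_mm, area)


# ---------------------------------------------------------------------------
# rendering

def render_channel(
    truth: GroundTruth,
    channel: ChannelSpec,
    optics: TissueOptics = TissueOptics(),
    blood: AbsorptionSpectrum = WHOLE_BLOOD,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render one channel: I = I_bg * exp(-mu_eff * thickness) + noise, in [0, 1].

    I_bg is the autofluorescence yield for filtered channels and the
    reflectance background for no-filter channels; mu_eff is the round-trip
    attenuation of the channel through blood.  Deterministic for a fixed seed.
    """
    mu = effective_attenuation(channel, blood)
    bg = optics.background_for(channel)
    img = bg * np.exp(-mu * truth.thickness_map)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def render_library(
    truth: GroundTruth,
    channels: Sequence[ChannelSpec] = DEFAULT_CHANNELS,
    optics: TissueOptics = TissueOptics(),
    blood: AbsorptionSpectrum = WHOLE_BLOOD,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SpectralLibrary:
    """Render every channel of a phantom into a spectral library."""
    images = {}
    for i, ch in enumerate(channels):
        images[ch] = render_channel(
            truth, ch, optics, blood, noise_sd=noise_sd, seed=seed + i
        )
    return SpectralLibrary(
        channels=images,
        pixel_pitch_mm=truth.pixel_pitch_mm,
        meta={"source": "phantom", "noise_sd": noise_sd, "seed": seed},
    )


# ---------------------------------------------------------------------------
# MVD analog

def mvd_analog_count(
    truth: GroundTruth, n_fields: int = 4, field_px: int = 64, seed: int = 0
) -> int:
    """Histology-style vessel count: distinct vessel objects per subfield.

    Emulates counting each stained endothelial cluster in 3-6 randomly chosen
    optical fields as an individual vessel: the mean over ``n_fields`` random
    subfields of the number of 8-connected vessel objects seen inside the
    subfield (two branches of one tree whose junction lies outside the field
    count as two profiles, exactly as on a histological section), rounded to
    the nearest integer.
    """
    if not 3 <= n_fields <= 6:
        raise ValueError("n_fields must lie in [3, 6]")
    h, w = truth.mask.shape
    if field_px > min(h, w):
        raise ValueError(f"field_px {field_px} larger than image {h}x{w}")
    structure = np.ones((3, 3), dtype=int)
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_fields):
        r0 = int(rng.integers(0, h - field_px + 1))
        c0 = int(rng.integers(0, w - field_px + 1))
        window = truth.mask[r0 : r0 + field_px, c0 : c0 + field_px]
        _, n_objects = ndi.label(window, structure=structure)
        counts.append(int(n_objects))
    return int(math.floor(float(np.mean(counts)) + 0.5))


# ---------------------------------------------------------------------------
# cohorts

def _subject_seed(cohort_seed: int, index: int) -> int:
    """Deterministic per-subject seed, independent of global RNG state."""
    return int(np.random.SeedSequence((cohort_seed, index)).generate_state(1)[0] % (2**31))


def generate_cohort(
    cs: CohortSpec,
    channels: Sequence[ChannelSpec] = DEFAULT_CHANNELS,
    optics: TissueOptics = TissueOptics(),
    blood: AbsorptionSpectrum = WHOLE_BLOOD,
) -> list[tuple[SpectralLibrary, GroundTruth, str]]:
    """Generate control + tumor subjects with per-subject derived seeds.

    Each subject gets an area target drawn around the group target (log-normal
    jitter of SD ``area_jitter_sd``), a freshly grown and rendered phantom,
    and an MVD-analog count.  Deterministic for a fixed cohort seed.
    """
    subjects: list[tuple[SpectralLibrary, GroundTruth, str]] = []
    base_target = cs.template.vessel_area_target
    labels = ["control"] * cs.n_control + ["tumor"] * cs.n_tumor
    for i, label in enumerate(labels):
        sseed = _subject_seed(cs.seed, i)
        srng = np.random.default_rng(sseed)
        jitter = float(np.exp(srng.normal(0.0, cs.area_jitter_sd)))
        target = base_target * jitter
        if label == "tumor":
            target *= cs.tumor_area_multiplier
        target = min(target, 0.45)
        spec = replace(
            cs.template, vessel_area_target=target, seed=int(srng.integers(2**31))
        )
        net = generate_vessel_network(spec)
        truth = make_ground_truth(net, spec)
        field = min(spec.width_px, spec.height_px) // 2
        truth.mvd_analog = mvd_analog_count(
            truth, n_fields=5, field_px=field, seed=int(srng.integers(2**31))
        )
        lib = render_library(
            truth,
            channels,
            optics,
            blood,
            noise_sd=spec.noise_sd,
            seed=int(srng.integers(2**31)),
        )
        subjects.append((lib, truth, label))
    return subjects
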