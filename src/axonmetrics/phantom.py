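"""Synthetic phantoms of obliquely cut myelinated fibers.

A myelinated fiber is modeled as a circular cylinder (axon of radius ``r``)
wrapped in a concentric myelin sheath of thickness ``t``. A planar section
cut at angle ``theta`` from the cylinder normal intersects it in two
concentric ellipses whose minor semi-axes equal the true radii (``r`` and
``r + t``) and whose major semi-axes are scaled by ``1 / cos(theta)`` — the
geometric fact that makes the minor axis a cut-angle-invariant diameter
estimator, which the morphometry stage exploits.

The generator samples a fiber population with controlled statistics (axon
diameters from a GEV law, g-ratios from a truncated normal clustered near
0.54, cut angles uniform up to a maximum), places the fibers without
overlap (optionally with tangent "kissing" pairs), rasterizes them into a
one-hot semantic map plus ground-truth instance labels, and can degrade the
semantic map with the artifact types seen in real electron micrographs:
missing myelin sectors, boundary jitter and score blur.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from .containers import AXON, BACKGROUND, DEFAULT_PIXEL_SIZE_NM, MYELIN, InstanceMaps, SemanticMap
from .gev import GEVParams, gev_sample

__all__ = [
    "FiberSpec",
    "PopulationConfig",
    "DegradationParams",
    "PlacementError",
    "sample_population",
    "rasterize",
    "degrade",
    "generate_phantom",
]


class PlacementError(RuntimeError):
    """Raised when the canvas cannot hold the requested fiber count."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could only place {achieved} of {requested} fibers without overlap; "
            "enlarge the canvas or reduce fiber_count"
        )


@dataclass(frozen=True)
class FiberSpec:
    """Ground-truth geometry of one fiber.

    Lengths in µm, angles in degrees; ``cut_angle_deg`` is measured from
    the section normal (0 = orthogonal cut), ``orientation_deg`` is the
    in-plane angle of the ellipse major axis from the raster x-axis.
    """

    fiber_id: int
    axon_radius_um: float
    myelin_thickness_um: float
    cut_angle_deg: float
    center_um: tuple[float, float]  # (x, y)
    orientation_deg: float = 0.0
    kissing_partner: int | None = None

    def __post_init__(self) -> None:
        if self.axon_radius_um <= 0 or self.myelin_thickness_um <= 0:
            raise ValueError("axon radius and myelin thickness must be positive")
        if not 0 <= self.cut_angle_deg < 90:
            raise ValueError("cut angle must lie in [0, 90) degrees")

    @property
    def g_ratio_true(self) -> float:
        r, t = self.axon_radius_um, self.myelin_thickness_um
        return (2 * r) / (2 * r + 2 * t)

    @property
    def outer_radius_um(self) -> float:
        return self.axon_radius_um + self.myelin_thickness_um

    @property
    def stretch(self) -> float:
        """Major-axis elongation factor 1 / cos(cut angle)."""
        return 1.0 / math.cos(math.radians(self.cut_angle_deg))


@dataclass(frozen=True)
class DegradationParams:
    """Artifact model for the semantic map.

    ``myelin_gap_probability`` — fraction of fibers losing an angular
    myelin sector of ``gap_arc_deg`` degrees; ``kissing_fraction`` —
    fraction of fibers placed tangent to a neighbor (acts at placement
    time); ``boundary_noise_amplitude_px`` — RMS amplitude of a smooth
    random boundary displacement field; ``semantic_blur_px`` — Gaussian
    sigma applied to the score channels.
    """

    myelin_gap_probability: float = 0.0
    gap_arc_deg: float = 90.0
    kissing_fraction: float = 0.0
    boundary_noise_amplitude_px: float = 0.0
    semantic_blur_px: float = 0.0

    def __post_init__(self) -> None:
        for name in ("myelin_gap_probability", "kissing_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 <= self.gap_arc_deg <= 180:
            raise ValueError("gap_arc_deg must lie in [0, 180]")
        if self.boundary_noise_amplitude_px < 0 or self.semantic_blur_px < 0:
            raise ValueError("noise amplitudes must be non-negative")

    @property
    def is_identity(self) -> bool:
        return (
            self.myelin_gap_probability == 0
            and self.boundary_noise_amplitude_px == 0
            and self.semantic_blur_px == 0
        )

    @classmethod
    def realistic(cls) -> "DegradationParams":
        """Moderate damage resembling aged post-mortem tissue artifacts."""
        return cls(
            myelin_gap_probability=0.1,
            gap_arc_deg=60.0,
            kissing_fraction=0.1,
            boundary_noise_amplitude_px=1.0,
            semantic_blur_px=1.0,
        )


@dataclass(frozen=True)
class PopulationConfig:
    """Statistical law of the phantom fiber population.

    Axon diameters (µm) follow the GEV ``axon_diameter_law``; g-ratios a
    normal law truncated to (0, 1) with mean ``g_ratio_mean`` and spread
    ``g_ratio_sd`` (0 = point mass); cut angles are uniform on
    [0, ``cut_angle_max_deg``]. ``canvas_px`` is (height, width).
    """

    fiber_count: int = 100
    axon_diameter_law: GEVParams = field(
        default_factory=lambda: GEVParams(mu=0.5, sigma=0.15, xi=0.1)
    )
    g_ratio_mean: float = 0.54
    g_ratio_sd: float = 0.05
    cut_angle_max_deg: float = 60.0
    canvas_px: tuple[int, int] = (1024, 1024)
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    degradation: DegradationParams = field(default_factory=DegradationParams)
    seed: int = 0
    min_diameter_um: float = 0.1  # draws below this physical floor are redrawn
    placement_gap_px: float = 2.0

    def __post_init__(self) -> None:
        if self.fiber_count < 0:
            raise ValueError("fiber_count must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if not 0 < self.g_ratio_mean < 1:
            raise ValueError("g_ratio_mean must lie in (0, 1)")
        if not 0 <= self.cut_angle_max_deg < 90:
            raise ValueError("cut_angle_max_deg must lie in [0, 90)")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0


def _sample_g_ratios(config: PopulationConfig, n: int, rng) -> np.ndarray:
    if config.g_ratio_sd == 0:
        return np.full(n, config.g_ratio_mean)
    from scipy.stats import truncnorm

    lo, hi = 1e-3, 1 - 1e-3
    a = (lo - config.g_ratio_mean) / config.g_ratio_sd
    b = (hi - config.g_ratio_mean) / config.g_ratio_sd
    return truncnorm.rvs(
        a, b, loc=config.g_ratio_mean, scale=config.g_ratio_sd, size=n, random_state=rng
    )


def _sample_diameters(config: PopulationConfig, n: int, rng) -> np.ndarray:
    """GEV axon-diameter draws with redraws below the physical floor."""
    out = np.empty(n)
    need = np.arange(n)
    while need.size:
        d = gev_sample(config.axon_diameter_law, need.size, seed=rng.integers(2**31 - 1))
        ok = d >= config.min_diameter_um
        out[need[ok]] = d[ok]
        need = need[~ok]
    return out


def sample_population(config: PopulationConfig) -> list[FiberSpec]:
    """Draw fiber geometries and place them on the canvas without overlap.

    Non-kissing fibers are placed by rejection sampling so that their outer
    bounding circles (semi-major axis plus a clearance gap) do not overlap;
    a ``kissing_fraction`` of fibers is placed tangent to a partner with a
    1 px shared dilation so their sheaths touch.
    """
    rng = np.random.default_rng(config.seed)
    n = config.fiber_count
    if n == 0:
        return []

    diam = _sample_diameters(config, n, rng)
    g = _sample_g_ratios(config, n, rng)
    r_ax = diam / 2.0
    t_my = r_ax * (1.0 / g - 1.0)  # so that r/(r+t) = g exactly
    angles = rng.uniform(0.0, config.cut_angle_max_deg, size=n)
    orient = rng.uniform(-90.0, 90.0, size=n)

    px_um = config.pixel_size_um
    H, W = config.canvas_px
    h_um, w_um = H * px_um, W * px_um

    # semi-major outer axis bounds the fiber footprint
    bound_um = (r_ax + t_my) / np.cos(np.radians(angles))

    n_kiss_pairs = int(round(config.degradation.kissing_fraction * n / 2.0))
    partner_of: dict[int, int] = {}
    for k in range(n_kiss_pairs):
        a, b = 2 * k, 2 * k + 1
        if b >= n:
            break
        partner_of[a] = b
        partner_of[b] = a

    # vectorized occupancy check against all previously placed fibers
    px_gap = config.placement_gap_px * px_um
    placed_x = np.empty(n)
    placed_y = np.empty(n)
    placed_b = np.empty(n)
    placed_which = np.empty(n, dtype=np.int64)
    n_placed = 0
    centers = np.full((n, 2), np.nan)

    def _fits(x: float, y: float, b: float, ignore: int | None = None) -> bool:
        margin = b + px_gap
        if not (margin <= x <= w_um - margin and margin <= y <= h_um - margin):
            return False
        if n_placed == 0:
            return True
        dx = placed_x[:n_placed] - x
        dy = placed_y[:n_placed] - y
        min_d = placed_b[:n_placed] + b + px_gap
        clash = dx * dx + dy * dy < min_d * min_d
        if ignore is not None:
            clash &= placed_which[:n_placed] != ignore
        return not clash.any()

    max_attempts = 2000
    for i in range(n):
        partner = partner_of.get(i)
        if partner is not None and partner < i and not np.isnan(centers[partner, 0]):
            # tangent placement beside the already-placed partner, minor axes
            # aligned, centers 1 px closer than tangency so the sheaths share
            # a dilated boundary
            orient[i] = orient[partner]
            b_self = (r_ax[i] + t_my[i])  # minor semi-axis (cut-angle invariant)
            b_part = (r_ax[partner] + t_my[partner])
            dist = b_self + b_part - 1.0 * px_um
            theta = math.radians(orient[partner] + 90.0)
            placed = False
            for sign in rng.permutation([1.0, -1.0]):
                x = centers[partner, 0] + sign * dist * math.cos(theta)
                y = centers[partner, 1] + sign * dist * math.sin(theta)
                if _fits(x, y, bound_um[i], ignore=partner):
                    centers[i] = (x, y)
                    placed = True
                    break
            if not placed:
                raise PlacementError(n, i)
        else:
            for _ in range(max_attempts):
                x = rng.uniform(0.0, w_um)
                y = rng.uniform(0.0, h_um)
                if _fits(x, y, bound_um[i]):
                    centers[i] = (x, y)
                    break
            else:
                raise PlacementError(n, i)
        placed_x[n_placed] = centers[i, 0]
        placed_y[n_placed] = centers[i, 1]
        placed_b[n_placed] = bound_um[i]
        placed_which[n_placed] = i
        n_placed += 1

    return [
        FiberSpec(
            fiber_id=i + 1,
            axon_radius_um=float(r_ax[i]),
            myelin_thickness_um=float(t_my[i]),
            cut_angle_deg=float(angles[i]),
            center_um=(float(centers[i, 0]), float(centers[i, 1])),
            orientation_deg=float(orient[i]),
            kissing_partner=(partner_of[i] + 1) if i in partner_of else None,
        )
        for i in range(n)
    ]


def _ellipse_pixels(spec: FiberSpec, semi_minor_um: float, shape, px_um: float):
    """Row/col indices of the rasterized cut ellipse with the given minor semi-axis.

    Drawn on a local patch around the fiber center and shifted into canvas
    coordinates, so cost scales with fiber size rather than canvas size.
    """
    cx, cy = spec.center_um
    b_px = semi_minor_um / px_um
    a_px = b_px * spec.stretch
    r0, c0 = cy / px_um, cx / px_um
    half = int(math.ceil(a_px)) + 2
    # negated so that the moment-fit orientation convention (degrees from
    # the raster x-axis, in (-90, 90]) recovers spec.orientation_deg
    rr, cc = draw_ellipse(
        half + (r0 - round(r0)),
        half + (c0 - round(c0)),
        r_radius=b_px,
        c_radius=a_px,
        shape=(2 * half + 1, 2 * half + 1),
        rotation=math.radians(-spec.orientation_deg),
    )
    rr = rr + int(round(r0)) - half
    cc = cc + int(round(c0)) - half
    keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    return rr[keep], cc[keep]


def _is_clipped(spec: FiberSpec, shape, px_um: float) -> bool:
    cx, cy = spec.center_um
    a_um = spec.outer_radius_um * spec.stretch
    H, W = shape
    return (
        cx - a_um < 0 or cy - a_um < 0 or cx + a_um > W * px_um or cy + a_um > H * px_um
    )


def rasterize(
    specs: list[FiberSpec],
    canvas_px: tuple[int, int],
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
) -> tuple[SemanticMap, InstanceMaps, pd.DataFrame]:
    """Render fiber specs into a one-hot semantic map, instance labels and truth.

    Each fiber becomes two concentric ellipses: the axon ellipse and the
    myelin annulus around it, both with minor semi-axes equal to the true
    radii and major semi-axes stretched by ``1/cos(cut angle)``. Fibers
    extending beyond the canvas are clipped and flagged in the truth table.
    """
    H, W = canvas_px
    px_um = pixel_size_nm / 1000.0
    axon_labels = np.zeros((H, W), dtype=np.uint16)
    myelin_labels = np.zeros((H, W), dtype=np.uint16)
    if len(specs) > 65535:
        raise ValueError("more than 65535 fibers exceed the 16-bit label range")

    rows = []
    for spec in specs:
        rr_o, cc_o = _ellipse_pixels(spec, spec.outer_radius_um, (H, W), px_um)
        rr_a, cc_a = _ellipse_pixels(spec, spec.axon_radius_um, (H, W), px_um)
        myelin_labels[rr_o, cc_o] = spec.fiber_id  # sheath first ...
        myelin_labels[rr_a, cc_a] = 0  # ... then carve out the axon
        axon_labels[rr_a, cc_a] = spec.fiber_id
        d = 2 * spec.axon_radius_um
        D = 2 * spec.outer_radius_um
        rows.append(
            {
                "fiber_id": spec.fiber_id,
                "axon_radius_um": spec.axon_radius_um,
                "myelin_thickness_um": spec.myelin_thickness_um,
                "cut_angle_deg": spec.cut_angle_deg,
                "g_ratio_true": spec.g_ratio_true,
                "clipped_flag": _is_clipped(spec, (H, W), px_um),
                "center_x_um": spec.center_um[0],
                "center_y_um": spec.center_um[1],
                "orientation_deg": spec.orientation_deg,
                "kissing_partner": spec.kissing_partner or 0,
                "axon_minor_true_um": d,
                "axon_major_true_um": d * spec.stretch,
                "outer_minor_true_um": D,
                "outer_major_true_um": D * spec.stretch,
            }
        )

    scores = np.zeros((H, W, 3), dtype=np.float32)
    scores[:, :, AXON] = axon_labels > 0
    scores[:, :, MYELIN] = myelin_labels > 0
    scores[:, :, BACKGROUND] = 1.0 - scores[:, :, AXON] - scores[:, :, MYELIN]

    truth = pd.DataFrame(
        rows,
        columns=[
            "fiber_id", "axon_radius_um", "myelin_thickness_um", "cut_angle_deg",
            "g_ratio_true", "clipped_flag", "center_x_um", "center_y_um",
            "orientation_deg", "kissing_partner", "axon_minor_true_um",
            "axon_major_true_um", "outer_minor_true_um", "outer_major_true_um",
        ],
    )
    return (
        SemanticMap(scores, pixel_size_nm),
        InstanceMaps(axon_labels, myelin_labels, pixel_size_nm),
        truth,
    )


def degrade(smap: SemanticMap, params: DegradationParams, seed=0) -> SemanticMap:
    """Apply artifact degradations to a semantic map.

    Order: myelin-sector gaps (per connected sheath component), smooth
    boundary displacement, Gaussian score blur; scores are renormalized to
    sum to 1 per pixel. With all parameters zero the input is returned
    unchanged (as a copy).
    """
    scores = smap.scores.astype(np.float32, copy=True)
    if params.is_identity:
        return SemanticMap(scores, smap.pixel_size_nm)
    rng = np.random.default_rng(seed)

    if params.myelin_gap_probability > 0 and params.gap_arc_deg > 0:
        myelin = np.argmax(scores, axis=2) == MYELIN
        labels, n_comp = ndi.label(myelin)
        if n_comp:
            centroids = ndi.center_of_mass(myelin, labels, range(1, n_comp + 1))
            hit = rng.uniform(size=n_comp) < params.myelin_gap_probability
            start = rng.uniform(0.0, 360.0, size=n_comp)
            for ci in np.flatnonzero(hit):
                comp = labels == ci + 1
                ys, xs = np.nonzero(comp)
                cy, cx = centroids[ci]
                ang = (np.degrees(np.arctan2(ys - cy, xs - cx)) - start[ci]) % 360.0
                sector = ang < params.gap_arc_deg
                rr, cc = ys[sector], xs[sector]
                scores[rr, cc, :] = 0.0
                scores[rr, cc, BACKGROUND] = 1.0

    if params.boundary_noise_amplitude_px > 0:
        H, W = scores.shape[:2]
        # smooth random displacement field with the requested RMS amplitude
        field_sigma = 8.0
        disp = []
        for _ in range(2):
            f = rng.standard_normal((H, W))
            f = ndi.gaussian_filter(f, field_sigma)
            rms = np.sqrt(np.mean(f**2))
            disp.append(f / max(rms, 1e-12) * params.boundary_noise_amplitude_px)
        yy, xx = np.mgrid[0:H, 0:W].astype(np.float32)
        coords = [yy + disp[0], xx + disp[1]]
        warped = np.empty_like(scores)
        for ch in range(3):
            warped[:, :, ch] = ndi.map_coordinates(
                scores[:, :, ch], coords, order=1, mode="nearest"
            )
        scores = warped

    if params.semantic_blur_px > 0:
        for ch in range(3):
            scores[:, :, ch] = ndi.gaussian_filter(
                scores[:, :, ch], params.semantic_blur_px
            )

    total = scores.sum(axis=2, keepdims=True)
    scores = np.where(total > 0, scores / total, 0.0).astype(np.float32)
    empty = (total[:, :, 0] <= 0)
    scores[empty, BACKGROUND] = 1.0
    return SemanticMap(scores, smap.pixel_size_nm)


def generate_phantom(
    config: PopulationConfig,
) -> tuple[SemanticMap, InstanceMaps, pd.DataFrame]:
    """Sample, rasterize and degrade a phantom in one call.

    The returned instance maps and truth table describe the undegraded
    ground truth; only the semantic map carries the degradation artifacts.
    """
    specs = sample_population(config)
    smap, inst, truth = rasterize(specs, config.canvas_px, config.pixel_size_nm)
    smap = degrade(smap, config.degradation, seed=config.seed + 1)
    return smap, inst, truth
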