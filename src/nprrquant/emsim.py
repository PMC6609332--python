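"""Synthetic immuno-EM annotations with known ground-truth densities.

Generates one micrograph worth of geometry: a convex-blob bouton outline
occupying a set fraction of the image, non-overlapping DCV discs inside it,
and gold particles placed as independent Poisson counts per compartment
(uniform positions within each compartment).  Counts are drawn with means
``density x analysis-area`` using the same area formulas the stereology
estimators use, so density recovery is unbiased by construction.

Coordinates are nm; image and compartment areas are um^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

from .stereology import NM2_PER_UM2, EMImageAnnotation

__all__ = ["EMSimParams", "CapacityError", "simulate_em_annotation"]


class CapacityError(RuntimeError):
    """Could not place the requested non-overlapping DCV discs."""


@dataclass(frozen=True)
class EMSimParams:
    """Ground truth for one synthetic micrograph.

    Default densities mirror the measured compartment contrast of a
    DCV-localized antigen: strong labeling on DCVs and the plasma membrane,
    sparse cytoplasmic labeling, near-background outside the bouton.
    """

    image_area_um2: float = 4.0
    bouton_fraction: float = 0.4
    n_dcv: int = 12
    dcv_disc_radius: float = 50.0  # nm
    density_dcv: float = 30.0  # gold/um^2
    density_cytoplasm: float = 2.0
    density_membrane_band: float = 15.0
    density_outside: float = 0.3
    membrane_band_halfwidth: float = 20.0  # nm
    n_outline_vertices: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.bouton_fraction < 1:
            raise ValueError("bouton_fraction must be in (0, 1)")
        if self.dcv_disc_radius <= 0:
            raise ValueError("dcv_disc_radius must be > 0")
        if self.image_area_um2 <= 0:
            raise ValueError("image_area_um2 must be > 0")
        if self.n_dcv < 0:
            raise ValueError("n_dcv must be >= 0")
        for name in ("density_dcv", "density_cytoplasm",
                     "density_membrane_band", "density_outside"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_(self, **kw) -> "EMSimParams":
        return replace(self, **kw)


def _bouton_polygon(params: EMSimParams, rng: np.random.Generator) -> Polygon:
    """Convex blob: regular polygon with radii perturbed +-15%, rescaled so
    its area equals bouton_fraction x image area exactly."""
    n = params.n_outline_vertices
    ang = 2 * np.pi * np.arange(n) / n
    radii = 1.0 + rng.uniform(-0.15, 0.15, size=n)
    # area of a star-shaped polygon with vertex radii r_i
    area_unit = 0.5 * np.sum(radii * np.roll(radii, -1) * np.sin(2 * np.pi / n))
    target_nm2 = params.bouton_fraction * params.image_area_um2 * NM2_PER_UM2
    scale = math.sqrt(target_nm2 / area_unit)
    side = math.sqrt(params.image_area_um2 * NM2_PER_UM2)
    cx = cy = side / 2
    xy = np.column_stack([
        cx + scale * radii * np.cos(ang),
        cy + scale * radii * np.sin(ang),
    ])
    poly = Polygon(xy)
    if not poly.is_valid:
        raise RuntimeError("generated outline invalid (should not happen)")
    return poly


def _place_dcv_centers(
    poly: Polygon, params: EMSimParams, rng: np.random.Generator,
    max_tries: int = 2000,
) -> np.ndarray:
    """Centers inside the bouton with pairwise distance >= 2r and the full
    disc inside the outline; bounded rejection sampling."""
    if params.n_dcv == 0:
        return np.empty((0, 2))
    r = params.dcv_disc_radius
    inner = poly.buffer(-r)
    if inner.is_empty:
        raise CapacityError("bouton too small to hold any DCV disc")
    minx, miny, maxx, maxy = inner.bounds
    centers: list[np.ndarray] = []
    tries = 0
    budget = max_tries * params.n_dcv
    while len(centers) < params.n_dcv:
        if tries >= budget:
            raise CapacityError(
                f"placed {len(centers)}/{params.n_dcv} DCV discs after "
                f"{budget} tries"
            )
        tries += 1
        p = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
        if not inner.covers(Point(p)):
            continue
        if any(np.hypot(*(p - c)) < 2 * r for c in centers):
            continue
        centers.append(p)
    return np.vstack(centers)


def _sample_in_discs(
    centers: np.ndarray, r: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    which = rng.integers(0, len(centers), size=n)
    theta = rng.uniform(0, 2 * np.pi, size=n)
    rad = r * np.sqrt(rng.uniform(0, 1, size=n))
    return centers[which] + np.column_stack([rad * np.cos(theta),
                                             rad * np.sin(theta)])


def _sample_in_band(
    poly: Polygon, halfwidth: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform-ish positions in the +-halfwidth band around the outline:
    a uniform station along the perimeter plus a uniform normal offset."""
    ring = poly.exterior
    s = rng.uniform(0, ring.length, size=n)
    off = rng.uniform(-halfwidth, halfwidth, size=n)
    pts = np.empty((n, 2))
    eps = 1e-3
    for i in range(n):
        p0 = ring.interpolate(s[i])
        p1 = ring.interpolate((s[i] + eps) % ring.length)
        tx, ty = p1.x - p0.x, p1.y - p0.y
        norm = math.hypot(tx, ty) or 1.0
        # outward-pointing normal of a ccw ring is (ty, -tx)/|t|
        pts[i] = (p0.x + off[i] * ty / norm, p0.y - off[i] * tx / norm)
    return pts


def _sample_rejection(
    region_test, bounds: tuple[float, float, float, float],
    n: int, rng: np.random.Generator, max_factor: int = 2000,
) -> np.ndarray:
    minx, miny, maxx, maxy = bounds
    out: list[np.ndarray] = []
    tries = 0
    while len(out) < n:
        if tries > max_factor * max(n, 1):
            raise RuntimeError("rejection sampling failed to fill the region")
        tries += 1
        m = max(4 * (n - len(out)), 16)
        cand = np.column_stack([
            rng.uniform(minx, maxx, size=m), rng.uniform(miny, maxy, size=m)
        ])
        ok = region_test(cand)
        for p in cand[ok]:
            if len(out) < n:
                out.append(p)
    return np.vstack(out) if out else np.empty((0, 2))


def simulate_em_annotation(params: EMSimParams) -> EMImageAnnotation:
    """One synthetic annotated micrograph; deterministic given the seed."""
    rng = np.random.default_rng(params.seed)
    poly = _bouton_polygon(params, rng)
    centers = _place_dcv_centers(poly, params, rng)
    r = params.dcv_disc_radius
    hw = params.membrane_band_halfwidth
    side = math.sqrt(params.image_area_um2 * NM2_PER_UM2)
    perim = poly.exterior.length

    # analysis-area means (um^2), matching the stereology estimators
    a_dcv = params.n_dcv * np.pi * r**2 / NM2_PER_UM2
    a_band = perim * 2 * hw / NM2_PER_UM2
    a_cyto = poly.area / NM2_PER_UM2 - a_dcv - a_band
    a_out = (params.image_area_um2 - poly.area / NM2_PER_UM2
             - perim * hw / NM2_PER_UM2)
    if a_cyto <= 0:
        raise CapacityError("cytoplasm area non-positive; fewer/smaller DCVs "
                            "or a larger bouton required")

    parts: list[np.ndarray] = []
    n_dcv_gold = rng.poisson(params.density_dcv * a_dcv) if params.n_dcv else 0
    if n_dcv_gold:
        parts.append(_sample_in_discs(centers, r, n_dcv_gold, rng))

    n_band = rng.poisson(params.density_membrane_band * a_band)
    if n_band:
        pts = _sample_in_band(poly, hw, n_band, rng)
        # band points that happen to fall inside a DCV disc would be
        # re-labelled dcv by the priority rule; keep them (they are rare
        # and the priority rule is part of the contract)
        parts.append(pts)

    exterior = poly.exterior

    def in_cyto(cand: np.ndarray) -> np.ndarray:
        pts = shapely.points(cand)
        ok = shapely.covers(poly, pts)
        ok &= shapely.distance(pts, exterior) > hw
        if len(centers):
            d2 = ((cand[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
            ok &= ~(d2 <= r**2).any(axis=1)
        return ok

    n_cyto = rng.poisson(params.density_cytoplasm * a_cyto)
    if n_cyto:
        parts.append(_sample_rejection(in_cyto, poly.bounds, n_cyto, rng))

    def in_outside(cand: np.ndarray) -> np.ndarray:
        pts = shapely.points(cand)
        ok = ~shapely.covers(poly, pts)
        ok &= shapely.distance(pts, exterior) > hw
        return ok

    n_out = rng.poisson(params.density_outside * a_out)
    if n_out:
        parts.append(_sample_rejection(in_outside, (0, 0, side, side),
                                       n_out, rng))

    gold = np.vstack(parts) if parts else np.empty((0, 2))
    return EMImageAnnotation(
        image_id=f"sim{params.seed:05d}",
        image_area_um2=params.image_area_um2,
        gold=gold,
        dcv_centers=centers,
        bouton_outline=np.asarray(poly.exterior.coords)[:-1],
        membrane_band_halfwidth=hw,
        dcv_disc_radius=r,
    )
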