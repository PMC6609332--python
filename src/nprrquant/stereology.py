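"""Stereological quantification of immunogold labeling on EM micrographs.

A micrograph annotation carries the bouton outline (a simple closed polygon),
dense-core-vesicle (DCV) centers, and gold-particle coordinates, all in nm;
image areas are in um^2.  Gold particles are assigned to compartments with
priority DCV > membrane > cytoplasm > outside:

* **dcv** — within ``dcv_disc_radius`` (default 50 nm) of any DCV center;
* **membrane** — within ``membrane_band_halfwidth`` (default 20 nm) of the
  bouton outline, on either side;
* **cytoplasm** — inside the outline;
* **outside** — everything else (mainly sER in real sections).

Compartment areas:

* DCV area = n_dcv * pi * r^2;
* membrane band area = perimeter * (2 * halfwidth) — curvature correction is
  negligible at these scales;
* cytoplasm area = bouton area - DCV area - membrane band area;
* outside area = image area - bouton area - perimeter * halfwidth (the outer
  half of the band).

The bouton area itself is a grid-intersection estimate (count of square-grid
points inside the outline times the cell area), as in classical stereology.
Densities are counts/area (gold/um^2); the DCV/bouton localization ratio is
DCV density over cytoplasm density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

__all__ = [
    "NM2_PER_UM2",
    "EMImageAnnotation",
    "CompartmentCounts",
    "assign_gold_compartments",
    "grid_area_estimate",
    "DensityReport",
    "density_report",
    "density_report_from_counts",
    "read_stereology_summary",
    "background_density",
    "filter_gold_aggregates",
]

NM2_PER_UM2 = 1e6
COMPARTMENTS = ("dcv", "membrane", "cytoplasm", "outside")
BACKGROUND_CEILING = 0.6  # gold/um^2; reported ceiling for control labeling


@dataclass
class EMImageAnnotation:
    """Geometry of one annotated micrograph (coordinates in nm, area in um^2)."""

    image_id: str
    image_area_um2: float
    gold: np.ndarray  # (n, 2) nm
    dcv_centers: np.ndarray  # (m, 2) nm
    bouton_outline: np.ndarray  # (k, 2) nm, simple closed ring
    membrane_band_halfwidth: float = 20.0  # nm
    dcv_disc_radius: float = 50.0  # nm

    def __post_init__(self) -> None:
        self.gold = np.asarray(self.gold, dtype=float).reshape(-1, 2)
        self.dcv_centers = np.asarray(self.dcv_centers, dtype=float).reshape(-1, 2)
        self.bouton_outline = np.asarray(self.bouton_outline, dtype=float)
        if self.image_area_um2 <= 0:
            raise ValueError("image_area_um2 must be > 0")
        if self.membrane_band_halfwidth <= 0 or self.dcv_disc_radius <= 0:
            raise ValueError("band halfwidth and disc radius must be > 0")
        for arr in (self.gold, self.dcv_centers, self.bouton_outline):
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError("coordinates must be finite")
        poly = self.polygon()
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"image {self.image_id}: bouton outline is not a "
                             "simple closed polygon")

    def polygon(self) -> Polygon:
        return Polygon(self.bouton_outline)

    @property
    def n_dcv(self) -> int:
        return len(self.dcv_centers)

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "image_area_um2": self.image_area_um2,
            "gold_nm": self.gold.tolist(),
            "dcv_centers_nm": self.dcv_centers.tolist(),
            "bouton_outline_nm": self.bouton_outline.tolist(),
            "membrane_band_halfwidth_nm": self.membrane_band_halfwidth,
            "dcv_disc_radius_nm": self.dcv_disc_radius,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EMImageAnnotation":
        return cls(
            image_id=d["image_id"],
            image_area_um2=d["image_area_um2"],
            gold=np.asarray(d["gold_nm"], dtype=float).reshape(-1, 2),
            dcv_centers=np.asarray(d["dcv_centers_nm"], dtype=float).reshape(-1, 2),
            bouton_outline=np.asarray(d["bouton_outline_nm"], dtype=float),
            membrane_band_halfwidth=d.get("membrane_band_halfwidth_nm", 20.0),
            dcv_disc_radius=d.get("dcv_disc_radius_nm", 50.0),
        )


def assign_gold_compartments(ann: EMImageAnnotation) -> np.ndarray:
    """Compartment label per gold particle (priority dcv > membrane >
    cytoplasm > outside); every particle gets exactly one label."""
    n = len(ann.gold)
    labels = np.full(n, "outside", dtype=object)
    if n == 0:
        return labels.astype(str)
    pts = shapely.points(ann.gold)
    poly = ann.polygon()
    if len(ann.dcv_centers):
        d2 = ((ann.gold[:, None, :] - ann.dcv_centers[None, :, :]) ** 2).sum(-1)
        in_dcv = (d2 <= ann.dcv_disc_radius**2).any(axis=1)
    else:
        in_dcv = np.zeros(n, dtype=bool)
    bdist = shapely.distance(pts, poly.exterior)
    in_band = bdist <= ann.membrane_band_halfwidth
    inside = shapely.covers(poly, pts)
    labels[inside] = "cytoplasm"
    labels[in_band] = "membrane"
    labels[in_dcv] = "dcv"
    return labels.astype(str)


def grid_area_estimate(
    region: Polygon | np.ndarray,
    spacing: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Grid-intersection area estimate, in um^2.

    Counts square-grid points covered by the region and multiplies by the
    cell area ``spacing**2``.  Points sit at cell centers, i.e. at
    ``origin + (i + 1/2) * spacing`` along each axis — each counted point
    then represents exactly one grid cell, so a grid-aligned rectangle is
    estimated exactly.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    poly = region if isinstance(region, Polygon) else Polygon(np.asarray(region))
    if poly.is_empty or poly.area == 0:
        return 0.0
    minx, miny, maxx, maxy = poly.bounds
    if spacing > max(maxx - minx, maxy - miny):
        warnings.warn("grid spacing exceeds the region bounding box; the "
                      "estimate may be 0", stacklevel=2)
    half = spacing / 2
    i0 = int(np.ceil((minx - origin[0] - half) / spacing))
    i1 = int(np.floor((maxx - origin[0] - half) / spacing))
    j0 = int(np.ceil((miny - origin[1] - half) / spacing))
    j1 = int(np.floor((maxy - origin[1] - half) / spacing))
    if i1 < i0 or j1 < j0:
        return 0.0
    xs = origin[0] + half + np.arange(i0, i1 + 1) * spacing
    ys = origin[1] + half + np.arange(j0, j1 + 1) * spacing
    gx, gy = np.meshgrid(xs, ys)
    pts = shapely.points(np.column_stack([gx.ravel(), gy.ravel()]))
    count = int(np.count_nonzero(shapely.covers(poly, pts)))
    return count * spacing**2 / NM2_PER_UM2


@dataclass
class CompartmentCounts:
    """Gold counts and analysis areas (um^2) for one micrograph."""

    image_id: str
    counts: dict[str, int]
    areas: dict[str, float]

    @property
    def total_gold(self) -> int:
        return sum(self.counts.values())


def _compartment_measurements(
    ann: EMImageAnnotation,
    grid_spacing: float | None = 50.0,
    drop_aggregates: bool = False,
) -> CompartmentCounts:
    gold = ann.gold
    if drop_aggregates and len(gold):
        gold = filter_gold_aggregates(gold)
        ann = EMImageAnnotation(
            image_id=ann.image_id,
            image_area_um2=ann.image_area_um2,
            gold=gold,
            dcv_centers=ann.dcv_centers,
            bouton_outline=ann.bouton_outline,
            membrane_band_halfwidth=ann.membrane_band_halfwidth,
            dcv_disc_radius=ann.dcv_disc_radius,
        )
    labels = assign_gold_compartments(ann)
    counts = {c: int(np.count_nonzero(labels == c)) for c in COMPARTMENTS}
    poly = ann.polygon()
    if grid_spacing is None:
        bouton_area = poly.area / NM2_PER_UM2
    else:
        bouton_area = grid_area_estimate(poly, grid_spacing)
    perimeter = poly.exterior.length  # nm
    dcv_area = ann.n_dcv * np.pi * ann.dcv_disc_radius**2 / NM2_PER_UM2
    band_area = perimeter * 2 * ann.membrane_band_halfwidth / NM2_PER_UM2
    cyto_area = bouton_area - dcv_area - band_area
    outside_area = (ann.image_area_um2 - bouton_area
                    - perimeter * ann.membrane_band_halfwidth / NM2_PER_UM2)
    areas = {
        "dcv": dcv_area,
        "membrane": band_area,
        "cytoplasm": cyto_area,
        "outside": outside_area,
    }
    return CompartmentCounts(image_id=ann.image_id, counts=counts, areas=areas)


@dataclass
class DensityReport:
    """Pooled per-compartment labeling densities and the localization ratio.

    ``dcv_over_bouton_ratio`` (pooled counts/areas) is the headline number;
    ``ratio_per_image_mean`` averages per-image ratios instead, and
    ``ratio_unsubtracted`` uses the whole bouton area (DCV discs and membrane
    band not subtracted) as the cytoplasm denominator.  All three are
    reported because published tables rarely state which convention was used.
    """

    counts: dict[str, int]
    areas: dict[str, float]
    densities: dict[str, float]
    dcv_over_bouton_ratio: float
    ratio_per_image_mean: float
    ratio_unsubtracted: float
    n_images: int
    background_density: float | None = None
    per_image: list[CompartmentCounts] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "areas_um2": self.areas,
            "densities_per_um2": self.densities,
            "dcv_over_bouton_ratio": self.dcv_over_bouton_ratio,
            "ratio_per_image_mean": self.ratio_per_image_mean,
            "ratio_unsubtracted": self.ratio_unsubtracted,
            "n_images": self.n_images,
            "background_density_per_um2": self.background_density,
        }


def _safe_ratio(num: float, den: float) -> float:
    if den <= 0:
        return float("inf") if num > 0 else float("nan")
    return num / den


def density_report(
    annotations: list[EMImageAnnotation],
    grid_spacing: float | None = 50.0,
    drop_aggregates: bool = False,
) -> DensityReport:
    """Per-compartment gold densities across micrographs.

    Pooled mode (the headline ratio) sums counts and areas across images
    before dividing; the per-image-mean variant averages per-image ratios.
    ``grid_spacing`` (nm) controls the grid-intersection bouton-area
    estimate; ``None`` uses the exact polygon area instead.
    """
    if not annotations:
        raise ValueError("need at least one annotation")
    per_image = [
        _compartment_measurements(a, grid_spacing, drop_aggregates)
        for a in annotations
    ]
    counts = {c: sum(m.counts[c] for m in per_image) for c in COMPARTMENTS}
    areas = {c: sum(m.areas[c] for m in per_image) for c in COMPARTMENTS}
    densities = {c: _safe_ratio(counts[c], areas[c]) for c in COMPARTMENTS}
    ratio = _safe_ratio(densities["dcv"], densities["cytoplasm"])
    per_ratios = [
        _safe_ratio(
            _safe_ratio(m.counts["dcv"], m.areas["dcv"]),
            _safe_ratio(m.counts["cytoplasm"], m.areas["cytoplasm"]),
        )
        for m in per_image
    ]
    finite = [r for r in per_ratios if np.isfinite(r)]
    dens_unsub = _safe_ratio(
        counts["cytoplasm"],
        sum(m.areas["dcv"] + m.areas["membrane"] + m.areas["cytoplasm"]
            for m in per_image),
    )
    return DensityReport(
        counts=counts,
        areas=areas,
        densities=densities,
        dcv_over_bouton_ratio=ratio,
        ratio_per_image_mean=float(np.mean(finite)) if finite else float("nan"),
        ratio_unsubtracted=_safe_ratio(densities["dcv"], dens_unsub),
        n_images=len(annotations),
        per_image=per_image,
    )


SUMMARY_COLUMNS = {
    "image_id", "image_area_um2", "n_dcv", "gold_dcv", "gold_cytoplasm",
    "gold_membrane", "gold_outside", "bouton_area_um2",
}


def read_stereology_summary(path) -> pd.DataFrame:
    """Read a per-micrograph stereology count table (TSV/CSV).

    Expected columns: image_id, image_area_um2, n_dcv, gold_dcv,
    gold_cytoplasm, gold_membrane, gold_outside, bouton_area_um2 — the
    measurement set of the stereological protocol.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = SUMMARY_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    return df


def density_report_from_counts(
    df: pd.DataFrame,
    dcv_disc_radius: float = 50.0,
    subtract_dcv_area: bool = True,
) -> DensityReport:
    """Densities and DCV/bouton ratio from a per-micrograph count table.

    The table carries no outline geometry, so the membrane band area is
    unavailable; the cytoplasm denominator is the bouton area minus (when
    ``subtract_dcv_area``) the summed DCV disc area.
    """
    dcv_area = df["n_dcv"].to_numpy(float) * np.pi * dcv_disc_radius**2 / NM2_PER_UM2
    bouton = df["bouton_area_um2"].to_numpy(float)
    cyto_area = bouton - dcv_area if subtract_dcv_area else bouton
    counts = {
        "dcv": int(df["gold_dcv"].sum()),
        "cytoplasm": int(df["gold_cytoplasm"].sum()),
        "membrane": int(df["gold_membrane"].sum()),
        "outside": int(df["gold_outside"].sum()),
    }
    areas = {
        "dcv": float(dcv_area.sum()),
        "cytoplasm": float(cyto_area.sum()),
        "membrane": float("nan"),
        "outside": float((df["image_area_um2"].to_numpy(float) - bouton).sum()),
    }
    densities = {
        c: _safe_ratio(counts[c], areas[c]) if np.isfinite(areas[c])
        else float("nan")
        for c in counts
    }
    ratio = _safe_ratio(densities["dcv"], densities["cytoplasm"])
    with np.errstate(divide="ignore", invalid="ignore"):
        per = ((df["gold_dcv"].to_numpy(float) / dcv_area)
               / (df["gold_cytoplasm"].to_numpy(float) / cyto_area))
    per = per[np.isfinite(per)]
    dens_unsub = _safe_ratio(counts["cytoplasm"], float(bouton.sum()))
    return DensityReport(
        counts=counts,
        areas=areas,
        densities=densities,
        dcv_over_bouton_ratio=ratio,
        ratio_per_image_mean=float(np.mean(per)) if per.size else float("nan"),
        ratio_unsubtracted=_safe_ratio(densities["dcv"], dens_unsub),
        n_images=len(df),
    )


def background_density(
    control_annotations: list[EMImageAnnotation] | pd.DataFrame,
    threshold: float = BACKGROUND_CEILING,
) -> tuple[float, bool]:
    """Background labeling density from control images: total control gold
    over total control area (gold/um^2), and whether it is below the
    acceptance ceiling (default 0.6 gold/um^2)."""
    if isinstance(control_annotations, pd.DataFrame):
        total_gold = float(
            control_annotations[
                ["gold_dcv", "gold_cytoplasm", "gold_membrane", "gold_outside"]
            ].to_numpy(float).sum()
        )
        total_area = float(control_annotations["image_area_um2"].sum())
    else:
        if not control_annotations:
            raise ValueError("need at least one control annotation")
        total_gold = float(sum(len(a.gold) for a in control_annotations))
        total_area = float(sum(a.image_area_um2 for a in control_annotations))
    if total_area <= 0:
        raise ValueError("total control area must be > 0")
    dens = total_gold / total_area
    return dens, dens < threshold


def filter_gold_aggregates(
    gold: np.ndarray, k: int = 4, d: float = 15.0
) -> np.ndarray:
    """Collapse obvious large gold aggregates to single particles.

    A particle with >= ``k`` neighbors within ``d`` nm belongs to an
    aggregate; each connected aggregate is replaced by its centroid.
    Off by default in the density report.
    """
    gold = np.asarray(gold, dtype=float).reshape(-1, 2)
    n = len(gold)
    if n == 0:
        return gold
    d2 = ((gold[:, None, :] - gold[None, :, :]) ** 2).sum(-1)
    close = d2 <= d**2
    neigh = close.sum(axis=1) - 1
    in_agg = neigh >= k
    keep = gold[~in_agg]
    # union connected aggregate members via simple label propagation
    idx = np.where(in_agg)[0]
    comp = {i: i for i in idx}

    def find(i):
        while comp[i] != i:
            comp[i] = comp[comp[i]]
            i = comp[i]
        return i

    for a in idx:
        for b in idx:
            if close[a, b]:
                ra, rb = find(a), find(b)
                if ra != rb:
                    comp[rb] = ra
    groups: dict[int, list[int]] = {}
    for i in idx:
        groups.setdefault(find(i), []).append(i)
    centroids = [gold[members].mean(axis=0) for members in groups.values()]
    if centroids:
        keep = np.vstack([keep, np.array(centroids)])
    return keep
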