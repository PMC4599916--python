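"""Synthetic multiplex liver-tissue images and per-cell intensity tables.

Real confocal acquisitions are rarely available for method validation, so
the pipeline is exercised on synthetic data with known ground truth that
emulates the statistical structure the analysis assumes: a few thousand
hepatocytes per condition
with paired nuclear/cytoplasmic NF-κB intensities, unimodal or bimodal
population structure, an optional zonal gradient around portal/central vein
landmarks, and a sparse GFAP-positive stellate-cell (HSC) population
measured whole-cell only.

Cells are rendered as concentric disks (nucleus inside the cell, phalloidin
ring on the boundary); HSCs as small elongated ellipses whose footprint is
dominated by the nucleus. Pixels are floats in [0, 1]; additive Gaussian
noise is truncated to that range. Two draws with the same spec and seed are
bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._raster import annulus_pixels, disk_pixels, ellipse_pixels
from .exceptions import ConfigurationError, GeometryError
from .zonation import ZoneClassifier, ZoneLandmark

__all__ = [
    "CHANNELS",
    "IntensityComponent",
    "FractionComponent",
    "HscComponent",
    "LandmarkSpec",
    "PopulationSpec",
    "GroundTruthCell",
    "MultiplexImage",
    "SyntheticDataset",
    "generate_dataset",
    "generate_cell_table",
    "render_tissue_image",
    "place_landmarks",
    "cells_from_table",
    "study_conditions",
    "save_multiplex",
    "load_channel",
    "write_landmarks",
    "read_landmarks",
]

CHANNELS = ("dapi", "phalloidin", "nfkb", "gfap")

DAPI_LEVEL = 0.9
PHALLOIDIN_LEVEL = 0.8
GFAP_LEVEL = 0.85
RING_HALF_WIDTH = 1.0  # phalloidin ring spans cell_radius +/- this many pixels
#: extra center-to-center clearance beyond radius sum in disjoint layout,
#: leaving room for the phalloidin rings plus a one-pixel gap
PLACEMENT_CLEARANCE = 3.0


@dataclass(frozen=True)
class IntensityComponent:
    """Mixture component parameterized directly by intensity means/sds."""

    weight: float
    nuclear_mean: float
    nuclear_sd: float
    cyto_mean: float
    cyto_sd: float

    def draw(self, n: int, rng: np.random.Generator):
        i_n = np.clip(rng.normal(self.nuclear_mean, self.nuclear_sd, n) if self.nuclear_sd > 0
                      else np.full(n, float(self.nuclear_mean)), 0.0, 1.0)
        i_c = np.clip(rng.normal(self.cyto_mean, self.cyto_sd, n) if self.cyto_sd > 0
                      else np.full(n, float(self.cyto_mean)), 0.0, 1.0)
        return i_n, i_c


@dataclass(frozen=True)
class FractionComponent:
    """Mixture component parameterized by the per-cell *nuclear fraction*.

    The cytoplasmic intensity is drawn directly; the nuclear intensity is
    back-calculated from a drawn fraction ``f`` so that the expected group
    mean nuclear fraction equals ``nf_mean`` by construction — the natural
    parameterization for designed group shifts.
    """

    weight: float
    nf_mean: float
    nf_sd: float
    cyto_mean: float
    cyto_sd: float
    area_weight: float = 0.15

    def draw(self, n: int, rng: np.random.Generator):
        f = rng.normal(self.nf_mean, self.nf_sd, n) if self.nf_sd > 0 else np.full(n, self.nf_mean)
        f = np.clip(f, 1e-3, 0.99)
        i_c = np.clip(rng.normal(self.cyto_mean, self.cyto_sd, n) if self.cyto_sd > 0
                      else np.full(n, float(self.cyto_mean)), 1e-3, 1.0)
        a = self.area_weight
        i_n = np.clip((1.0 - a) * i_c * f / (a * (1.0 - f)), 0.0, 1.0)
        return i_n, i_c


@dataclass(frozen=True)
class HscComponent:
    weight: float
    mean: float
    sd: float


@dataclass(frozen=True)
class LandmarkSpec:
    """How many portal/central vein landmarks to place, and their radii."""

    n_portal: int = 1
    n_central: int = 1
    zone_radius: float = 120.0  # ~6 hepatocyte diameters at the default cell size
    lumen_radius: float = 15.0
    min_separation: float | None = None  # default: zone_radius


@dataclass(frozen=True)
class PopulationSpec:
    """Generator configuration for one experimental condition."""

    n_cells: int = 200
    components: tuple = (IntensityComponent(1.0, 0.28, 0.05, 0.40, 0.06),)
    frame: tuple[int, int] = (512, 512)
    n_images: int = 1
    nucleus_radius: float = 5.0
    cell_radius: float = 10.0
    radius_jitter: float = 0.8
    layout: str = "disjoint"
    noise_sd: float = 0.02
    n_hsc: int = 0
    hsc_components: tuple = (HscComponent(1.0, 0.32, 0.08),)
    hsc_axes: tuple[float, float] = (7.0, 4.0)
    group: str = "carbohydrate_baseline"
    landmarks: LandmarkSpec | None = None
    zonal_slope_portal: float = 0.0  # added to I_N, scaled by (1 - d/zone_radius)
    zonal_slope_central: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_cells <= 0:
            raise ConfigurationError("n_cells must be positive")
        for comps, what in ((self.components, "hepatocyte"), (self.hsc_components, "HSC")):
            w = sum(c.weight for c in comps)
            if comps and abs(w - 1.0) > 1e-9:
                raise ConfigurationError(f"{what} component weights sum to {w}, expected 1")
            if any(c.weight <= 0 for c in comps):
                raise ConfigurationError(f"{what} component weights must be positive")
        if not (0 < self.nucleus_radius < self.cell_radius):
            raise ConfigurationError("require 0 < nucleus_radius < cell_radius")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.layout not in ("disjoint", "free"):
            raise ConfigurationError(f"unknown layout {self.layout!r}")


@dataclass(frozen=True)
class GroundTruthCell:
    """Known parameters of one synthetic cell."""

    cell_id: int
    center: tuple[float, float]  # (row, col)
    nucleus_radius: float
    cell_radius: float
    true_nuclear_intensity: float
    true_cytoplasmic_intensity: float
    zone: str = "midzonal"
    cell_type: str = "hepatocyte"
    true_wholecell_intensity: float = float("nan")
    minor_radius: float | None = None  # HSC ellipse minor semi-axis
    orientation: float = 0.0

    def __post_init__(self):
        if not self.nucleus_radius < self.cell_radius:
            raise ConfigurationError("nucleus_radius must be smaller than cell_radius")


@dataclass
class MultiplexImage:
    """Four-channel synthetic field: dapi, phalloidin, nfkb, gfap in [0, 1]."""

    channels: dict

    def __post_init__(self):
        shapes = {ch: arr.shape for ch, arr in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ConfigurationError(f"channel shapes differ: {shapes}")
        for ch, arr in self.channels.items():
            if not np.all(np.isfinite(arr)) or arr.min() < 0 or arr.max() > 1:
                raise ConfigurationError(f"channel {ch!r} has values outside [0, 1]")

    @property
    def height(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def width(self) -> int:
        return next(iter(self.channels.values())).shape[1]


@dataclass
class SyntheticDataset:
    """A generated condition: the cell table plus per-image landmarks."""

    table: pd.DataFrame
    landmarks: dict  # image_id -> list[ZoneLandmark]
    spec: PopulationSpec


# ---------------------------------------------------------------------------
# placement

def _place_disjoint(rng, n, frame, radii, forbidden, max_tries_per_cell=4000):
    """Rejection-sample n non-overlapping circle centers inside the frame.

    ``radii`` are effective footprint radii (including ring clearance);
    ``forbidden`` is a list of (y, x, radius) exclusion disks (vein lumens).
    Exceeding the retry budget raises GeometryError rather than silently
    overlapping.
    """
    h, w = frame
    ys = np.empty(n)
    xs = np.empty(n)
    placed_r = np.empty(n)
    for i in range(n):
        r = radii[i]
        lo_y, hi_y = r + RING_HALF_WIDTH, h - 1 - r - RING_HALF_WIDTH
        lo_x, hi_x = r + RING_HALF_WIDTH, w - 1 - r - RING_HALF_WIDTH
        if lo_y >= hi_y or lo_x >= hi_x:
            raise GeometryError(f"cell radius {r} does not fit in frame {frame}")
        for _ in range(max_tries_per_cell):
            y = rng.uniform(lo_y, hi_y)
            x = rng.uniform(lo_x, hi_x)
            if i > 0:
                d2 = (ys[:i] - y) ** 2 + (xs[:i] - x) ** 2
                if np.any(d2 < (placed_r[:i] + r + PLACEMENT_CLEARANCE) ** 2):
                    continue
            if any((y - fy) ** 2 + (x - fx) ** 2 < (fr + r) ** 2 for fy, fx, fr in forbidden):
                continue
            ys[i], xs[i], placed_r[i] = y, x, r
            break
        else:
            raise GeometryError(
                f"could not place cell {i + 1}/{n} disjointly after "
                f"{max_tries_per_cell} tries; lower the density"
            )
    return ys, xs


def place_landmarks(
    frame=(512, 512),
    n_portal: int = 1,
    n_central: int = 1,
    zone_radius: float = 120.0,
    lumen_radius: float = 15.0,
    min_separation: float | None = None,
    rng=None,
    seed=None,
    max_tries: int = 5000,
):
    """Place portal and central vein landmarks inside the frame, deterministically under seed."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if min_separation is None:
        min_separation = zone_radius
    h, w = frame
    margin = lumen_radius + 1
    landmarks: list[ZoneLandmark] = []
    for lm_type in ["portal"] * n_portal + ["central"] * n_central:
        for _ in range(max_tries):
            y = rng.uniform(margin, h - 1 - margin)
            x = rng.uniform(margin, w - 1 - margin)
            if all(math.hypot(y - lm.y, x - lm.x) >= min_separation for lm in landmarks):
                landmarks.append(ZoneLandmark(lm_type, y, x, zone_radius, lumen_radius))
                break
        else:
            raise GeometryError(
                f"could not place landmarks with min separation {min_separation} in frame {frame}"
            )
    return landmarks


# ---------------------------------------------------------------------------
# table generation

def _split_counts(total: int, k: int) -> list[int]:
    base = total // k
    return [base + (1 if i < total % k else 0) for i in range(k)]


def generate_dataset(spec: PopulationSpec) -> SyntheticDataset:
    """Generate ground-truth cells (and landmarks) for every image of a condition.

    The returned table follows the CellMeasurement schema plus ground-truth
    columns; the fast path uses the true intensities as the measured ones,
    bypassing rendering and segmentation.
    """
    rng = np.random.default_rng(spec.seed)
    comp_weights = np.array([c.weight for c in spec.components])
    hsc_weights = np.array([c.weight for c in spec.hsc_components])
    rows = []
    landmarks_by_image: dict[str, list] = {}
    cell_counter = 0
    hep_counts = _split_counts(spec.n_cells, spec.n_images)
    hsc_counts = _split_counts(spec.n_hsc, spec.n_images) if spec.n_hsc else [0] * spec.n_images

    for img_idx in range(spec.n_images):
        image_id = f"{spec.group}-{img_idx:02d}"
        n_hep, n_hsc = hep_counts[img_idx], hsc_counts[img_idx]

        landmarks = []
        if spec.landmarks is not None:
            lmspec = spec.landmarks
            landmarks = place_landmarks(
                spec.frame, lmspec.n_portal, lmspec.n_central, lmspec.zone_radius,
                lmspec.lumen_radius, lmspec.min_separation, rng=rng,
            )
        landmarks_by_image[image_id] = landmarks

        jit = spec.radius_jitter
        cell_r = spec.cell_radius + (rng.uniform(-jit, jit, n_hep) if jit > 0 else np.zeros(n_hep))
        nuc_r = spec.nucleus_radius + (rng.uniform(-jit, jit, n_hep) / 2 if jit > 0 else np.zeros(n_hep))
        nuc_r = np.minimum(nuc_r, cell_r - 2.0)
        hsc_major = np.full(n_hsc, spec.hsc_axes[0])
        hsc_minor = np.full(n_hsc, spec.hsc_axes[1])
        orientations = rng.uniform(0, np.pi, n_hsc)

        footprints = np.concatenate([cell_r, hsc_major])
        forbidden = [(lm.y, lm.x, lm.lumen_radius) for lm in landmarks]
        if spec.layout == "disjoint":
            ys, xs = _place_disjoint(rng, n_hep + n_hsc, spec.frame, footprints, forbidden)
        else:
            h, w = spec.frame
            pad = footprints + RING_HALF_WIDTH
            ys = rng.uniform(pad, h - 1 - pad)
            xs = rng.uniform(pad, w - 1 - pad)

        comp = rng.choice(len(spec.components), size=n_hep, p=comp_weights)
        i_n = np.empty(n_hep)
        i_c = np.empty(n_hep)
        for ci, c in enumerate(spec.components):
            m = comp == ci
            if m.any():
                i_n[m], i_c[m] = c.draw(int(m.sum()), rng)

        zones = np.full(n_hep + n_hsc, "midzonal", dtype=object)
        if landmarks:
            clf = ZoneClassifier(landmarks).fit()
            pts = np.column_stack([ys, xs])
            zones = clf.predict(pts)
            # linear zonal gradient on nuclear intensity, sign per landmark type
            centers = np.array([[lm.y, lm.x] for lm in landmarks])
            dist = np.sqrt(((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
            nearest = np.argmin(dist, axis=1)
            for k in range(n_hep):
                lm = landmarks[nearest[k]]
                d = dist[k, nearest[k]]
                if d <= lm.zone_radius:
                    slope = (spec.zonal_slope_portal if lm.landmark_type == "portal"
                             else spec.zonal_slope_central)
                    i_n[k] = np.clip(i_n[k] + slope * (1.0 - d / lm.zone_radius), 0.0, 1.0)

        for k in range(n_hep):
            rows.append({
                "image_id": image_id, "cell_id": cell_counter, "cell_type": "hepatocyte",
                "group": spec.group, "zone": zones[k], "component": int(comp[k]),
                "y": ys[k], "x": xs[k],
                "nucleus_radius": nuc_r[k], "cell_radius": cell_r[k],
                "minor_radius": np.nan, "orientation": 0.0,
                "true_i_nuclear": i_n[k], "true_i_cytoplasmic": i_c[k],
                "true_i_wholecell": np.nan,
                "i_nuclear": i_n[k], "i_cytoplasmic": i_c[k], "i_wholecell": np.nan,
                "normalized": False,
            })
            cell_counter += 1

        if n_hsc:
            hcomp = rng.choice(len(spec.hsc_components), size=n_hsc, p=hsc_weights)
            i_w = np.empty(n_hsc)
            for ci, c in enumerate(spec.hsc_components):
                m = hcomp == ci
                if m.any():
                    i_w[m] = np.clip(rng.normal(c.mean, c.sd, int(m.sum())) if c.sd > 0
                                     else np.full(int(m.sum()), c.mean), 0.0, 1.0)
            for k in range(n_hsc):
                j = n_hep + k
                rows.append({
                    "image_id": image_id, "cell_id": cell_counter, "cell_type": "hsc",
                    "group": spec.group, "zone": zones[j], "component": int(hcomp[k]),
                    "y": ys[j], "x": xs[j],
                    "nucleus_radius": hsc_minor[k], "cell_radius": hsc_major[k],
                    "minor_radius": hsc_minor[k], "orientation": orientations[k],
                    "true_i_nuclear": np.nan, "true_i_cytoplasmic": np.nan,
                    "true_i_wholecell": i_w[k],
                    "i_nuclear": np.nan, "i_cytoplasmic": np.nan, "i_wholecell": i_w[k],
                    "normalized": False,
                })
                cell_counter += 1

    table = pd.DataFrame(rows)
    return SyntheticDataset(table=table, landmarks=landmarks_by_image, spec=spec)


def generate_cell_table(spec: PopulationSpec) -> pd.DataFrame:
    """Ground-truth cell table for a condition (fast path, no rendering)."""
    return generate_dataset(spec).table


def cells_from_table(table: pd.DataFrame) -> list:
    """Convert cell-table rows into :class:`GroundTruthCell` objects."""
    cells = []
    for row in table.itertuples(index=False):
        is_hsc = row.cell_type == "hsc"
        cells.append(GroundTruthCell(
            cell_id=int(row.cell_id),
            center=(float(row.y), float(row.x)),
            nucleus_radius=float(row.nucleus_radius),
            cell_radius=float(row.cell_radius),
            true_nuclear_intensity=float(row.true_i_nuclear) if not is_hsc else 0.0,
            true_cytoplasmic_intensity=float(row.true_i_cytoplasmic) if not is_hsc else 0.0,
            zone=str(row.zone),
            cell_type=str(row.cell_type),
            true_wholecell_intensity=float(row.true_i_wholecell) if is_hsc else float("nan"),
            minor_radius=float(row.minor_radius) if is_hsc else None,
            orientation=float(row.orientation),
        ))
    return cells


# ---------------------------------------------------------------------------
# rendering

def render_tissue_image(cells, spec: PopulationSpec, rng=None) -> MultiplexImage:
    """Rasterize ground-truth cells into a four-channel field.

    Noise-free contract: the mean of the nfkb channel over a hepatocyte's
    nucleus disk equals its true nuclear intensity exactly, and over its
    cytoplasmic annulus its true cytoplasmic intensity; gfap is zero outside
    HSC footprints.
    """
    if isinstance(cells, pd.DataFrame):
        cells = cells_from_table(cells)
    shape = spec.frame
    h, w = shape
    chan = {ch: np.zeros(shape, dtype=float) for ch in CHANNELS}
    for cell in cells:
        cy, cx = cell.center
        reach = cell.cell_radius + RING_HALF_WIDTH
        if cy - reach < 0 or cy + reach > h - 1 or cx - reach < 0 or cx + reach > w - 1:
            raise GeometryError(
                f"cell {cell.cell_id} at {cell.center} with radius {cell.cell_radius} "
                f"does not fit inside frame {shape}"
            )
        if cell.cell_type == "hepatocyte":
            nr, nc = disk_pixels(shape, cell.center, cell.nucleus_radius)
            chan["dapi"][nr, nc] = DAPI_LEVEL
            chan["nfkb"][nr, nc] = cell.true_nuclear_intensity
            ar, ac = annulus_pixels(shape, cell.center, cell.nucleus_radius, cell.cell_radius)
            chan["nfkb"][ar, ac] = cell.true_cytoplasmic_intensity
            rr, rc = annulus_pixels(
                shape, cell.center, cell.cell_radius - RING_HALF_WIDTH,
                cell.cell_radius + RING_HALF_WIDTH,
            )
            chan["phalloidin"][rr, rc] = PHALLOIDIN_LEVEL
        else:  # HSC: elongated ellipse, nucleus dominates the footprint
            minor = cell.minor_radius if cell.minor_radius else cell.cell_radius / 2
            br, bc = ellipse_pixels(shape, cell.center, cell.cell_radius, minor, cell.orientation)
            chan["gfap"][br, bc] = GFAP_LEVEL
            chan["nfkb"][br, bc] = cell.true_wholecell_intensity
            kr, kc = ellipse_pixels(
                shape, cell.center, 0.85 * cell.cell_radius, 0.85 * minor, cell.orientation
            )
            chan["dapi"][kr, kc] = 0.8 * DAPI_LEVEL
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        for ch in CHANNELS:
            chan[ch] = np.clip(chan[ch] + rng.normal(0.0, spec.noise_sd, shape), 0.0, 1.0)
    return MultiplexImage(channels=chan)


# ---------------------------------------------------------------------------
# study-condition presets

def study_conditions(seed: int | None = None, scale: float = 1.0) -> dict:
    """Reference specs for the four diet × surgery conditions.

    Per-condition hepatocyte totals (3941/2938 at baseline, 3639/3221 after
    partial hepatectomy) and HSC totals (152/132/163/128) match the scale of
    a typical two-rats-per-condition confocal study; the ethanol baseline is
    bimodal in both hepatocyte intensity space and HSC whole-cell intensity.
    ``scale`` shrinks every count proportionally for quick runs.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    def n(x):
        return max(int(round(x * scale)), 10)

    def images_for(total):
        return max(int(math.ceil(total / 200)), 1)

    conditions = {
        "carbohydrate_baseline": dict(
            n_cells=n(3941), n_hsc=max(int(round(152 * scale)), 4),
            components=(IntensityComponent(1.0, 0.28, 0.05, 0.40, 0.06),),
            hsc_components=(HscComponent(1.0, 0.32, 0.08),),
        ),
        "ethanol_baseline": dict(
            n_cells=n(2938), n_hsc=max(int(round(132 * scale)), 4),
            components=(
                IntensityComponent(0.6, 0.22, 0.04, 0.32, 0.05),
                IntensityComponent(0.4, 0.55, 0.05, 0.60, 0.05),
            ),
            hsc_components=(HscComponent(0.4, 0.33, 0.08), HscComponent(0.6, 0.65, 0.08)),
        ),
        "carbohydrate_phx": dict(
            n_cells=n(3639), n_hsc=max(int(round(163 * scale)), 4),
            components=(IntensityComponent(1.0, 0.45, 0.06, 0.42, 0.06),),
            hsc_components=(HscComponent(1.0, 0.25, 0.07),),
        ),
        "ethanol_phx": dict(
            n_cells=n(3221), n_hsc=max(int(round(128 * scale)), 4),
            components=(IntensityComponent(1.0, 0.40, 0.06, 0.50, 0.06),),
            hsc_components=(HscComponent(1.0, 0.28, 0.07),),
        ),
    }
    specs = {}
    for (group, kw), s in zip(conditions.items(), seeds):
        specs[group] = PopulationSpec(
            group=group, n_images=images_for(kw["n_cells"]), seed=s, **kw
        )
    return specs


# ---------------------------------------------------------------------------
# I/O

def save_multiplex(image: MultiplexImage, outdir, image_id: str, fmt: str = "tiff") -> dict:
    """Write one greyscale file per channel (16-bit TIFF or 8-bit PNG)."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for ch, arr in image.channels.items():
        if fmt == "tiff":
            import tifffile

            path = outdir / f"{image_id}_{ch}.tif"
            tifffile.imwrite(path, np.round(arr * 65535).astype(np.uint16))
        elif fmt == "png":
            import imageio.v3 as iio

            path = outdir / f"{image_id}_{ch}.png"
            iio.imwrite(path, np.round(arr * 255).astype(np.uint8))
        else:
            raise ConfigurationError(f"unknown image format {fmt!r}")
        paths[ch] = path
    return paths


def load_channel(path) -> np.ndarray:
    """Read a greyscale TIFF/PNG back into a float array in [0, 1]."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    return arr.astype(float)


def write_landmarks(landmarks, path) -> None:
    pd.DataFrame(
        [
            {"type": lm.landmark_type, "x": lm.x, "y": lm.y,
             "zone_radius": lm.zone_radius, "lumen_radius": lm.lumen_radius}
            for lm in landmarks
        ]
    ).to_csv(path, index=False)


def read_landmarks(path) -> list:
    df = pd.read_csv(path)
    return [
        ZoneLandmark(str(r.type), float(r.y), float(r.x), float(r.zone_radius),
                     float(r.lumen_radius))
        for r in df.itertuples(index=False)
    ]
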