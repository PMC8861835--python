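"""Synthetic landscapes and plain-text raster I/O.

A :class:`Landscape` is a stack of co-registered single-band grids on a
projected coordinate system (metres).  Layers mirror the covariates a
sagebrush-steppe habitat analysis works from: elevation, a three-class
escape-cover map (open / shrub taller than 0.5 m / tree), fractional
vegetation components, and Euclidean distance-to-feature surfaces for
roads, aspen stands and forest.

Grids are stored row-major with row 0 at the *top* (largest y), the usual
raster convention, and serialised as ESRI ASCII grids (.asc) so every
artefact stays plain text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

# Cover classes for the escape-cover layer.
COVER_OPEN = 0
COVER_SHRUB = 1  # shrubs > 0.5 m tall; shorter shrubs do not conceal a coyote
COVER_TREE = 2

FRACTION_LAYERS = ("shrub_height", "bare_ground", "herbaceous", "sage_height")
DISTANCE_LAYERS = ("distance_to_road", "distance_to_aspen", "distance_to_forest")


@dataclass
class Landscape:
    """Co-registered covariate grids on a square-cell projected grid.

    Parameters
    ----------
    origin
        (x, y) of the *lower-left corner* of the grid, metres.
    resolution
        Cell size in metres (> 0).
    layers
        Mapping layer name -> 2-D float array; all layers share one shape.
    """

    origin: tuple[float, float]
    resolution: float
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers disagree on shape: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.layers.values()))
        return first.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the covered area, metres."""
        ny, nx = self.shape
        x0, y0 = self.origin
        return (x0, x0 + nx * self.resolution, y0, y0 + ny * self.resolution)

    # ---- coordinate transforms ------------------------------------------
    def to_rowcol(self, x, y):
        """Map projected coordinates to (row, col) indices, clipped to grid."""
        ny, nx = self.shape
        x0, y0 = self.origin
        col = np.clip(
            np.floor((np.asarray(x) - x0) / self.resolution).astype(int), 0, nx - 1
        )
        row = np.clip(
            ny - 1 - np.floor((np.asarray(y) - y0) / self.resolution).astype(int),
            0,
            ny - 1,
        )
        return row, col

    def cell_center(self, row, col):
        ny, _ = self.shape
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.resolution
        y = y0 + (ny - np.asarray(row) - 0.5) * self.resolution
        return x, y

    def contains(self, x, y):
        xmin, xmax, ymin, ymax = self.extent
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def sample(self, layer: str, x, y):
        """Nearest-cell value of ``layer`` at projected coordinates."""
        row, col = self.to_rowcol(x, y)
        return self.layers[layer][row, col]

    # ---- plain-text persistence -----------------------------------------
    def write_ascii(self, directory: str | Path) -> None:
        """Write every layer as an ESRI ASCII grid ``<name>.asc``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(directory / f"{name}.asc", arr, self.origin, self.resolution)

    @classmethod
    def read_ascii(cls, directory: str | Path) -> "Landscape":
        directory = Path(directory)
        layers = {}
        origin = None
        res = None
        for path in sorted(directory.glob("*.asc")):
            arr, org, r = read_ascii_grid(path)
            layers[path.stem] = arr
            origin, res = org, r
        if not layers:
            raise FileNotFoundError(f"no .asc grids under {directory}")
        return cls(origin=origin, resolution=res, layers=layers)


def write_ascii_grid(path, arr, origin, resolution, nodata=-9999.0):
    arr = np.asarray(arr, dtype=float)
    ny, nx = arr.shape
    header = (
        f"ncols {nx}\nnrows {ny}\nxllcorner {origin[0]:.6f}\n"
        f"yllcorner {origin[1]:.6f}\ncellsize {resolution:.6f}\nNODATA_value {nodata}\n"
    )
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in arr)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path):
    lines = Path(path).read_text().splitlines()
    hdr = {}
    for ln in lines[:6]:
        key, val = ln.split()
        hdr[key.lower()] = float(val)
    arr = np.loadtxt(lines[6:])
    arr = arr.reshape(int(hdr["nrows"]), int(hdr["ncols"]))
    return arr, (hdr["xllcorner"], hdr["yllcorner"]), hdr["cellsize"]


def _smooth_unit_field(rng, shape, smoothness):
    """Spatially autocorrelated standard-normal field (z-scored)."""
    z = rng.standard_normal(shape)
    if smoothness > 0:
        z = ndimage.gaussian_filter(z, sigma=smoothness, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    return z


def _to_fraction(z):
    """Squash a z-scored field into (0, 1) with a logistic transform."""
    return 1.0 / (1.0 + np.exp(-z))


def gen_landscape(
    seed: int,
    extent: tuple[int, int] = (128, 128),
    resolution: float = 30.0,
    smoothness: float = 6.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> Landscape:
    """Generate a synthetic landscape with spatially autocorrelated layers.

    Layers emulate a 30-m covariate stack: ``elevation`` (m), ``cover``
    (0 open / 1 shrub>0.5 m / 2 tree), four fractional vegetation layers in
    [0, 1], and Euclidean ``distance_to_road`` / ``distance_to_aspen`` /
    ``distance_to_forest`` (m).  ``smoothness`` is the Gaussian-filter sigma
    in cells; 0 gives white noise.

    The cover map honours the escape-cover reclassification rule: cells
    whose shrub canopy is <= 0.5 m tall are "open" regardless of the latent
    shrub class, because short shrubs cannot conceal a coyote.
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    ny, nx = int(extent[0]), int(extent[1])
    if ny < 32 or nx < 32:
        raise ValueError("extent must be at least 32x32 cells")
    rng = np.random.default_rng(seed)
    shape = (ny, nx)

    elev_z = _smooth_unit_field(rng, shape, smoothness)
    elevation = 2100.0 + 250.0 * elev_z

    # Latent vegetation structure; shrub height in metres (0-1.6 m).
    veg_z = _smooth_unit_field(rng, shape, smoothness)
    shrub_height_m = 1.6 * _to_fraction(1.5 * veg_z)

    cover = np.full(shape, COVER_OPEN, dtype=int)
    tree_cut = np.quantile(veg_z, 0.90)
    shrub_cut = np.quantile(veg_z, 0.55)
    cover[(veg_z > shrub_cut) & (shrub_height_m > 0.5)] = COVER_SHRUB
    cover[veg_z > tree_cut] = COVER_TREE

    layers: dict[str, np.ndarray] = {
        "elevation": elevation,
        "cover": cover.astype(float),
        # shrub_height exported as a [0,1] fraction of the 1.6 m ceiling
        "shrub_height": shrub_height_m / 1.6,
        "bare_ground": _to_fraction(_smooth_unit_field(rng, shape, smoothness)),
        "herbaceous": _to_fraction(_smooth_unit_field(rng, shape, smoothness)),
        "sage_height": _to_fraction(_smooth_unit_field(rng, shape, smoothness)),
    }

    # Feature masks for the distance layers: a road running across the grid,
    # sparse aspen stands, and the tree class as "forest".
    road_mask = np.zeros(shape, dtype=bool)
    row_anchor = rng.integers(ny // 4, 3 * ny // 4)
    drift = np.cumsum(rng.integers(-1, 2, size=nx))
    road_rows = np.clip(row_anchor + drift, 0, ny - 1)
    road_mask[road_rows, np.arange(nx)] = True

    aspen_z = _smooth_unit_field(rng, shape, smoothness)
    aspen_mask = aspen_z > np.quantile(aspen_z, 0.97)
    forest_mask = cover == COVER_TREE

    for name, mask in (
        ("distance_to_road", road_mask),
        ("distance_to_aspen", aspen_mask),
        ("distance_to_forest", forest_mask),
    ):
        if mask.any():
            dist = ndimage.distance_transform_edt(~mask) * resolution
        else:  # degenerate mask: fall back to distance from the grid centre
            cy, cx = ny / 2, nx / 2
            rr, cc = np.mgrid[0:ny, 0:nx]
            dist = np.hypot(rr - cy, cc - cx) * resolution
        layers[name] = dist

    return Landscape(origin=origin, resolution=resolution, layers=layers)


def standardized_layer(landscape: Landscape, name: str) -> np.ndarray:
    """Grid-wide z-score of one layer (used by the track simulator)."""
    arr = landscape.layers[name]
    sd = arr.std()
    if sd == 0:
        return np.zeros_like(arr)
    return (arr - arr.mean()) / sd
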