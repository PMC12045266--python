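"""Synthetic two-channel stain images and boundary recovery.

Emulates the image-to-geometry stage of the workflow: a fluorescence-like
raster (channel 0 = nucleus stain, channel 1 = ER stain) is rendered from a
known :class:`~porefem.geometry.CellGeometry`, then segmented by intensity
k-means clustering plus morphological cleanup, and the foreground regions
are vectorized back into simplified closed polygons in um coordinates.

Raster convention: row 0 is the top of the image; geometry coordinates have
the origin at the lower-left of the box with y up. The conversion is done
explicitly in :func:`render_stain_image` / :func:`contours_from_labels`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from skimage import measure, morphology
from skimage.draw import polygon2mask
from skimage.filters import gaussian

from .geometry import CellGeometry, ClosedContour, GeometryError

__all__ = [
    "SyntheticStainImage",
    "render_stain_image",
    "segment_image",
    "contours_from_labels",
    "save_stain_image",
    "load_stain_image",
]


@dataclass
class SyntheticStainImage:
    """Rendered two-channel stain image with its ground-truth geometry."""

    pixels: np.ndarray  # (rows, cols, 2) float in [0, 1]
    pixel_size_um: float
    noise: float
    blur_px: float
    ground_truth: CellGeometry

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _to_rowcol(vertices_um: np.ndarray, n_rows: int, pixel_size: float) -> np.ndarray:
    """um coordinates (x right, y up) -> raster (row down, col right)."""
    col = vertices_um[:, 0] / pixel_size
    row = n_rows - vertices_um[:, 1] / pixel_size
    return np.column_stack([row, col])


def _to_um(rowcol: np.ndarray, n_rows: int, pixel_size: float) -> np.ndarray:
    x = rowcol[:, 1] * pixel_size
    y = (n_rows - rowcol[:, 0]) * pixel_size
    return np.column_stack([x, y])


def render_stain_image(
    geometry: CellGeometry,
    pixel_size: float = 0.2,
    blur: float = 1.0,
    noise: float = 0.05,
    seed: int = 0,
) -> SyntheticStainImage:
    """Render a noisy two-channel stain image of the geometry.

    Channel 0 is bright (1.0) inside the nucleus, channel 1 inside every ER
    loop; a Gaussian blur of ``blur`` pixels and additive Gaussian noise of
    standard deviation ``noise`` are applied, then intensities are clipped
    to [0, 1]. The ground-truth geometry is embedded for round-trip tests.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if noise < 0 or blur < 0:
        raise ValueError("noise and blur must be nonnegative")
    w, h = geometry.domain_box
    n_rows = int(round(h / pixel_size))
    n_cols = int(round(w / pixel_size))
    img = np.zeros((n_rows, n_cols, 2), dtype=float)
    img[..., 0] = polygon2mask((n_rows, n_cols), _to_rowcol(geometry.nucleus.vertices, n_rows, pixel_size))
    for loop in geometry.er_loops:
        img[..., 1] = np.maximum(
            img[..., 1], polygon2mask((n_rows, n_cols), _to_rowcol(loop.vertices, n_rows, pixel_size))
        )
    if blur > 0:
        for c in range(2):
            img[..., c] = gaussian(img[..., c], sigma=blur, preserve_range=True)
    if noise > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return SyntheticStainImage(img, pixel_size, noise, blur, geometry)


def _cluster_foreground(channel: np.ndarray, n_clusters: int) -> np.ndarray:
    """Intensity k-means; pixels of the brightest cluster are foreground."""
    flat = channel.reshape(-1, 1)
    if np.ptp(flat) < 1e-12:  # constant image: nothing to cluster
        return np.zeros(channel.shape, dtype=bool)
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=n_clusters, n_init=3, random_state=0)
    labels = km.fit_predict(flat)
    brightest = int(np.argmax(km.cluster_centers_.ravel()))
    return (labels == brightest).reshape(channel.shape)


def segment_image(
    image: SyntheticStainImage | np.ndarray,
    n_clusters: int = 2,
    min_region_px: int = 16,
) -> list[np.ndarray]:
    """Cluster-segment each channel into labelled foreground regions.

    Returns one integer label map per channel (0 = background, 1..n =
    connected foreground regions). Foreground is the brightest of
    ``n_clusters`` intensity clusters, cleaned by a morphological opening;
    connected regions below ``min_region_px`` pixels are removed. A blank
    or constant channel yields an all-zero label map.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be at least 2")
    pixels = image.pixels if isinstance(image, SyntheticStainImage) else np.asarray(image, dtype=float)
    if pixels.ndim == 2:
        pixels = pixels[..., None]
    label_maps = []
    for c in range(pixels.shape[-1]):
        fg = _cluster_foreground(pixels[..., c], n_clusters)
        fg = morphology.opening(fg, morphology.disk(1))
        if min_region_px > 1:
            fg = morphology.remove_small_objects(fg, max_size=min_region_px - 1)
        label_maps.append(measure.label(fg, connectivity=1))
    return label_maps


def contours_from_labels(
    label_map: np.ndarray,
    simplify_tol_um: float = 0.05,
    pixel_size: float = 0.2,
    label: str = "er",
) -> list[ClosedContour]:
    """Vectorize a label map: one simplified closed polygon per region.

    Polygons are traced at the 0.5 iso-level of each region mask, converted
    to um (y flipped back up), simplified with a Douglas-Peucker tolerance
    ``simplify_tol_um``, and normalized counterclockwise. Regions touching
    the image border are closed along the border with a warning.
    """
    label_map = np.asarray(label_map)
    n_rows = label_map.shape[0]
    out: list[ClosedContour] = []
    for region_id in range(1, int(label_map.max()) + 1):
        mask = label_map == region_id
        if not mask.any():
            continue
        if (mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()):
            warnings.warn(
                f"region {region_id} touches the image border; contour closed along the border",
                stacklevel=2,
            )
        padded = np.pad(mask.astype(float), 1)
        traced = measure.find_contours(padded, 0.5)
        if not traced:
            continue
        rc = max(traced, key=len) - 1.0  # undo padding offset
        pts = _to_um(rc, n_rows, pixel_size)
        poly = Polygon(pts)
        if simplify_tol_um > 0:
            poly = poly.simplify(simplify_tol_um, preserve_topology=True)
        xy = np.asarray(poly.exterior.coords)[:-1]
        if len(xy) < 8:  # re-densify tiny polygons so the contour invariant holds
            dense = Polygon(pts).simplify(simplify_tol_um / 4, preserve_topology=True)
            xy = np.asarray(dense.exterior.coords)[:-1]
        try:
            out.append(ClosedContour(xy, label))
        except GeometryError:
            # degenerate sliver region: skip rather than fail the whole map
            continue
    return out


def save_stain_image(image: SyntheticStainImage, path: str) -> None:
    """Write the two-channel image as 16-bit TIFF (2 planes) or RGB PNG.

    In the RGB encoding the nucleus stain goes to the blue channel and the
    ER stain to the green channel, mirroring DAPI / ER-tracker micrographs.
    """
    arr16 = np.clip(image.pixels * 65535.0, 0, 65535).astype(np.uint16)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, np.moveaxis(arr16, -1, 0))  # (C, rows, cols)
    elif path.lower().endswith(".png"):
        import imageio.v3 as iio

        # 16-bit RGB PNG is not portable; PNG export is 8-bit
        arr8 = np.clip(image.pixels * 255.0, 0, 255).astype(np.uint8)
        rgb = np.zeros(image.shape + (3,), dtype=np.uint8)
        rgb[..., 2] = arr8[..., 0]  # nucleus -> blue
        rgb[..., 1] = arr8[..., 1]  # ER -> green
        iio.imwrite(path, rgb)
    else:
        raise ValueError(f"unsupported image format: {path}")


def load_stain_image(path: str) -> np.ndarray:
    """Read a stain image back as a (rows, cols, 2) float array in [0, 1].

    Accepts the 2-plane TIFF and RGB PNG layouts written by
    :func:`save_stain_image` (blue -> nucleus channel, green -> ER channel).
    """
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        planes = tifffile.imread(path)
        if planes.ndim != 3 or planes.shape[0] != 2:
            raise ValueError("expected a 2-plane TIFF stain image")
        arr = np.moveaxis(planes, 0, -1).astype(float)
    else:
        import imageio.v3 as iio

        rgb = iio.imread(path)
        if rgb.ndim != 3 or rgb.shape[-1] < 3:
            raise ValueError("expected an RGB stain image")
        arr = np.stack([rgb[..., 2], rgb[..., 1]], axis=-1).astype(float)
    scale = 65535.0 if arr.max() > 255 else (255.0 if arr.max() > 1 else 1.0)
    return arr / scale
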