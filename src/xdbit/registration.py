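"""Counts-to-AnnData: image registration and spot projection.

The chip deposits a fluorescent frame of alignment marks along the
outermost channels of each capture area.  After the run, a low-resolution
alignment image records both the marks and the nuclei stain; a
high-resolution image of the same scene was taken before the run.  Two
transforms chain the spot grid onto the high-resolution image:

* grid -> alignment image: a planar affine estimated from >= 3 marker
  vertices whose positions are known both on the chip (µm) and in the
  image (px), detected automatically or supplied manually;
* alignment -> high-resolution image: a feature-based affine from
  scale-invariant keypoint matches between the two nuclei images,
  estimated robustly with random-sample consensus.

Coordinates are (x = column, y = row), origin top-left, in both the µm
grid frame and pixel frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint
from skimage.feature import SIFT, match_descriptors
from skimage.filters import threshold_otsu
from skimage.measure import label, ransac, regionprops
from skimage.morphology import closing, footprint_rectangle
from skimage.transform import AffineTransform as _SkAffine

from .chip_geometry import SpotGrid

__all__ = [
    "ImagePlane",
    "AffineTransform2D",
    "MarkerVertices",
    "RegistrationError",
    "estimate_affine_from_points",
    "detect_marker_vertices",
    "robust_affine_from_matches",
    "register_feature_based",
    "project_spots",
]

#: default pixel sizes, µm per pixel
ALIGNMENT_PIXEL_SIZE_UM = 0.49
HIRES_PIXEL_SIZE_UM = 0.24


class RegistrationError(RuntimeError):
    """Raised when a transform cannot be estimated."""


@dataclass(frozen=True)
class ImagePlane:
    """A single-channel intensity raster with physical pixel size."""

    data: np.ndarray
    pixel_size_um: float
    channel: str = "nuclei"

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or min(self.data.shape) < 1:
            raise ValueError("image must be a non-empty 2D raster")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


class AffineTransform2D:
    """Planar affine map given by a 2x3 matrix acting on (x, y) points."""

    def __init__(self, matrix: np.ndarray):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise RegistrationError("affine linear part is singular")
        self.matrix = m

    # -- constructors -------------------------------------------------------

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def from_components(
        cls,
        scale: float | tuple[float, float] = 1.0,
        rotation_deg: float = 0.0,
        translation: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform2D":
        sx, sy = (scale, scale) if np.isscalar(scale) else scale
        th = np.deg2rad(rotation_deg)
        c, s = np.cos(th), np.sin(th)
        lin = np.array([[c, -s], [s, c]]) @ np.diag([sx, sy])
        return cls(np.column_stack([lin, np.asarray(translation, float)]))

    # -- action -------------------------------------------------------------

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def compose(self, inner: "AffineTransform2D") -> "AffineTransform2D":
        """self o inner: apply ``inner`` first, then ``self``."""
        a, b = self.matrix, inner.matrix
        lin = a[:, :2] @ b[:, :2]
        trans = a[:, :2] @ b[:, 2] + a[:, 2]
        return AffineTransform2D(np.column_stack([lin, trans]))

    def invert(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.matrix[:, :2])
        return AffineTransform2D(np.column_stack([inv, -inv @ self.matrix[:, 2]]))

    # -- I/O ----------------------------------------------------------------

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"matrix": self.matrix.tolist()}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AffineTransform2D":
        with open(path) as fh:
            return cls(np.asarray(json.load(fh)["matrix"]))

    def __repr__(self) -> str:  # pragma: no cover
        return f"AffineTransform2D({self.matrix.tolist()})"


@dataclass(frozen=True)
class MarkerVertices:
    """Labeled marker-frame corners: image px against known grid µm."""

    labels: tuple[str, ...]
    image_px: np.ndarray  # (n, 2) detected corner positions
    grid_um: np.ndarray | None = None  # (n, 2) reference positions, if known

    def __post_init__(self) -> None:
        pts = np.asarray(self.image_px, float)
        if pts.shape[0] < 3:
            raise RegistrationError("need at least 3 marker vertices")
        if _collinear(pts):
            raise RegistrationError("marker vertices are collinear")

    @classmethod
    def from_tsv(cls, path) -> "MarkerVertices":
        """Manual-points fallback file: columns label, x_px, y_px."""
        df = pd.read_csv(path, sep="\t")
        return cls(
            labels=tuple(df["label"].astype(str)),
            image_px=df[["x_px", "y_px"]].to_numpy(float),
        )


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    pts = np.asarray(pts, float)
    if len(pts) < 3:
        return True
    d = pts - pts.mean(axis=0)
    s = np.linalg.svd(d, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


# ---------------------------------------------------------------------------
# point-based estimation
# ---------------------------------------------------------------------------

def estimate_affine_from_points(
    src_points: np.ndarray, dst_points: np.ndarray
) -> AffineTransform2D:
    """Least-squares affine minimising sum ||T(src) - dst||^2.

    Exact for three non-collinear correspondences; with more points the
    normal equations give the unique least-squares solution.
    """
    src = np.atleast_2d(np.asarray(src_points, float))
    dst = np.atleast_2d(np.asarray(dst_points, float))
    if src.shape != dst.shape or src.shape[0] < 3:
        raise RegistrationError("need >= 3 matched point pairs of equal shape")
    if _collinear(src):
        raise RegistrationError("source points are collinear")
    design = np.column_stack([src, np.ones(len(src))])
    coeffs, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return AffineTransform2D(coeffs.T)


# ---------------------------------------------------------------------------
# marker-frame corner detection
# ---------------------------------------------------------------------------

def detect_marker_vertices(
    image: ImagePlane,
    closing_size: int = 5,
    manual_points: MarkerVertices | None = None,
) -> MarkerVertices:
    """Find the four corners of the alignment-mark frame.

    Otsu-thresholds the marker channel, closes small gaps and keeps the
    largest connected component (the frame).  The returned corners are
    those of the frame's *centerline* quadrilateral: the minimum-area
    bounding rectangle of the frame pixels (its outer boundary) averaged
    with that of the enclosed hole (its inner boundary), since the marker
    stroke is one channel wide and the reference grid positions run along
    the channel center lines.  If no usable frame is found the manual
    points are returned when provided, otherwise a ``RegistrationError``
    asks for a manual-points file.
    """
    img = np.asarray(image.data, float)
    if img.max() <= img.min():
        if manual_points is not None:
            return manual_points
        raise RegistrationError(
            "no alignment-mark frame found (flat image); supply manual points"
        )
    mask = img > threshold_otsu(img)
    mask = closing(mask, footprint_rectangle((closing_size, closing_size)))
    lab = label(mask)
    props = regionprops(lab)
    if not props:
        if manual_points is not None:
            return manual_points
        raise RegistrationError(
            "no alignment-mark frame found; supply manual points"
        )
    largest = max(props, key=lambda p: p.area)
    frame = lab == largest.label
    rr, cc = np.nonzero(frame)
    # frame pixels as (x, y); min-area rotated rectangle of their hull
    quad = MultiPoint(np.column_stack([cc, rr])).minimum_rotated_rectangle
    corners = np.asarray(quad.exterior.coords)[:4]
    inner = _inner_rectangle(frame)
    if inner is not None:
        corners = (corners + _match_corner_order(inner, corners)) / 2.0
    if _collinear(corners):
        if manual_points is not None:
            return manual_points
        raise RegistrationError("degenerate frame; supply manual points")
    # stable labelling: order corners as TL, TR, BR, BL by angle around center
    center = corners.mean(axis=0)
    ang = np.arctan2(corners[:, 1] - center[1], corners[:, 0] - center[0])
    order = np.argsort(ang)  # CCW in image coords = TL..BL visually clockwise
    corners = corners[order]
    start = int(np.argmin(corners.sum(axis=1)))  # top-left first
    corners = np.roll(corners, -start, axis=0)
    return MarkerVertices(
        labels=("top_left", "top_right", "bottom_right", "bottom_left")
        if _is_clockwise_screen(corners)
        else ("top_left", "bottom_left", "bottom_right", "top_right"),
        image_px=corners,
    )


def _inner_rectangle(frame_mask: np.ndarray) -> np.ndarray | None:
    """Min-area rectangle corners of the hole enclosed by the frame."""
    holes = label(~frame_mask)
    rr, cc = np.nonzero(frame_mask)
    r0, r1, c0, c1 = rr.min(), rr.max(), cc.min(), cc.max()
    best, best_area = None, 0
    for p in regionprops(holes):
        hr0, hc0, hr1, hc1 = p.bbox
        if hr0 > r0 and hc0 > c0 and hr1 <= r1 and hc1 <= c1 and p.area > best_area:
            best, best_area = p, p.area
    if best is None:
        return None
    hr, hc = np.nonzero(holes == best.label)
    quad = MultiPoint(np.column_stack([hc, hr])).minimum_rotated_rectangle
    coords = np.asarray(quad.exterior.coords)
    if len(coords) < 5:  # degenerate hole (line or point)
        return None
    return coords[:4]


def _match_corner_order(pts: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Reorder ``pts`` so each row pairs with the nearest row of ``ref``."""
    out = np.empty_like(ref)
    for i, r in enumerate(ref):
        out[i] = pts[np.argmin(np.linalg.norm(pts - r, axis=1))]
    return out


def _is_clockwise_screen(corners: np.ndarray) -> bool:
    # screen coords (y down): positive shoelace area = clockwise on screen
    x, y = corners[:, 0], corners[:, 1]
    return float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) > 0


def frame_reference_corners_um(grid: SpotGrid, well_id: str) -> np.ndarray:
    """Grid-side µm positions of the marker-frame corners of one area.

    The frame is drawn along the center lines of the outermost alignment
    channels; its corners are the intersections of the first and last
    alignment channels, ordered TL, TR, BR, BL.
    """
    layout = grid.layout
    if not layout.alignment_channels:
        raise RegistrationError("layout has no alignment channels")
    lo, hi = min(layout.alignment_channels), max(layout.alignment_channels)
    ox, oy = layout.section_origins[well_id]
    half = layout.channel_width / 2.0
    c = lambda i: i * layout.pitch + half
    return np.array(
        [
            [ox + c(lo), oy + c(lo)],
            [ox + c(hi), oy + c(lo)],
            [ox + c(hi), oy + c(hi)],
            [ox + c(lo), oy + c(hi)],
        ]
    )


# ---------------------------------------------------------------------------
# feature-based registration
# ---------------------------------------------------------------------------

def robust_affine_from_matches(
    src: np.ndarray,
    dst: np.ndarray,
    inlier_threshold_px: float = 3.0,
    min_inliers: int = 3,
    max_trials: int = 1000,
    seed: int = 0,
) -> tuple[AffineTransform2D, np.ndarray]:
    """Affine from noisy point matches by random-sample consensus.

    Draws 3-point samples, scores inliers within ``inlier_threshold_px``
    and refines the best model by least squares on its inliers.  Returns
    the transform and the boolean inlier mask.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if len(src) < min_inliers:
        raise RegistrationError(f"need >= {min_inliers} matches")
    model, inliers = ransac(
        (src, dst),
        _SkAffine,
        min_samples=3,
        residual_threshold=inlier_threshold_px,
        max_trials=max_trials,
        rng=seed,
    )
    if model is None or inliers is None or inliers.sum() < min_inliers:
        raise RegistrationError("random-sample consensus found < 3 inliers")
    return estimate_affine_from_points(src[inliers], dst[inliers]), inliers


def register_feature_based(
    image_a: ImagePlane,
    image_b: ImagePlane,
    ratio: float = 0.75,
    inlier_threshold_px: float = 3.0,
    min_inliers: int = 3,
    max_trials: int = 1000,
    seed: int = 0,
    upsampling: int = 1,
) -> tuple[AffineTransform2D, dict]:
    """Affine mapping image_a pixel coordinates into image_b.

    Scale-invariant blob keypoints and descriptors are extracted from both
    images and matched nearest-neighbour with a ratio test; a robust
    affine is found by random-sample consensus (3-point samples, inliers
    within ``inlier_threshold_px``) and refined by least squares on the
    inliers.  Returns the transform and a report with inlier count and
    RMS residual.
    """
    def _features(plane: ImagePlane):
        det = SIFT(upsampling=upsampling)
        try:
            det.detect_and_extract(np.asarray(plane.data, float))
        except RuntimeError as exc:  # no keypoints in a featureless image
            raise RegistrationError(f"keypoint detection failed: {exc}") from exc
        # keypoints are (row, col); convert to (x, y)
        return det.keypoints[:, ::-1].astype(float), det.descriptors

    kp_a, desc_a = _features(image_a)
    kp_b, desc_b = _features(image_b)
    if len(kp_a) < min_inliers or len(kp_b) < min_inliers:
        raise RegistrationError("too few keypoints for feature registration")
    matches = match_descriptors(
        desc_a, desc_b, cross_check=True, max_ratio=ratio
    )
    if len(matches) < min_inliers:
        raise RegistrationError(
            f"only {len(matches)} descriptor matches; need >= {min_inliers}"
        )
    src = kp_a[matches[:, 0]]
    dst = kp_b[matches[:, 1]]
    transform, inliers = robust_affine_from_matches(
        src,
        dst,
        inlier_threshold_px=inlier_threshold_px,
        min_inliers=min_inliers,
        max_trials=max_trials,
        seed=seed,
    )
    resid = transform.apply(src[inliers]) - dst[inliers]
    report = {
        "n_matches": int(len(matches)),
        "n_inliers": int(inliers.sum()),
        "rms_residual_px": float(np.sqrt((resid**2).sum(axis=1).mean())),
    }
    return transform, report


# ---------------------------------------------------------------------------
# spot projection
# ---------------------------------------------------------------------------

def project_spots(
    grid: SpotGrid,
    transform: AffineTransform2D,
    image_shape: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Project spot centers and outlines into image pixel coordinates.

    ``transform`` maps the µm grid frame into image pixels.  Each spot
    contributes its transformed center and the transformed corners of its
    channel-width square outline.  Spots landing outside ``image_shape``
    (rows, cols) are flagged ``out_of_bounds`` but kept.
    """
    layout = grid.layout
    half = layout.channel_width / 2.0
    centers = np.array([s.center_um for s in grid.spots])
    px = transform.apply(centers)
    offsets = np.array(
        [[-half, -half], [half, -half], [half, half], [-half, half]]
    )
    polys = [transform.apply(c + offsets) for c in centers]
    df = pd.DataFrame(
        {
            "well_id": [s.well_id for s in grid.spots],
            "x_idx": [s.x_idx for s in grid.spots],
            "y_idx": [s.y_idx for s in grid.spots],
            "is_barcoded": [s.is_barcoded for s in grid.spots],
            "x_px": px[:, 0],
            "y_px": px[:, 1],
            "polygon_px": [p.tolist() for p in polys],
        }
    )
    if image_shape is not None:
        nrows, ncols = image_shape
        df["out_of_bounds"] = ~(
            (px[:, 0] >= 0)
            & (px[:, 0] < ncols)
            & (px[:, 1] >= 0)
            & (px[:, 1] < nrows)
        )
    return df
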