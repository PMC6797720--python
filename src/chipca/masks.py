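"""Device masks: the simulation domain of a microfluidic chip.

A mask is a black/white raster of a device's top view: white pixels are
positions a cell may occupy, black pixels are walls.  One pixel represents
one cell-sized square (20 x 20 um by default).  Masks are loaded from PNG
or JPEG images, binarized with a luminance threshold so that anti-aliasing
and compression artifacts cannot leave a third state, or generated
synthetically from parametric device layouts (a straight channel joining
two wells, a radial array of channels, a multi-chamber device, or a custom
union of discs and rectangles).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "DeviceMask",
    "DeviceSpec",
    "Disc",
    "Rect",
    "OrientedRect",
    "GeometryError",
    "GeometryWarning",
    "MaskInputError",
    "load_mask",
    "make_device",
    "mask_to_image",
    "write_mask",
    "connected_components",
]

#: physical side length of one lattice pixel, micrometres (one pixel = one cell)
DEFAULT_PIXEL_SIZE_UM = 20.0

# 4-connectivity structuring element shared by labeling and morphology
_VON_NEUMANN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class MaskInputError(ValueError):
    """The raster image could not be decoded or is empty."""


class GeometryError(ValueError):
    """The mask geometry is unusable (e.g. no allowed pixel survives)."""


class GeometryWarning(UserWarning):
    """Non-fatal geometry issue, e.g. a disconnected allowed region."""


@dataclass(frozen=True)
class DeviceMask:
    """Boolean lattice of cell-permitted (True) vs wall (False) pixels.

    Parameters
    ----------
    allowed : (n_rows, n_cols) bool array
        True where a cell may sit.  Raster convention: 0-based (row, col),
        origin top-left, rows increase downward.
    pixel_size_um : float
        Physical side length of one pixel.  Metadata only: no lattice
        operation depends on it, it is carried for reporting.
    """

    allowed: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        arr = np.asarray(self.allowed, dtype=bool)
        if arr.ndim != 2 or arr.size == 0:
            raise GeometryError("mask must be a non-empty 2D grid")
        if not arr.any():
            raise GeometryError("mask has zero allowed pixels")
        if not self.pixel_size_um > 0:
            raise GeometryError("pixel_size_um must be > 0")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "allowed", arr)

    @property
    def n_rows(self) -> int:
        return self.allowed.shape[0]

    @property
    def n_cols(self) -> int:
        return self.allowed.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.allowed.shape

    @property
    def n_allowed(self) -> int:
        return int(self.allowed.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DeviceMask):
            return NotImplemented
        return (
            self.allowed.shape == other.allowed.shape
            and bool(np.array_equal(self.allowed, other.allowed))
            and self.pixel_size_um == other.pixel_size_um
        )


# --------------------------------------------------------------------------
# raster I/O


def load_mask(
    image,
    luminance_threshold: int = 128,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> DeviceMask:
    """Binarize a raster image into a :class:`DeviceMask`.

    Every pixel whose mean luminance is >= ``luminance_threshold`` becomes
    allowed, every other pixel a wall; no intermediate grey state survives.
    PNG is the canonical lossless format; JPEG is tolerated precisely
    because thresholding absorbs its compression artifacts.

    Parameters
    ----------
    image : path-like, file object or PIL.Image.Image
    luminance_threshold : int in [0, 255]
    """
    if not 0 <= luminance_threshold <= 255:
        raise MaskInputError("luminance_threshold must be in [0, 255]")
    if isinstance(image, Image.Image):
        img = image
    else:
        try:
            img = Image.open(image)
        except Exception as exc:  # undecodable / missing file
            raise MaskInputError(f"cannot decode mask image: {exc}") from exc
    arr = np.asarray(img.convert("L"), dtype=np.uint8)
    if arr.size == 0:
        raise MaskInputError("mask image has no pixels")
    allowed = arr >= luminance_threshold
    if not allowed.any():
        raise GeometryError(
            "no allowed pixels after thresholding; mask is unusable"
        )
    return DeviceMask(allowed=allowed, pixel_size_um=pixel_size_um)


def mask_to_image(mask: DeviceMask) -> Image.Image:
    """Render a mask as a pure black/white RGB image (allowed -> 255)."""
    rgb = np.zeros((mask.n_rows, mask.n_cols, 3), dtype=np.uint8)
    rgb[mask.allowed] = 255
    return Image.fromarray(rgb, mode="RGB")


def write_mask(mask: DeviceMask, path) -> None:
    """Write a mask as a lossless PNG (bit-exact black/white)."""
    mask_to_image(mask).save(path, format="PNG")


def connected_components(mask: DeviceMask) -> tuple[np.ndarray, list[int]]:
    """Label the allowed region with 4-connectivity.

    Returns ``(labels, sizes)`` where ``labels`` is an int array (0 on
    walls, 1..k on allowed pixels) and ``sizes[i]`` is the pixel count of
    component ``i + 1``.  Sizes sum to the allowed-pixel count.
    """
    labels, n = ndimage.label(mask.allowed, structure=_VON_NEUMANN)
    sizes = ndimage.sum_labels(
        np.ones_like(labels), labels, index=range(1, n + 1)
    )
    return labels, [int(s) for s in sizes]


# --------------------------------------------------------------------------
# synthetic device geometry
#
# Shapes live in physical coordinates (micrometres), x to the right and y
# downward, matching the raster convention.  A pixel is allowed iff its
# *center* lies inside the union of the spec's shapes -- deterministic and
# trivially checkable by an independent point-in-shape scan.


@dataclass(frozen=True)
class Disc:
    cx: float
    cy: float
    r: float

    def contains(self, x, y):
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.r**2


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle [x0, x1] x [y0, y1] (closed)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x, y):
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)


@dataclass(frozen=True)
class OrientedRect:
    """Rectangle anchored at (cx, cy), extending `length` along `angle_rad`
    with half-width `half_width` perpendicular to it."""

    cx: float
    cy: float
    angle_rad: float
    length: float
    half_width: float

    def contains(self, x, y):
        dx = x - self.cx
        dy = y - self.cy
        c, s = math.cos(self.angle_rad), math.sin(self.angle_rad)
        u = dx * c + dy * s
        v = -dx * s + dy * c
        return (u >= 0) & (u <= self.length) & (np.abs(v) <= self.half_width)


Shape = Disc | Rect | OrientedRect


@dataclass(frozen=True)
class DeviceSpec:
    """Parametric description of a microfluidic layout (lengths in um).

    ``kind`` is one of ``single_channel`` (two circular wells joined by a
    straight channel), ``radial`` (central chamber with N evenly spaced
    channels each ending in a well), ``multi_chamber`` (two rows of
    rectangular chambers hanging off a central channel with inlet/outlet
    wells -- the "metastasis" layout) or ``custom`` (explicit shape union,
    used e.g. for blood-brain-barrier-like assemblies).
    """

    kind: str
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    well_radius_um: float = 1000.0
    channel_width_um: float = 200.0
    channel_length_um: float = 4000.0
    well_gap_um: float | None = None  # edge-to-edge well gap; default = channel length
    n_channels: int = 6
    chamber_radius_um: float = 1500.0
    chamber_width_um: float = 1200.0
    chamber_height_um: float = 800.0
    n_chambers: int = 3
    connector_length_um: float = 200.0
    margin_um: float = 40.0
    shapes: tuple[Shape, ...] = field(default_factory=tuple)

    KINDS = ("single_channel", "radial", "multi_chamber", "custom")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise GeometryError(
                f"unknown device kind {self.kind!r}; choose from {self.KINDS}"
            )
        positives = {
            "pixel_size_um": self.pixel_size_um,
            "well_radius_um": self.well_radius_um,
            "channel_width_um": self.channel_width_um,
            "chamber_radius_um": self.chamber_radius_um,
            "chamber_width_um": self.chamber_width_um,
            "chamber_height_um": self.chamber_height_um,
            "connector_length_um": self.connector_length_um,
        }
        for name, value in positives.items():
            if not value > 0:
                raise GeometryError(f"{name} must be > 0 (got {value})")
        if self.channel_length_um < 0:
            raise GeometryError("channel_length_um must be >= 0")
        if self.margin_um < 0:
            raise GeometryError("margin_um must be >= 0")
        if self.kind == "radial" and self.n_channels < 1:
            raise GeometryError("radial device needs n_channels >= 1")
        if self.kind == "multi_chamber" and self.n_chambers < 1:
            raise GeometryError("multi_chamber device needs n_chambers >= 1")
        if self.kind == "custom" and not self.shapes:
            raise GeometryError("custom device needs at least one shape")


def device_shapes(spec: DeviceSpec) -> tuple[list[Shape], float, float]:
    """Resolve a spec into shapes plus canvas (width_um, height_um)."""
    m = spec.margin_um
    if spec.kind == "single_channel":
        r = spec.well_radius_um
        L = spec.channel_length_um
        gap = spec.well_gap_um if spec.well_gap_um is not None else L
        w = spec.channel_width_um
        cy = m + max(r, w / 2)
        height = 2 * cy
        x_left = m + r
        x_right = x_left + 2 * r + gap
        width = x_right + r + m
        shapes: list[Shape] = [
            Disc(x_left, cy, r),
            Disc(x_right, cy, r),
        ]
        if L > 0:
            shapes.append(
                Rect(x_left + r, cy - w / 2, x_left + r + L, cy + w / 2)
            )
        return shapes, width, height
    if spec.kind == "radial":
        R = spec.chamber_radius_um
        L = spec.channel_length_um
        w = spec.channel_width_um
        rw = spec.well_radius_um
        extent = R + L + 2 * rw + m
        cx = cy = extent
        shapes = [Disc(cx, cy, R)]
        for i in range(spec.n_channels):
            theta = 2 * math.pi * i / spec.n_channels
            shapes.append(OrientedRect(cx, cy, theta, R + L, w / 2))
            shapes.append(
                Disc(
                    cx + (R + L + rw) * math.cos(theta),
                    cy + (R + L + rw) * math.sin(theta),
                    rw,
                )
            )
        return shapes, 2 * extent, 2 * extent
    if spec.kind == "multi_chamber":
        W, H = spec.chamber_width_um, spec.chamber_height_um
        w = spec.channel_width_um
        g = spec.connector_length_um
        r = spec.well_radius_um
        n = spec.n_chambers
        cy = m + H + g + w / 2  # central channel axis
        height = 2 * cy
        # chambers spread evenly along the channel between the wells
        span = n * W + (n + 1) * W / 2
        x_left = m + r
        x_right = x_left + 2 * r + span
        width = x_right + r + m
        shapes = [
            Disc(x_left, cy, r),
            Disc(x_right, cy, r),
            Rect(x_left + r, cy - w / 2, x_right - r, cy + w / 2),
        ]
        for i in range(n):
            x0 = x_left + r + W / 2 * (i + 1) + W * i
            for sign in (-1, 1):
                y_near = cy + sign * w / 2
                y_far = cy + sign * (w / 2 + g + H)
                shapes.append(
                    Rect(
                        x0 + W / 2 - w / 4,
                        min(y_near, y_near + sign * g),
                        x0 + W / 2 + w / 4,
                        max(y_near, y_near + sign * g),
                    )
                )
                shapes.append(
                    Rect(x0, min(y_near + sign * g, y_far), x0 + W, max(y_near + sign * g, y_far))
                )
        return shapes, width, height
    # custom: bounding box of the given shapes plus margin
    xs: list[float] = []
    ys: list[float] = []
    for sh in spec.shapes:
        if isinstance(sh, Disc):
            xs += [sh.cx - sh.r, sh.cx + sh.r]
            ys += [sh.cy - sh.r, sh.cy + sh.r]
        elif isinstance(sh, Rect):
            xs += [sh.x0, sh.x1]
            ys += [sh.y0, sh.y1]
        else:
            reach = sh.length + sh.half_width
            xs += [sh.cx - reach, sh.cx + reach]
            ys += [sh.cy - reach, sh.cy + reach]
    dx, dy = -min(xs) + spec.margin_um, -min(ys) + spec.margin_um
    shifted = [_shift_shape(sh, dx, dy) for sh in spec.shapes]
    width = max(xs) - min(xs) + 2 * spec.margin_um
    height = max(ys) - min(ys) + 2 * spec.margin_um
    return shifted, width, height


def _shift_shape(sh: Shape, dx: float, dy: float) -> Shape:
    if isinstance(sh, Disc):
        return replace(sh, cx=sh.cx + dx, cy=sh.cy + dy)
    if isinstance(sh, Rect):
        return Rect(sh.x0 + dx, sh.y0 + dy, sh.x1 + dx, sh.y1 + dy)
    return replace(sh, cx=sh.cx + dx, cy=sh.cy + dy)


def make_device(spec: DeviceSpec, warn_disconnected: bool = True) -> DeviceMask:
    """Rasterize a :class:`DeviceSpec` into a mask.

    A pixel is allowed iff its center lies inside the union of the spec's
    shapes.  If the allowed set rasterizes to more than one 4-connected
    component a :class:`GeometryWarning` is issued (not fatal: some layouts
    are legitimately disconnected).
    """
    shapes, width_um, height_um = device_shapes(spec)
    px = spec.pixel_size_um
    n_cols = max(1, int(math.ceil(width_um / px)))
    n_rows = max(1, int(math.ceil(height_um / px)))
    cols = (np.arange(n_cols) + 0.5) * px
    rows = (np.arange(n_rows) + 0.5) * px
    X, Y = np.meshgrid(cols, rows)
    allowed = np.zeros((n_rows, n_cols), dtype=bool)
    for sh in shapes:
        allowed |= sh.contains(X, Y)
    if not allowed.any():
        raise GeometryError("device rasterized to zero allowed pixels")
    mask = DeviceMask(allowed=allowed, pixel_size_um=px)
    if warn_disconnected:
        _, sizes = connected_components(mask)
        if len(sizes) > 1:
            warnings.warn(
                f"device rasterized to {len(sizes)} disconnected regions "
                f"(sizes {sizes})",
                GeometryWarning,
                stacklevel=2,
            )
    return mask
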