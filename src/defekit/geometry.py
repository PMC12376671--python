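"""Pixel-to-millimetre optical calibration and frame-timestamp handling.

The camera looks down into the bowl, so an object of fixed physical width
spans fewer pixels the farther it is from the lens.  Two equivalent routes
convert a detected pixel width to millimetres:

* the **pinhole chain** — from the camera's horizontal field of view and
  the measured camera-to-stool distance ``d``, the real-world width
  spanned by the full image is ``D_hor = 2 d tan(FOV/2)``, and an object
  of ``P_stool`` pixels is ``D_hor * P_stool / P_img`` millimetres wide;
* the **transformation coefficient** — a fitted power law
  ``y(x) = a (b x^c + 1)`` giving the mm-per-pixel factor as a function
  of ``x``, the vertical pixel count from the *bottom* of the image to
  the stool's dropping location.  Stool thickness in millimetres is then
  ``T = y(x) * P_stool``.

The default coefficient constants ``(a, b, c) = (0.092840, 0.000037,
1.497)`` are read in grouped form, ``a * (b x^c + 1)``: only that reading
produces mm-per-pixel magnitudes (0.09-0.25 over the bowl) consistent
with the pinhole chain at the three calibrated drop distances.  The
ungrouped literal reading is available as a formula variant.

Detection rows are counted from the image *top* (the convention of the
detection stream); ``x`` is counted from the image *bottom*.  The module
carries the ``x = image_height - row`` conversion explicitly.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .errors import (
    DegenerateFitError,
    IncompleteDropError,
    StreamOrderError,
    TimestampParseError,
)
from .records import DROPPED, DROPPING, StoolDetection

__all__ = [
    "CalibrationModel",
    "DEFAULT_COEFF",
    "parse_timestamp",
    "format_timestamp",
    "horizontal_extent",
    "stool_width_mm_pinhole",
    "transform_coefficient",
    "thickness_mm",
    "x_from_row",
    "row_from_x",
    "calibration_x_for_distance",
    "fit_coefficient",
    "dropping_duration",
]

#: Fitted power-law constants (a, b, c) of the transformation coefficient.
DEFAULT_COEFF: tuple[float, float, float] = (0.092840, 0.000037, 1.497)

_TIMESTAMP_RE = re.compile(r"^(\d{2})(\d{2})(\d{2})\.(\d{4})(?:\.[A-Za-z0-9]+)?$")


@dataclass(frozen=True)
class CalibrationModel:
    """Geometry of the in-bowl camera and its fitted pixel→mm conversion.

    Parameters
    ----------
    fov_hor : float
        Horizontal field of view in radians (default: 66 degrees, the
        public specification of the camera module used).
    image_width_px, image_height_px : int
        Sensor resolution (default 2304 x 2592, portrait orientation).
    distances_mm : dict
        Camera-to-stool distance for the three habitual drop locations.
    coeff : tuple
        Power-law constants (a, b, c) of the transformation coefficient.
    waterline_row : int
        Image row (from the top) of the water surface; detections above
        it are *dropping*, at/below it *dropped*.
    variant : str
        ``"grouped"`` -> y = a (b x^c + 1); ``"literal"`` -> y = a b x^c + 1.
    """

    fov_hor: float = math.radians(66.0)
    image_width_px: int = 2304
    image_height_px: int = 2592
    distances_mm: dict[str, float] = field(
        default_factory=lambda: {"rear": 193.0, "center": 237.0, "front": 290.0}
    )
    coeff: tuple[float, float, float] = DEFAULT_COEFF
    waterline_row: int = 1300
    variant: str = "grouped"

    def __post_init__(self) -> None:
        if not 0.0 < self.fov_hor < math.pi:
            raise ValueError("fov_hor must lie in (0, pi) radians")
        if any(d <= 0 for d in self.distances_mm.values()):
            raise ValueError("all camera-to-stool distances must be positive")
        if not 0 < self.waterline_row < self.image_height_px:
            raise ValueError("waterline_row must lie inside the image")
        a, b, c = self.coeff
        if a <= 0 or b <= 0 or c <= 0:
            raise ValueError("coefficient constants a, b, c must be positive")
        if self.variant not in ("grouped", "literal"):
            raise ValueError(f"unknown formula variant {self.variant!r}")

    # -- convenience -------------------------------------------------------

    def mm_per_px_pinhole(self, d_mm: float) -> float:
        """Pinhole-chain mm-per-pixel factor at camera distance ``d_mm``."""
        return horizontal_extent(d_mm, self.fov_hor) / self.image_width_px

    def to_dict(self) -> dict:
        return {
            "fov_hor_deg": math.degrees(self.fov_hor),
            "image_width_px": self.image_width_px,
            "image_height_px": self.image_height_px,
            "distances_mm": dict(self.distances_mm),
            "coeff": {"a": self.coeff[0], "b": self.coeff[1], "c": self.coeff[2]},
            "waterline_row": self.waterline_row,
            "variant": self.variant,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CalibrationModel":
        kwargs = {}
        if "fov_hor_deg" in data:
            kwargs["fov_hor"] = math.radians(float(data["fov_hor_deg"]))
        for key in ("image_width_px", "image_height_px", "waterline_row"):
            if key in data:
                kwargs[key] = int(data[key])
        if "distances_mm" in data:
            kwargs["distances_mm"] = {k: float(v) for k, v in data["distances_mm"].items()}
        if "coeff" in data:
            c = data["coeff"]
            kwargs["coeff"] = (float(c["a"]), float(c["b"]), float(c["c"]))
        if "variant" in data:
            kwargs["variant"] = str(data["variant"])
        return cls(**kwargs)

    def with_(self, **kwargs) -> "CalibrationModel":
        return replace(self, **kwargs)


# -- timestamps ------------------------------------------------------------


def parse_timestamp(frame_name: str) -> float:
    """Seconds of day encoded in an ``hhmmss.ssss`` frame filename.

    ``"135958.5042.jpeg"`` -> ``50398.5042`` (13:59:58.5042).  An optional
    extension after the fractional part is ignored.
    """
    m = _TIMESTAMP_RE.match(frame_name)
    if m is None:
        raise TimestampParseError(f"not an hhmmss.ssss frame name: {frame_name!r}")
    hh, mm, ss, frac = m.groups()
    h, mi, s = int(hh), int(mm), int(ss)
    if h > 23 or mi > 59 or s > 59:
        raise TimestampParseError(f"invalid time of day in {frame_name!r}")
    return h * 3600 + mi * 60 + s + int(frac) / 10000.0


def format_timestamp(time_s: float, extension: str = "") -> str:
    """Inverse of :func:`parse_timestamp` (round-trips on the valid domain)."""
    if not 0.0 <= time_s < 86400.0:
        raise ValueError(f"time_s must lie in [0, 86400), got {time_s}")
    total = round(time_s * 10000)
    frac = total % 10000
    seconds = total // 10000
    h, rem = divmod(seconds, 3600)
    mi, s = divmod(rem, 60)
    name = f"{h:02d}{mi:02d}{s:02d}.{frac:04d}"
    return name + extension


# -- pinhole chain ---------------------------------------------------------


def horizontal_extent(d_mm: float, fov_hor: float) -> float:
    """Real-world width (mm) covered by the full image at distance ``d_mm``."""
    if d_mm < 0:
        raise ValueError("distance must be >= 0")
    if not 0.0 <= fov_hor < math.pi:
        raise ValueError("fov_hor must lie in [0, pi) radians")
    return 2.0 * d_mm * math.tan(fov_hor / 2.0)


def stool_width_mm_pinhole(
    p_stool: float, p_img: int, d_mm: float, fov_hor: float
) -> float:
    """Stool width in mm from its pixel width via the pinhole chain."""
    if p_img <= 0:
        raise ValueError("image width must be positive")
    if not 0 <= p_stool <= p_img:
        raise ValueError("stool pixel width must lie in [0, image width]")
    return horizontal_extent(d_mm, fov_hor) * p_stool / p_img


# -- transformation coefficient --------------------------------------------


def transform_coefficient(
    x: float,
    coeff: tuple[float, float, float] = DEFAULT_COEFF,
    variant: str = "grouped",
) -> float:
    """mm-per-pixel factor at vertical pixel count ``x`` from the image bottom.

    Grouped reading (default): ``a * (b * x**c + 1)``; strictly increasing
    in ``x`` for positive constants.  The literal reading ``a*b*x**c + 1``
    is retained as a variant for comparison.
    """
    if x < 0:
        raise ValueError("x (pixels from image bottom) must be >= 0")
    a, b, c = coeff
    if variant == "grouped":
        return a * (b * x**c + 1.0)
    if variant == "literal":
        return a * b * x**c + 1.0
    raise ValueError(f"unknown formula variant {variant!r}")


def thickness_mm(p_stool: float, x: float, model: CalibrationModel | None = None) -> float:
    """Stool thickness in mm: transformation coefficient at ``x`` times pixels."""
    if p_stool < 0:
        raise ValueError("stool pixel width must be >= 0")
    model = model if model is not None else CalibrationModel()
    return transform_coefficient(x, model.coeff, model.variant) * p_stool


def x_from_row(pixel_row: int, model: CalibrationModel) -> float:
    """Convert a row counted from the image top to pixels from the bottom."""
    if not 0 <= pixel_row <= model.image_height_px:
        raise ValueError("pixel_row outside the image")
    return float(model.image_height_px - pixel_row)


def row_from_x(x: float, model: CalibrationModel) -> int:
    if not 0 <= x <= model.image_height_px:
        raise ValueError("x outside the image")
    return int(round(model.image_height_px - x))


def calibration_x_for_distance(d_mm: float, model: CalibrationModel | None = None) -> float:
    """Invert the coefficient: the ``x`` at which the fitted mm-per-pixel
    factor equals the pinhole-chain factor for camera distance ``d_mm``.

    This ties the two conversion routes together and locates the image
    height of each calibrated drop position.
    """
    model = model if model is not None else CalibrationModel()
    target = model.mm_per_px_pinhole(d_mm)
    a, b, c = model.coeff
    if model.variant == "grouped":
        xc = (target / a - 1.0) / b
    else:  # literal: y = a b x^c + 1
        xc = (target - 1.0) / (a * b)
    if xc <= 0:
        raise ValueError(
            f"pinhole factor {target:.5f} mm/px unreachable by the fitted coefficient"
        )
    return xc ** (1.0 / c)


def fit_coefficient(
    calibration_points: list[tuple[float, float]],
) -> tuple[tuple[float, float, float], float]:
    """Least-squares fit of ``y = a (b x^c + 1)`` to (x, mm-per-px) points.

    Returns ``((a, b, c), residual_norm)``.  Needs at least three points
    with distinct x.  On noiseless synthetic input generated from the
    model family the generating constants are recovered.
    """
    pts = sorted(set((float(x), float(y)) for x, y in calibration_points))
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if len(np.unique(xs)) < 3:
        raise DegenerateFitError("need >= 3 calibration points with distinct x")
    if np.any(ys <= 0):
        raise DegenerateFitError("mm-per-pixel factors must be positive")

    def model(x, a, b, c):
        return a * (b * np.power(x, c) + 1.0)

    # Initial guesses: a ~ the intercept (factor at x -> 0); b, c from a
    # log-linear fit of y/a - 1 against x.
    a0 = min(ys.min() * 0.95, ys.min() - 1e-6)
    if a0 <= 0:
        a0 = ys.min() * 0.5
    with np.errstate(invalid="ignore", divide="ignore"):
        z = ys / a0 - 1.0
        mask = (z > 0) & (xs > 0)
        if mask.sum() >= 2:
            slope, intercept = np.polyfit(np.log(xs[mask]), np.log(z[mask]), 1)
            c0 = float(np.clip(slope, 0.1, 5.0))
            b0 = float(np.exp(intercept))
        else:
            b0, c0 = 1e-4, 1.5
    try:
        import warnings

        with warnings.catch_warnings():
            # an exactly-determined 3-point fit has no covariance estimate
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model,
                xs,
                ys,
                p0=(a0, b0, c0),
                bounds=([1e-12, 1e-12, 1e-3], [np.inf, np.inf, 10.0]),
                maxfev=20000,
            )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise DegenerateFitError(f"coefficient fit failed: {exc}") from exc
    residual = float(np.linalg.norm(model(xs, *popt) - ys))
    return (float(popt[0]), float(popt[1]), float(popt[2])), residual


# -- dropping duration -----------------------------------------------------


def dropping_duration(
    detections: list[tuple[float, StoolDetection]],
    waterline_row: int = 1300,
) -> float:
    """Stool-dropping duration of one drop episode.

    ``detections`` is the episode's time-ordered ``(time_s, detection)``
    sequence.  The duration is the time gap between the first detection
    in the dropping region (above the waterline) and the first in the
    dropped region (at/below it); zero when both fall in the same frame.
    """
    t_dropping = None
    t_dropped = None
    for t, det in detections:
        tag = det.filter_tag or (DROPPING if det.pixel_row < waterline_row else DROPPED)
        if tag == DROPPING and t_dropping is None:
            t_dropping = t
        elif tag == DROPPED and t_dropped is None:
            t_dropped = t
    if t_dropping is None or t_dropped is None:
        missing = "dropping" if t_dropping is None else "dropped"
        raise IncompleteDropError(f"episode has no {missing}-filter detection")
    if t_dropped < t_dropping:
        raise StreamOrderError(
            f"dropped detection at {t_dropped} precedes dropping at {t_dropping}"
        )
    return t_dropped - t_dropping
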