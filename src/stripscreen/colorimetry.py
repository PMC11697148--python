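"""Color-space feature extraction for colorimetric test-strip images.

A strip region-of-interest (ROI) arrives as an 8-bit RGB pixel grid. Each
pixel is re-expressed in the four dominant color models — RGB, HSV, YCbCr
and CIELAB — giving 12 per-pixel channels, and each channel is reduced to
six summary statistics (minimum, maximum, mean, standard deviation, range,
median). Every image is therefore described by 72 named variables, plus one
extra scalar used for the longitudinal trajectories: the *combined minimum
RGB value*, the per-pixel mean of (R, G, B) minimised over the strip, i.e.
the darkest (most saliva-saturated) point of the strip.

Conventions
-----------
* HSV: standard hexcone conversion on channels scaled to [0, 1]; hue is
  reported in degrees [0, 360). Achromatic pixels (max = min) have no
  defined hue; they carry H = 0 and are flagged degenerate.
* YCbCr: full-range ITU-R BT.601 (the JPEG/JFIF convention) — the dialect
  consumer smartphone imagery uses. Values stay at floating precision.
* CIELAB: sRGB inverse companding, the published IEC 61966-2-1 sRGB→XYZ
  matrix, D65 white point, 2° observer.
* Standard deviation uses the sample (n−1) denominator; a single-pixel
  image has sd defined as 0. The median uses the midpoint convention.
* Hue is summarised linearly like every other channel (no circular
  statistics); degenerate-hue pixels contribute 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from skimage import color as _skcolor

__all__ = [
    "CHANNELS",
    "SUMMARIES",
    "FEATURE_SCHEMA",
    "StripImage",
    "ChannelStack",
    "rgb_to_hsv",
    "rgb_to_ycbcr",
    "rgb_to_cielab",
    "extract_channels",
    "summarize_channels",
    "combined_rgb_value",
    "extract_features",
    "extract_features_batch",
    "load_strip_png",
    "extract_cohort_features",
]

#: The 12 per-pixel channels, in fixed schema order (grouped by color model).
CHANNELS = ("R", "G", "B", "H", "S", "V", "Y", "Cb", "Cr", "Lstar", "astar", "bstar")

#: The six summary statistics applied to every channel.
SUMMARIES = ("min", "max", "mean", "sd", "range", "median")

#: The fixed, documented 72-variable feature schema (channel-major order).
FEATURE_SCHEMA = tuple(f"{ch}_{s}" for ch in CHANNELS for s in SUMMARIES)

#: Name of the extra trajectory scalar carried alongside the 72 features.
COMBINED_RGB_COLUMN = "combined_rgb_min"

# Published sRGB → XYZ (D65, 2° observer) matrix, IEC 61966-2-1.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
# D65 reference white = row sums of the matrix above (exact for this matrix).
_WHITE_D65 = _SRGB_TO_XYZ.sum(axis=1)

# Full-range BT.601 RGB → YCbCr matrix (JPEG/JFIF convention).
_RGB_TO_YCBCR = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168735892, -0.331264108, 0.5],
        [0.5, -0.418687589, -0.081312411],
    ]
)
_YCBCR_OFFSET = np.array([0.0, 128.0, 128.0])


def _validate_rgb(rgb: np.ndarray) -> np.ndarray:
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("expected RGB input with a trailing axis of length 3")
    if not np.isfinite(arr).all():
        raise ValueError("RGB channels must be finite")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB channels must lie in [0, 255]")
    return arr


def rgb_to_hsv(rgb):
    """Convert 8-bit RGB to (H, S, V).

    Parameters
    ----------
    rgb : array_like, shape (..., 3)
        Channel values in [0, 255].

    Returns
    -------
    H : ndarray
        Hue in degrees, [0, 360). Achromatic pixels return 0.
    S, V : ndarray
        Saturation and value in [0, 1].
    """
    arr = _validate_rgb(rgb)
    hsv = _skcolor.rgb2hsv(arr / 255.0)
    return hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2]


def rgb_to_ycbcr(rgb):
    """Convert 8-bit RGB to full-range BT.601 (Y, Cb, Cr).

    Y = 0.299 R + 0.587 G + 0.114 B; Cb and Cr carry a +128 offset.
    Results are clipped to [0, 255] and kept at floating precision.
    """
    arr = _validate_rgb(rgb)
    ycc = arr @ _RGB_TO_YCBCR.T + _YCBCR_OFFSET
    ycc = np.clip(ycc, 0.0, 255.0)
    return ycc[..., 0], ycc[..., 1], ycc[..., 2]


def rgb_to_cielab(rgb):
    """Convert 8-bit RGB to CIELAB (L*, a*, b*), sRGB / D65 / 2° observer.

    The path is sRGB inverse companding → linear RGB → XYZ → Lab with the
    standard cube-root / linear-segment lightness function.
    """
    arr = _validate_rgb(rgb) / 255.0
    lin = np.where(arr <= 0.04045, arr / 12.92, ((arr + 0.055) / 1.055) ** 2.4)
    xyz = lin @ _SRGB_TO_XYZ.T
    t = xyz / _WHITE_D65
    delta = 6.0 / 29.0
    f = np.where(t > delta**3, np.cbrt(t), t / (3.0 * delta * delta) + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return L, a, b


@dataclass
class StripImage:
    """One strip ROI: an H×W grid of 8-bit RGB pixels tied to a test."""

    pixels: np.ndarray  # (H, W, 3) uint8
    participant_id: str | None = None
    week: int | None = None

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim != 3 or arr.shape[-1] != 3 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("strip image must be an H×W×3 grid with H, W >= 1")
        _validate_rgb(arr)
        self.pixels = arr.astype(np.uint8)


@dataclass
class ChannelStack:
    """Per-pixel values of the 12 channels for one image.

    ``data`` has shape (H, W, 12) in :data:`CHANNELS` order.
    ``hue_degenerate`` marks achromatic pixels whose hue is undefined
    (carried as H = 0).
    """

    data: np.ndarray
    hue_degenerate: np.ndarray
    participant_id: str | None = None
    week: int | None = None
    channels: tuple = field(default=CHANNELS)

    def channel(self, name: str) -> np.ndarray:
        return self.data[..., CHANNELS.index(name)]


def _channels_from_array(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """12-channel stack for an (..., H, W, 3) float array in [0, 255]."""
    h, s, v = rgb_to_hsv(arr)
    y, cb, cr = rgb_to_ycbcr(arr)
    L, a, b = rgb_to_cielab(arr)
    data = np.stack(
        [arr[..., 0], arr[..., 1], arr[..., 2], h, s, v, y, cb, cr, L, a, b],
        axis=-1,
    )
    degenerate = arr.max(axis=-1) == arr.min(axis=-1)
    return data, degenerate


def extract_channels(image: StripImage | np.ndarray) -> ChannelStack:
    """Apply the three conversions pixel-wise and stack with raw R, G, B."""
    if isinstance(image, StripImage):
        arr, pid, week = image.pixels.astype(float), image.participant_id, image.week
    else:
        arr, pid, week = _validate_rgb(image), None, None
        if arr.ndim != 3:
            raise ValueError("expected an H×W×3 image")
    data, degenerate = _channels_from_array(arr)
    return ChannelStack(data=data, hue_degenerate=degenerate, participant_id=pid, week=week)


def _summarize_block(data: np.ndarray, axis) -> dict[str, np.ndarray]:
    n = int(np.prod([data.shape[ax] for ax in axis]))
    mn = data.min(axis=axis)
    mx = data.max(axis=axis)
    out = {
        "min": mn,
        "max": mx,
        "mean": data.mean(axis=axis),
        # sample sd (n-1); a single pixel has sd defined as 0
        "sd": data.std(axis=axis, ddof=1) if n > 1 else np.zeros_like(mn),
        "range": mx - mn,
        "median": np.median(data, axis=axis),
    }
    return out


def summarize_channels(stack: ChannelStack) -> pd.Series:
    """Reduce a channel stack to the 72-variable feature vector.

    Returns a Series indexed by :data:`FEATURE_SCHEMA`, with
    ``participant_id`` and ``week`` attached via ``.attrs`` when known.
    """
    data = np.asarray(stack.data, dtype=float)
    if data.size == 0:
        raise ValueError("cannot summarize an empty pixel set")
    stats = _summarize_block(data, axis=(0, 1))
    values = {
        f"{ch}_{s}": float(stats[s][i])
        for i, ch in enumerate(CHANNELS)
        for s in SUMMARIES
    }
    out = pd.Series(values).reindex(list(FEATURE_SCHEMA))
    out.attrs["participant_id"] = stack.participant_id
    out.attrs["week"] = stack.week
    return out


def combined_rgb_value(image: StripImage | np.ndarray) -> float:
    """Minimum over pixels of the per-pixel mean of (R, G, B).

    This is the darkest point of the strip — the region most saturated with
    saliva — and is the scalar tracked longitudinally per test.
    """
    arr = image.pixels if isinstance(image, StripImage) else np.asarray(image)
    arr = _validate_rgb(arr)
    if arr.size == 0:
        raise ValueError("cannot compute the combined RGB value of an empty image")
    return float(arr.mean(axis=-1).min())


def extract_features(image: StripImage | np.ndarray,
                     participant_id: str | None = None,
                     week: int | None = None) -> pd.Series:
    """72 features plus the combined minimum RGB value for one image."""
    if isinstance(image, StripImage):
        participant_id = participant_id or image.participant_id
        week = week if week is not None else image.week
    feats = summarize_channels(extract_channels(image))
    feats[COMBINED_RGB_COLUMN] = combined_rgb_value(image)
    feats.attrs["participant_id"] = participant_id
    feats.attrs["week"] = week
    return feats


def extract_features_batch(images: np.ndarray,
                           participant_ids,
                           weeks) -> pd.DataFrame:
    """Vectorised extraction for a batch of same-size images.

    Parameters
    ----------
    images : ndarray, shape (N, H, W, 3)
        8-bit RGB images.
    participant_ids, weeks : sequences of length N

    Returns
    -------
    DataFrame with columns participant_id, week, the 72 features and
    ``combined_rgb_min`` — identical (to floating precision) to calling
    :func:`extract_features` image by image.
    """
    arr = _validate_rgb(images)
    if arr.ndim != 4:
        raise ValueError("expected a batch of shape (N, H, W, 3)")
    n = arr.shape[0]
    data, _ = _channels_from_array(arr)  # (N, H, W, 12)
    stats = _summarize_block(data.reshape(n, -1, 12), axis=(1,))
    cols = {"participant_id": list(participant_ids), "week": list(weeks)}
    for i, ch in enumerate(CHANNELS):
        for s in SUMMARIES:
            cols[f"{ch}_{s}"] = stats[s][:, i]
    cols[COMBINED_RGB_COLUMN] = arr.mean(axis=-1).reshape(n, -1).min(axis=1)
    return pd.DataFrame(cols)


def load_strip_png(path) -> np.ndarray:
    """Read an 8-bit RGB PNG strip ROI. Images with an alpha channel are
    rejected rather than silently flattened."""
    with Image.open(path) as im:
        if im.mode == "RGBA" or "A" in im.getbands():
            raise ValueError(f"{path}: alpha channel not supported; provide plain RGB")
        if im.mode != "RGB":
            raise ValueError(f"{path}: expected an RGB image, got mode {im.mode}")
        return np.asarray(im, dtype=np.uint8)


def extract_cohort_features(images_dir, testlog: pd.DataFrame) -> pd.DataFrame:
    """Extract the feature table for every submitted test in a test log.

    ``testlog`` needs columns participant_id, week, submitted, image_path;
    rows with ``submitted == False`` are skipped. Returns one row per test:
    participant_id, week, the 72 schema features and combined_rgb_min.
    """
    from pathlib import Path

    images_dir = Path(images_dir)
    rows = []
    for rec in testlog.itertuples(index=False):
        if not rec.submitted:
            continue
        img = load_strip_png(images_dir / rec.image_path)
        feats = extract_features(img, participant_id=rec.participant_id, week=int(rec.week))
        row = {"participant_id": rec.participant_id, "week": int(rec.week)}
        row.update(feats.to_dict())
        rows.append(row)
    columns = ["participant_id", "week", *FEATURE_SCHEMA, COMBINED_RGB_COLUMN]
    return pd.DataFrame(rows, columns=columns)
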