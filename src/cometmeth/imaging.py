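"""Synthetic comet images and a tail-intensity scorer.

A comet is rendered as an isotropic 2-D Gaussian *head* plus an
exponentially decaying *tail* band extending toward increasing column
index (+x, the anode side — a fixed convention both the generator and the
scorer assume).  The generator records the exact fraction of total signal
placed in the tail, so the scorer can be validated against ground truth;
the scorer itself never sees it.

Scoring contract: tail intensity is the percentage of the comet's
background-subtracted signal that lies beyond the head — outside a disk of
radius ``k * FWHM`` around the head centre and at columns past it.  Head%
and tail% sum to 100 by construction.

Pixel conventions: 0-based, row-major, origin top-left (as stored in
TIFF); ``pixels[row, col]``.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage import measure, morphology

from .exceptions import GeometryError, ParameterError, UnscorableImageError

__all__ = [
    "CometImage",
    "CometScore",
    "simulate_comet_image",
    "score_comet",
    "save_comet_tiff",
    "load_comet_tiff",
    "score_directory",
]


@dataclass
class CometImage:
    """A single-comet grayscale image with optional ground truth."""

    pixels: np.ndarray
    pixel_size: float = 1.0
    truth_tail_fraction: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ParameterError("pixels must be a 2-D array")
        if np.any(self.pixels < 0):
            raise ParameterError("pixel values must be non-negative")
        if self.truth_tail_fraction is not None and not (
                0.0 <= self.truth_tail_fraction <= 1.0):
            raise ParameterError("truth_tail_fraction must lie in [0, 1]")


@dataclass
class CometScore:
    """Scorer output for one comet.  head_pct + tail_intensity == 100."""

    tail_intensity: float
    head_pct: float
    head_center: tuple[float, float]  # (row, col)
    head_radius: float
    background: float
    total_signal: float
    comet_mask: np.ndarray
    head_mask: np.ndarray
    tail_mask: np.ndarray


def simulate_comet_image(tail_fraction: float,
                         head_sigma: float = 2.0,
                         tail_length: float = 500.0,
                         total_signal: float = 1e5,
                         noise_model: str = "none",
                         noise_sd: float = 0.0,
                         size: tuple[int, int] = (64, 3072),
                         head_col: int | None = None,
                         seed: int | None = None) -> CometImage:
    """Render one synthetic comet with a known tail fraction.

    Parameters
    ----------
    tail_fraction : float
        Fraction of total signal placed in the tail (0-1); the ground
        truth the scorer is judged against.
    head_sigma : float
        SD of the isotropic head Gaussian, pixels; the tail band shares
        this vertical profile.
    tail_length : float
        Decay length of the exponential tail along +x, pixels.  The frame
        must hold at least three decay lengths past the head centre.
    total_signal : float
        Total rendered counts; 0 produces a blank (unscorable) image.
    noise_model : {"none", "poisson", "gaussian"}
        Applied after rendering; ``gaussian`` uses ``noise_sd`` counts,
        clipped at zero.
    size : (rows, cols)
        Frame shape.
    head_col : int, optional
        Head centre column (default ``4 * head_sigma + 8``); the head
        row is the frame's middle row.
    seed : int, optional
        RNG seed for the noise draw (recorded on the image).

    The rendered head and tail masses are normalised within the frame so
    that the in-frame tail mass is exactly ``tail_fraction * total_signal``
    before noise.
    """
    if not (0.0 <= tail_fraction <= 1.0):
        raise ParameterError(f"tail_fraction must lie in [0, 1], got {tail_fraction!r}")
    if head_sigma <= 0 or tail_length <= 0:
        raise ParameterError("head_sigma and tail_length must be > 0")
    if total_signal < 0:
        raise ParameterError("total_signal must be >= 0")
    rows, cols = size
    if head_col is None:
        head_col = int(round(4 * head_sigma)) + 8
    head_row = rows // 2
    margin = 4.0 * head_sigma
    if (head_row - margin < 0 or head_row + margin > rows - 1
            or head_col - margin < 0 or head_col + margin > cols - 1):
        raise GeometryError("head does not fit inside the frame")
    if cols - 1 - head_col < 3.0 * tail_length:
        raise GeometryError(
            f"tail (3 x {tail_length} px) does not fit in the "
            f"{cols - 1 - head_col} px past the head centre")

    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    img = np.zeros((rows, cols), dtype=float)

    head_mass = total_signal * (1.0 - tail_fraction)
    if head_mass > 0:
        g = np.exp(-((rr - head_row) ** 2 + (cc - head_col) ** 2)
                   / (2.0 * head_sigma ** 2))
        img += g * (head_mass / g.sum())

    tail_mass = total_signal * tail_fraction
    if tail_mass > 0:
        x = cc - head_col
        band = np.where(x >= 0, np.exp(-np.maximum(x, 0) / tail_length), 0.0)
        band = band * np.exp(-((rr - head_row) ** 2) / (2.0 * head_sigma ** 2))
        img += band * (tail_mass / band.sum())

    rng = np.random.default_rng(seed)
    if noise_model == "poisson":
        img = rng.poisson(img).astype(float)
    elif noise_model == "gaussian":
        img = np.clip(img + rng.normal(0.0, noise_sd, size=img.shape), 0.0, None)
    elif noise_model != "none":
        raise ParameterError(f"unknown noise_model {noise_model!r}")

    return CometImage(pixels=img, truth_tail_fraction=tail_fraction, seed=seed)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _corner_background(img: np.ndarray, frac: float = 0.1,
                       min_px: int = 4) -> tuple[float, float]:
    """Median and robust SD of the four corner patches."""
    r = max(min_px, int(frac * img.shape[0]))
    c = max(min_px, int(frac * img.shape[1]))
    patches = np.concatenate([
        img[:r, :c].ravel(), img[:r, -c:].ravel(),
        img[-r:, :c].ravel(), img[-r:, -c:].ravel()])
    med = float(np.median(patches))
    # 1.4826 * MAD: robust to a tail sneaking into a corner
    sd = float(1.4826 * np.median(np.abs(patches - med)))
    return med, sd


def _gauss1d(x, amp, mu, sigma):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2))


def _head_geometry(img: np.ndarray, comet: np.ndarray, policy: str
                   ) -> tuple[float, float, float]:
    """Locate the head centre (row, col) and estimate its Gaussian sigma.

    The vertical profile through the head is head-dominated (the tail
    shares at most its width), so sigma comes from the rows; the column
    centre uses only columns at or left of the peak, which the tail never
    reaches.
    """
    smooth = ndimage.gaussian_filter(np.where(comet, img, 0.0), 1.0)
    head_row, head_col = np.unravel_index(int(np.argmax(smooth)), img.shape)

    strip = np.where(comet, img, 0.0)[:, max(head_col - 1, 0):head_col + 2]
    vprof = strip.sum(axis=1)
    rows = np.arange(img.shape[0], dtype=float)
    w = np.clip(vprof, 0.0, None)
    if w.sum() <= 0:
        raise UnscorableImageError("empty head profile")
    mu_r = float((rows * w).sum() / w.sum())
    sigma = float(np.sqrt(((rows - mu_r) ** 2 * w).sum() / w.sum()))
    sigma = max(sigma, 0.5)

    if policy == "brightest-disk":
        return float(head_row), float(head_col), sigma
    if policy != "fit-gaussian":
        raise ParameterError(f"unknown head_policy {policy!r}")

    # refine by least-squares Gaussian fits to the two 1-D profiles
    try:
        popt, _ = curve_fit(_gauss1d, rows, vprof,
                            p0=(vprof.max(), mu_r, sigma), maxfev=2000)
        mu_r, sigma = float(popt[1]), abs(float(popt[2]))
    except RuntimeError:
        pass
    left = np.where(comet, img, 0.0)[:, :head_col + 1].sum(axis=0)
    colx = np.arange(left.size, dtype=float)
    try:
        popt, _ = curve_fit(_gauss1d, colx, left,
                            p0=(left.max(), head_col, sigma), maxfev=2000)
        head_col_f = float(popt[1])
    except RuntimeError:
        head_col_f = float(head_col)
    return mu_r, head_col_f, max(sigma, 0.5)


def score_comet(image: CometImage,
                background_policy="corner-median",
                head_policy: str = "brightest-disk",
                k_head: float = 1.5) -> CometScore:
    """Score one comet image into a tail-intensity percentage.

    Steps: subtract background (corner-patch median, or a fixed value);
    threshold and take the largest connected above-background component;
    locate the head per ``head_policy``; the head region is a disk of
    radius ``k_head * FWHM`` around the head centre; everything in the
    component past the head-centre column and outside that disk is tail.

    Returns a :class:`CometScore`; deterministic for a given image.
    """
    img = image.pixels
    if background_policy == "corner-median":
        bg, noise_sd = _corner_background(img)
    else:
        bg, noise_sd = float(background_policy), 0.0
    sub = np.clip(img - bg, 0.0, None)
    peak = float(sub.max())
    if peak <= 0:
        raise UnscorableImageError("blank image: no signal above background")

    threshold = max(2.0 * noise_sd, 1e-4 * peak)
    mask = sub > threshold
    mask = morphology.closing(mask, morphology.disk(1))
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise UnscorableImageError("no connected object above background")
    masses = ndimage.sum_labels(sub, labels, index=np.arange(1, labels.max() + 1))
    order = np.argsort(masses)[::-1]
    if masses.size > 1 and masses[order[1]] > 0.2 * masses[order[0]]:
        warnings.warn(
            "multiple comparable objects in frame; scoring the largest",
            stacklevel=2)
    comet = labels == (order[0] + 1)

    head_row, head_col, sigma = _head_geometry(sub, comet, head_policy)
    fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma
    r_head = k_head * fwhm

    rr = np.arange(img.shape[0])[:, None]
    cc = np.arange(img.shape[1])[None, :]
    in_disk = (rr - head_row) ** 2 + (cc - head_col) ** 2 <= r_head ** 2
    tail_mask = comet & ~in_disk & (cc > head_col)
    head_mask = comet & ~tail_mask

    total = float(sub[comet].sum())
    if total <= 0:
        raise UnscorableImageError("comet has zero integrated signal")
    tail_pct = 100.0 * float(sub[tail_mask].sum()) / total
    return CometScore(
        tail_intensity=tail_pct,
        head_pct=100.0 - tail_pct,
        head_center=(head_row, head_col),
        head_radius=float(r_head),
        background=bg,
        total_signal=total,
        comet_mask=comet,
        head_mask=head_mask,
        tail_mask=tail_mask,
    )


# ---------------------------------------------------------------------------
# TIFF round-trip and batch scoring
# ---------------------------------------------------------------------------

def save_comet_tiff(image: CometImage, path) -> None:
    """Write a single-comet grayscale TIFF (float32), truth in metadata."""
    meta = {}
    if image.truth_tail_fraction is not None:
        meta["truth_tail_fraction"] = image.truth_tail_fraction
    if image.seed is not None:
        meta["seed"] = image.seed
    tifffile.imwrite(path, image.pixels.astype(np.float32),
                     description=json.dumps(meta))


def load_comet_tiff(path) -> CometImage:
    """Read a grayscale TIFF, recovering recorded ground truth if present."""
    with tifffile.TiffFile(path) as tf:
        pixels = tf.asarray().astype(float)
        desc = tf.pages[0].description or ""
    truth, seed = None, None
    try:
        meta = json.loads(desc)
        truth = meta.get("truth_tail_fraction")
        seed = meta.get("seed")
    except (json.JSONDecodeError, AttributeError):
        pass
    return CometImage(pixels=pixels, truth_tail_fraction=truth, seed=seed)


#: filename convention for batch scoring:
#: ``{sample}__{condition}__w{well}__{treatment}__c{cell}.tif``
_NAME_RE = re.compile(
    r"^(?P<sample_id>[^_]+(?:_[^_]+)*?)__(?P<condition>[^_]+)"
    r"__w(?P<well>\d+)__(?P<treatment>[A-Za-z]+)__c(?P<cell_id>\d+)\.tiff?$")


def score_directory(directory, **score_kwargs) -> pd.DataFrame:
    """Score every TIFF in a directory into the per-comet table schema.

    Filenames must follow
    ``{sample}__{condition}__w{well}__{treatment}__c{cell}.tif``.
    Unscorable images are skipped with a warning.
    """
    rows = []
    for path in sorted(Path(directory).iterdir()):
        m = _NAME_RE.match(path.name)
        if not m:
            continue
        try:
            score = score_comet(load_comet_tiff(path), **score_kwargs)
        except UnscorableImageError as err:
            warnings.warn(f"{path.name}: {err}; skipped", stacklevel=2)
            continue
        rows.append({
            "sample_id": m["sample_id"],
            "condition": m["condition"],
            "well": int(m["well"]),
            "cell_id": int(m["cell_id"]),
            "treatment": m["treatment"],
            "tail_intensity": score.tail_intensity,
        })
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "well", "cell_id",
                       "treatment", "tail_intensity"])
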