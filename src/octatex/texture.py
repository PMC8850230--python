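"""Spatial autocorrelation texture analysis of en-face OCTA images.

The texture of an en-face slab is summarised by its normalized spatial
autocorrelation: fine, homogeneous capillary textures decorrelate within a
few pixels, whereas coarse textures with flow voids stay correlated over
tens of pixels.  The 2D autocorrelation map is reduced to a radial lag
curve rho(d) (d in pixels, convertible to um through the pixel scale), from
which two scalar features are read off:

* the zero crossing — the first lag at which rho drops to or below zero
  (healthy choriocapillaris curves reach it around 90 um);
* the plateau level — the mean rho over a far-lag window (100-150 um by
  default), which stays visibly positive (roughly 0.05-0.2) for coarse,
  flow-void-dominated textures.

The estimator is the unbiased spatial autocovariance: the whole-image mean
is subtracted once, each integer offset is averaged over its actually
overlapping pixel pairs (no periodic wrap-around), and the map is
normalized by the whole-image variance so rho(0,0) = 1.  Because the mean
and variance are global, the estimate is exactly invariant under affine
intensity rescaling a*I + b — manual brightness/contrast adjustments do not
change the curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.fft

from .image_io import EnFaceImage

DEFAULT_MAX_LAG_PX = 30
DEFAULT_PLATEAU_WINDOW_UM = (100.0, 150.0)


@dataclass
class AutocorrCurve:
    """Radially averaged autocorrelation of one image."""

    lags_px: np.ndarray
    rho: np.ndarray
    n_pairs: np.ndarray  # offsets pooled per radial bin
    pixel_scale_um: float = 5.0
    subject_id: str = ""
    group: str = ""
    layer: str = ""

    @property
    def lags_um(self) -> np.ndarray:
        return self.lags_px * self.pixel_scale_um

    @property
    def max_lag_px(self) -> int:
        return int(self.lags_px[-1])


@dataclass
class CurveFeatures:
    """Scalar features of an autocorrelation curve."""

    zero_crossing_um: float
    censored: bool
    plateau_rho: float
    plateau_window_um: tuple[float, float] = DEFAULT_PLATEAU_WINDOW_UM


def _pixels(img: EnFaceImage | np.ndarray) -> np.ndarray:
    if isinstance(img, EnFaceImage):
        return img.pixels.astype(float)
    return np.asarray(img, dtype=float)


def autocorrelation_2d(
    img: EnFaceImage | np.ndarray, max_lag: int = DEFAULT_MAX_LAG_PX
) -> np.ndarray:
    """Normalized 2D autocorrelation map rho(dy, dx) for |dy|,|dx| <= max_lag.

    Returns a (2*max_lag+1) x (2*max_lag+1) array indexed so that entry
    [max_lag + dy, max_lag + dx] is rho at offset (dy, dx).  The map is
    centro-symmetric and rho(0, 0) = 1.

    The estimator averages (I(x) - mu)(I(x + delta) - mu) over the
    N_valid(delta) = (H - |dy|) (W - |dx|) genuinely overlapping pairs of a
    non-periodic image, then divides by the global variance.  Implemented
    with a zero-padded FFT; padding by max_lag prevents wrap-around.
    """
    arr = _pixels(img)
    h, w = arr.shape
    if max_lag >= min(h, w) / 2:
        raise ValueError(f"max_lag {max_lag} too large for {h}x{w} image")
    mu = arr.mean()
    var = arr.var()  # ddof=0: makes rho(0,0) exactly 1
    if var == 0:
        raise ValueError("constant image: autocorrelation undefined (zero variance)")
    centered = arr - mu

    size = (
        scipy.fft.next_fast_len(h + max_lag),
        scipy.fft.next_fast_len(w + max_lag),
    )
    f = scipy.fft.rfft2(centered, s=size)
    raw = scipy.fft.irfft2(f * np.conj(f), s=size)

    lags = np.arange(-max_lag, max_lag + 1)
    rho = np.empty((2 * max_lag + 1, 2 * max_lag + 1))
    counts = (h - np.abs(lags))[:, None] * (w - np.abs(lags))[None, :]
    rho[:] = raw[np.ix_(lags % size[0], lags % size[1])] / counts / var
    return rho


def autocorrelation_2d_bruteforce(
    img: EnFaceImage | np.ndarray, max_lag: int
) -> np.ndarray:
    """Literal pair-enumeration estimator; oracle for small images only."""
    arr = _pixels(img)
    h, w = arr.shape
    mu = arr.mean()
    var = arr.var()
    if var == 0:
        raise ValueError("constant image")
    centered = arr - mu
    rho = np.empty((2 * max_lag + 1, 2 * max_lag + 1))
    for dy in range(-max_lag, max_lag + 1):
        for dx in range(-max_lag, max_lag + 1):
            total = 0.0
            n = 0
            for y in range(h):
                for x in range(w):
                    y2, x2 = y + dy, x + dx
                    if 0 <= y2 < h and 0 <= x2 < w:
                        total += centered[y, x] * centered[y2, x2]
                        n += 1
            rho[max_lag + dy, max_lag + dx] = total / n / var
    return rho


def radial_profile(
    acf: np.ndarray,
    pixel_scale_um: float = 5.0,
    subject_id: str = "",
    group: str = "",
    layer: str = "",
) -> AutocorrCurve:
    """Pool the 2D map into integer radial lag bins.

    Offset (dy, dx) contributes to bin d = round(sqrt(dy^2 + dx^2)); bins
    beyond the map half-width are discarded, so the curve runs d = 0..L
    with L = max_lag of the map.
    """
    max_lag = (acf.shape[0] - 1) // 2
    lags = np.arange(-max_lag, max_lag + 1)
    dist = np.hypot(lags[:, None], lags[None, :])
    bins = np.rint(dist).astype(int)
    keep = bins <= max_lag
    rho = np.bincount(bins[keep], weights=acf[keep], minlength=max_lag + 1)
    n_pairs = np.bincount(bins[keep], minlength=max_lag + 1)
    return AutocorrCurve(
        lags_px=np.arange(max_lag + 1),
        rho=rho / n_pairs,
        n_pairs=n_pairs,
        pixel_scale_um=pixel_scale_um,
        subject_id=subject_id,
        group=group,
        layer=layer,
    )


def curve_from_image(
    img: EnFaceImage, max_lag: int = DEFAULT_MAX_LAG_PX
) -> AutocorrCurve:
    """Full image -> radial curve convenience path, carrying metadata."""
    acf = autocorrelation_2d(img, max_lag=max_lag)
    return radial_profile(
        acf,
        pixel_scale_um=img.pixel_scale_um,
        subject_id=img.subject_id,
        group=img.group,
        layer=img.layer,
    )


def zero_crossing(curve: AutocorrCurve) -> tuple[float, bool]:
    """First lag (in um) with rho <= 0, or (max lag, censored=True).

    Reported at whole-pixel resolution, without sub-bin interpolation.
    """
    nonpos = np.nonzero(curve.rho[1:] <= 0)[0]
    if nonpos.size == 0:
        return float(curve.lags_um[-1]), True
    return float(curve.lags_um[nonpos[0] + 1]), False


def plateau_value(
    curve: AutocorrCurve,
    window_um: tuple[float, float] = DEFAULT_PLATEAU_WINDOW_UM,
) -> float:
    """Mean rho over the far-lag window (inclusive bounds, in um)."""
    lo, hi = window_um
    mask = (curve.lags_um >= lo) & (curve.lags_um <= hi)
    if not mask.any():
        raise ValueError(f"plateau window {window_um} um contains no lag bins")
    return float(curve.rho[mask].mean())


def compute_features(
    curve: AutocorrCurve,
    plateau_window_um: tuple[float, float] = DEFAULT_PLATEAU_WINDOW_UM,
) -> CurveFeatures:
    zc, censored = zero_crossing(curve)
    return CurveFeatures(
        zero_crossing_um=zc,
        censored=censored,
        plateau_rho=plateau_value(curve, plateau_window_um),
        plateau_window_um=plateau_window_um,
    )


def curves_to_frame(curves: Sequence[AutocorrCurve]) -> pd.DataFrame:
    """Wide CSV layout: one row per subject, rho_###um columns."""
    rows = []
    for c in curves:
        row = {"subject_id": c.subject_id, "group": c.group, "layer": c.layer}
        for lag_um, r in zip(c.lags_um, c.rho):
            row[f"rho_{int(round(lag_um)):03d}um"] = r
        rows.append(row)
    return pd.DataFrame(rows)


def features_to_frame(
    curves: Sequence[AutocorrCurve],
    plateau_window_um: tuple[float, float] = DEFAULT_PLATEAU_WINDOW_UM,
) -> pd.DataFrame:
    rows = []
    for c in curves:
        f = compute_features(c, plateau_window_um)
        rows.append(
            {
                "subject_id": c.subject_id,
                "group": c.group,
                "layer": c.layer,
                "zero_crossing_um": f.zero_crossing_um,
                "censored": f.censored,
                "plateau_rho": f.plateau_rho,
            }
        )
    return pd.DataFrame(rows)
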