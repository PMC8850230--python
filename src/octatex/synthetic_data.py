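"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

No public image corpus accompanies sector-wise choriocapillaris studies, so
every pipeline stage is exercised on synthetic inputs whose *texture
statistics* are controlled exactly:

* Control-like slabs are Gaussian random fields — white noise smoothed with
  an isotropic Gaussian kernel of scale ``kernel_sigma_px``.  The smoothing
  kernel convolved with itself is again Gaussian, so the field's normalized
  autocorrelation is exp(-d^2 / (4 sigma^2)) in closed form; a small sigma
  (2 px by default) yields the fast-decaying curve of a finely homogeneous
  capillary texture.
* Case-like slabs use a larger sigma (8 px) and add dark flow-void spots:
  discs with lognormal radii placed by a homogeneous Poisson process, whose
  interiors are attenuated multiplicatively.  The result is a coarse
  texture whose radial curve stays positive over the far-lag window.
* CFD tables are drawn per sector from the published group normal
  parameters, clipped to the valid percentage range.

Smoothing uses periodic (wrap) boundaries so the field is stationary and
the closed-form curve holds without edge effects; the analysis-side
estimator remains non-periodic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from . import reference_tables
from .image_io import EnFaceImage

DEFAULT_SIZE = 512
DEFAULT_PIXEL_SCALE_UM = 5.0


@dataclass
class TextureParams:
    """Parameters of one synthetic en-face texture.

    ``spot_density`` is the expected flow-void count per mm^2;
    ``spot_radius_um`` the (mean, sd) of the lognormal disc radius;
    ``spot_depth`` the fractional intensity reduction inside a disc
    (1 = total void).  ``base_mean``/``base_sd`` set the 8-bit intensity
    scale of the background field.
    """

    size: int = DEFAULT_SIZE
    kernel_sigma_px: float = 2.0
    spot_density: float = 0.0
    spot_radius_um: tuple[float, float] = (100.0, 40.0)
    spot_depth: float = 0.8
    base_mean: float = 120.0
    base_sd: float = 30.0
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.kernel_sigma_px > 0:
            raise ValueError("kernel_sigma_px must be positive")
        if not 0.0 <= self.spot_depth <= 1.0:
            raise ValueError("spot_depth must lie in [0, 1]")
        if self.spot_density < 0:
            raise ValueError("spot_density must be >= 0")


#: parameter presets for the two study arms: fine control texture vs
#: coarse case texture with flow voids
CONTROL_PARAMS = TextureParams(kernel_sigma_px=2.0, spot_density=0.0)
CASE_PARAMS = TextureParams(kernel_sigma_px=8.0, spot_density=1.5)


def theoretical_acf(d: np.ndarray, kernel_sigma_px: float) -> np.ndarray:
    """Closed-form normalized ACF of Gaussian-smoothed white noise."""
    d = np.asarray(d, dtype=float)
    return np.exp(-(d**2) / (4.0 * kernel_sigma_px**2))


def gaussian_field(params: TextureParams, **metadata) -> EnFaceImage:
    """Smoothed-noise background field, rescaled and quantized to 8-bit."""
    rng = np.random.default_rng(params.seed)
    noise = rng.standard_normal((params.size, params.size))
    smooth = ndimage.gaussian_filter(noise, params.kernel_sigma_px, mode="wrap")
    smooth = (smooth - smooth.mean()) / smooth.std()
    pixels = np.clip(
        np.round(params.base_mean + params.base_sd * smooth), 0, 255
    ).astype(np.uint8)
    return EnFaceImage(
        pixels=pixels, pixel_scale_um=params.pixel_scale_um, **metadata
    )


def _lognormal_radii(rng: np.random.Generator, mean: float, sd: float, n: int):
    if sd == 0:
        return np.full(n, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), n)


def add_dark_spots(img: EnFaceImage, params: TextureParams) -> EnFaceImage:
    """Attenuate Poisson-placed discs; overlapping spots multiply."""
    if params.spot_density == 0 or params.spot_depth == 0:
        return img
    rng = np.random.default_rng(params.seed + 1)  # independent of the field
    h, w = img.pixels.shape
    area_mm2 = (h * img.pixel_scale_um / 1000.0) * (w * img.pixel_scale_um / 1000.0)
    n_spots = rng.poisson(params.spot_density * area_mm2)
    if n_spots == 0:
        return img
    centers = rng.uniform(0, [h, w], size=(n_spots, 2))
    radii_px = (
        _lognormal_radii(rng, *params.spot_radius_um, n_spots)
        / img.pixel_scale_um
    )
    yy, xx = np.mgrid[0:h, 0:w]
    attenuation = np.ones((h, w))
    for (cy, cx), r in zip(centers, radii_px):
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        attenuation[inside] *= 1.0 - params.spot_depth
    pixels = np.round(img.pixels * attenuation).astype(np.uint8)
    return EnFaceImage(
        pixels=pixels,
        pixel_scale_um=img.pixel_scale_um,
        subject_id=img.subject_id,
        eye=img.eye,
        group=img.group,
        layer=img.layer,
        signal_strength=img.signal_strength,
    )


def subject_seed(master_seed: int, index: int) -> int:
    """Stated per-subject seed hash: SeedSequence(master, index) -> uint32."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0])


def make_texture_cohort(
    n_control: int = 13,
    n_case: int = 40,
    control_params: TextureParams = CONTROL_PARAMS,
    case_params: TextureParams = CASE_PARAMS,
    master_seed: int = 0,
    layer: str = "CCL",
) -> tuple[list[EnFaceImage], pd.DataFrame]:
    """Generate a control + case image cohort and its manifest.

    Subjects receive deterministic seeds derived from ``master_seed`` and
    their index, so the corpus is reproducible and subjects independent.
    Default arm sizes mirror the study's 13 control and 40 case eyes.
    """
    if n_control < 0 or n_case < 0 or n_control + n_case < 1:
        raise ValueError("need at least one subject")
    images: list[EnFaceImage] = []
    rows = []
    rng = np.random.default_rng(subject_seed(master_seed, 10**6))
    for i in range(n_control + n_case):
        is_control = i < n_control
        params = control_params if is_control else case_params
        params = TextureParams(**{**asdict(params), "seed": subject_seed(master_seed, i)})
        sid = f"C{i:03d}" if is_control else f"P{i - n_control:03d}"
        group = "control" if is_control else "case"
        img = gaussian_field(
            params, subject_id=sid, group=group, layer=layer,
            signal_strength=int(rng.integers(7, 11)),
        )
        if not is_control:
            img = add_dark_spots(img, params)
        images.append(img)
        rows.append(
            {
                "subject_id": sid,
                "eye": "OD",
                "group": group,
                "layer": layer,
                "signal_strength": img.signal_strength,
                "image_path": f"{sid}_{layer}.png",
                "pixel_scale_um": params.pixel_scale_um,
            }
        )
    return images, pd.DataFrame(rows)


@dataclass
class CfdCohortParams:
    """Per-sector normal parameters for a synthetic case/control CFD table.

    Defaults are the published per-sector group means and SDs with the
    table's own sample sizes (41 cases, 35 controls).
    """

    summary: pd.DataFrame = field(
        default_factory=reference_tables.case_control_summary
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.summary["sd_case"] <= 0).any() or (
            self.summary["sd_control"] <= 0
        ).any():
            raise ValueError("group SDs must be positive")
        if (self.summary[["n_case", "n_control"]] < 2).any().any():
            raise ValueError("group sizes must be >= 2")


def make_cfd_cohort(params: Optional[CfdCohortParams] = None) -> pd.DataFrame:
    """Draw a long per-subject CFD table from the group parameters.

    Percent-valued sectors are clipped to [0, 100]; the ``thickness``
    sector (um) is clipped below at 1.  With the published parameters the
    clipping probability is negligible.
    """
    params = params or CfdCohortParams()
    rng = np.random.default_rng(params.seed)
    rows = []
    for _, r in params.summary.iterrows():
        for group, mean, sd, n in (
            ("case", r["mean_case"], r["sd_case"], int(r["n_case"])),
            ("control", r["mean_control"], r["sd_control"], int(r["n_control"])),
        ):
            values = rng.normal(mean, sd, n)
            if r["sector"] == "thickness":
                values = np.clip(values, 1.0, None)
            else:
                values = np.clip(values, 0.0, 100.0)
            prefix = "P" if group == "case" else "C"
            rows.extend(
                {
                    "subject_id": f"{prefix}{i:03d}",
                    "group": group,
                    "layer": "CCL",
                    "sector": r["sector"],
                    "value": v,
                }
                for i, v in enumerate(values)
            )
    return pd.DataFrame(rows)


def fit_kernel_sigma(lags_px: np.ndarray, rho: np.ndarray) -> float:
    """Least-squares recovery of the smoothing scale from a measured curve.

    Fits exp(-d^2 / (4 sigma^2)) over the positive part of the curve; used
    to validate that the generator produces the correlation length it
    claims.
    """
    from scipy.optimize import curve_fit

    lags_px = np.asarray(lags_px, dtype=float)
    rho = np.asarray(rho, dtype=float)
    popt, _ = curve_fit(
        lambda d, s: theoretical_acf(d, s), lags_px, rho, p0=[2.0],
        bounds=(1e-3, 100.0),
    )
    return float(popt[0])
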