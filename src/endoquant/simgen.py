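"""Synthetic-microscopy data generator with known ground truth.

Three generators emulate the statistical structure of the raw data behind a
quantitative endocytosis study:

* :func:`render_spot_field` — TIRF-like fields of diffraction-limited
  puncta (clathrin-coated pits): pixel-integrated Gaussian spots of known
  sub-pixel position and amplitude on a constant or gently sloping
  background, with Poisson photon noise plus Gaussian read noise, and an
  optional correlated second channel (a fraction of spots carry cargo
  signal in channel 2).
* :func:`render_cell_field` — epifluorescence-like whole-cell fields:
  disjoint elliptical cells whose interior mean intensity is drawn from a
  condition-dependent distribution, on a uniform coverslip background.
* :func:`simulate_uptake_series` — fluid-phase uptake time courses with a
  linear accumulation in the control condition and a piecewise-linear,
  delayed-onset elevated slope in treated conditions.

Every generator is seeded and bit-reproducible; each draws from a named
substream of the master seed.  Ground truth is returned alongside the data
so each downstream analysis stage can be validated against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

from ._rng import derive_rng
from .psf import spot_image

__all__ = [
    "OpticalModel",
    "NoiseModel",
    "SpotGroundTruth",
    "SceneSpec",
    "CellFieldSpec",
    "UptakeModelSpec",
    "PlacementError",
    "render_spot_field",
    "render_cell_field",
    "simulate_uptake_series",
    "correlated_channels",
]


class PlacementError(RuntimeError):
    """Raised when random placement cannot satisfy a separation constraint."""


# --------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class OpticalModel:
    """Imaging-system description for rendering.

    psf_sigma
        Gaussian PSF standard deviation in pixels (diffraction-limited
        spots; default 1.4 px for a high-NA TIRF objective).
    image_shape
        (rows, cols) of the rendered frame.
    bit_depth
        Camera bit depth; rendered values are clipped to [0, 2**bit_depth - 1].
    """

    psf_sigma: float = 1.4
    image_shape: tuple[int, int] = (256, 256)
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if min(self.image_shape) < 32:
            raise ValueError("image dimensions must be >= 32 pixels")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")

    @property
    def max_value(self) -> float:
        return float(2**self.bit_depth - 1)


@dataclass(frozen=True)
class NoiseModel:
    """Poisson-Gaussian camera noise.

    The noisy value of a pixel with noise-free intensity v is

        poisson(photon_scale * v) / photon_scale + N(0, read_noise_sd) + baseline_offset

    so the variance of a flat region at level v is
    ``v / photon_scale + read_noise_sd**2``.  ``photon_scale = 0`` disables
    the Poisson component (pure additive Gaussian noise);
    ``read_noise_sd = 0`` disables the Gaussian component.
    """

    read_noise_sd: float = 10.0
    photon_scale: float = 1.0
    baseline_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0 or self.photon_scale < 0 or self.baseline_offset < 0:
            raise ValueError("noise parameters must be >= 0")

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(image, dtype=float)
        if self.photon_scale > 0:
            out = rng.poisson(np.clip(out, 0, None) * self.photon_scale) / self.photon_scale
        if self.read_noise_sd > 0:
            out = out + rng.normal(0.0, self.read_noise_sd, size=out.shape)
        return out + self.baseline_offset

    def flat_field_variance(self, level: float) -> float:
        """Closed-form variance of a flat region rendered at ``level``."""
        var = self.read_noise_sd**2
        if self.photon_scale > 0:
            var += level / self.photon_scale
        return var


@dataclass(frozen=True)
class SpotGroundTruth:
    """One rendered spot: sub-pixel position (row, col), peak amplitude
    above local background, PSF sigma, and the channel-2 amplitude (0 for
    spots without cargo signal)."""

    spot_id: int
    x: float
    y: float
    amplitude: float
    sigma: float
    channel2_amplitude: float = 0.0
    saturated: bool = False


_DISTRIBUTIONS = ("constant", "uniform", "normal", "lognormal")


@dataclass(frozen=True)
class SceneSpec:
    """Full parametric description of one synthetic TIRF field."""

    optical: OpticalModel = field(default_factory=OpticalModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_spots: int = 30
    #: (name, params): ("constant", {"value": a}) | ("uniform", {"low","high"})
    #: | ("normal", {"mean","sd"}) | ("lognormal", {"mean","cv"})
    amplitude_distribution: tuple[str, dict] = ("lognormal", {"mean": 300.0, "cv": 0.3})
    #: constant level, or (level, slope_row, slope_col) linear gradient
    background: float | tuple[float, float, float] = 100.0
    colocalization_fraction: float = 0.0
    channel2_amplitude_distribution: tuple[str, dict] | None = None
    min_separation: float = 6.0
    #: spots are placed at least this far from every image edge so that the
    #: default fit window never touches the border
    edge_margin: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.colocalization_fraction <= 1.0:
            raise ValueError("colocalization_fraction must be in [0, 1]")
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")
        name = self.amplitude_distribution[0]
        if name not in _DISTRIBUTIONS:
            raise ValueError(f"unknown amplitude distribution {name!r}")
        rows, cols = self.optical.image_shape
        usable = (rows - 2 * self.edge_margin) * (cols - 2 * self.edge_margin)
        if self.n_spots * np.pi * (self.min_separation / 2.0) ** 2 > max(usable, 0):
            raise ValueError("n_spots x exclusion area exceeds usable image area")


@dataclass(frozen=True)
class CellFieldSpec:
    """Epifluorescence-like field of disjoint elliptical cells.

    ``condition_means`` maps a condition label to the distribution of
    per-cell *raw* interior mean intensity (intensity units).  The default
    cell-to-cell coefficient of variation of 0.15 reflects typical
    cell-to-cell variability of marker expression in cultured cells.
    """

    n_cells: int = 20
    condition_means: dict[str, tuple[str, dict]] = field(
        default_factory=lambda: {"control": ("normal", {"mean": 1000.0, "sd": 150.0})}
    )
    background_level: float = 100.0
    pixel_noise_sd: float = 50.0
    image_shape: tuple[int, int] = (512, 512)
    semi_axis_range: tuple[float, float] = (10.0, 20.0)
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.semi_axis_range[0] <= 2 or self.semi_axis_range[1] < self.semi_axis_range[0]:
            raise ValueError("invalid semi_axis_range")


@dataclass(frozen=True)
class UptakeModelSpec:
    """Piecewise-linear fluid-phase uptake model.

    The control condition accumulates probe linearly:
    ``mean(t) = control_slope * t``.  A treated condition follows the
    control slope until ``onset_delay`` and an elevated slope thereafter.
    Replicates (independent experiments) at each timepoint get additive
    Gaussian noise and are clipped at zero; the t = 0 readout is the assay
    blank and is exactly zero.

    Defaults mirror a delayed-onset fluid-phase response: timepoints
    0/10/20 min, a 3-fold slope elevation after a 10 min delay (hence a
    2-fold treated/control ratio at 20 min and no difference at <= 10 min).
    """

    timepoints: tuple[float, ...] = (0.0, 10.0, 20.0)
    control_slope: float = 1.0
    treated_slopes: dict[str, float] = field(default_factory=lambda: {"usmb": 3.0})
    onset_delay: float = 10.0
    replicate_noise_sd: float = 2.0
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0) or t[0] < 0:
            raise ValueError("timepoints must be strictly increasing and >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.control_slope < 0 or any(s < 0 for s in self.treated_slopes.values()):
            raise ValueError("accumulation slopes must be >= 0 "
                             "(uptake assays are non-decreasing in expectation)")


# --------------------------------------------------------------------------
# sampling helpers


def _sample_distribution(dist: tuple[str, dict], n: int, rng: np.random.Generator) -> np.ndarray:
    name, params = dist
    if name == "constant":
        return np.full(n, float(params["value"]))
    if name == "uniform":
        return rng.uniform(params["low"], params["high"], n)
    if name == "normal":
        return rng.normal(params["mean"], params["sd"], n)
    if name == "lognormal":
        mean, cv = float(params["mean"]), float(params["cv"])
        s2 = np.log1p(cv * cv)
        return rng.lognormal(np.log(mean) - s2 / 2.0, np.sqrt(s2), n)
    raise ValueError(f"unknown distribution {name!r}")


def _place_points(
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_separation: float,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> np.ndarray:
    """Uniform random points with pairwise distance >= min_separation."""
    placed: list[tuple[float, float]] = []
    lo_r, hi_r = margin, shape[0] - 1 - margin
    lo_c, hi_c = margin, shape[1] - 1 - margin
    for _ in range(n):
        for _attempt in range(max_tries):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_separation**2 for pr, pc in placed):
                placed.append((r, c))
                break
        else:
            raise PlacementError(
                f"could not place {n} spots with min_separation="
                f"{min_separation} px after {max_tries} tries per spot"
            )
    return np.asarray(placed, dtype=float).reshape(n, 2)


# --------------------------------------------------------------------------
# generators


def render_spot_field(
    spec: SceneSpec,
) -> tuple[dict[str, np.ndarray], list[SpotGroundTruth]]:
    """Render a seeded synthetic TIRF field.

    Returns a dict of channel images (``"ch1"`` always; ``"ch2"`` when
    ``colocalization_fraction > 0`` or a channel-2 distribution is set) and
    the ground-truth spot list in render order.  Spots are rendered with the
    pixel-integrated Gaussian model, so the integrated intensity of each
    noiseless spot is exactly ``2*pi*amplitude*sigma**2``.
    """
    rng = derive_rng(spec.seed, "spot_field")
    opt = spec.optical
    rows, cols = opt.image_shape
    sigma = opt.psf_sigma

    if isinstance(spec.background, (int, float)):
        bg = np.full((rows, cols), float(spec.background))
    else:
        level, sr, sc = spec.background
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        bg = level + sr * rr + sc * cc

    positions = _place_points(spec.n_spots, (rows, cols), spec.edge_margin,
                              spec.min_separation, rng)
    amplitudes = _sample_distribution(spec.amplitude_distribution, spec.n_spots, rng)
    amplitudes = np.clip(amplitudes, 0.0, None)

    two_channel = spec.colocalization_fraction > 0 or spec.channel2_amplitude_distribution is not None
    carriers = np.zeros(spec.n_spots, dtype=bool)
    amp2 = np.zeros(spec.n_spots)
    if two_channel and spec.n_spots:
        n_carriers = int(round(spec.colocalization_fraction * spec.n_spots))
        carriers[rng.permutation(spec.n_spots)[:n_carriers]] = True
        dist2 = spec.channel2_amplitude_distribution or spec.amplitude_distribution
        amp2[carriers] = np.clip(_sample_distribution(dist2, int(carriers.sum()), rng), 0.0, None)

    clean1 = bg.copy()
    clean2 = bg.copy() if two_channel else None
    half = int(np.ceil(6 * sigma))
    for i in range(spec.n_spots):
        r0, c0 = positions[i]
        rlo, rhi = int(np.floor(r0)) - half, int(np.floor(r0)) + half + 1
        clo, chi = int(np.floor(c0)) - half, int(np.floor(c0)) + half + 1
        rlo, rhi = max(rlo, 0), min(rhi, rows)
        clo, chi = max(clo, 0), min(chi, cols)
        patch = spot_image(np.arange(rlo, rhi), np.arange(clo, chi), r0, c0,
                           amplitudes[i], sigma)
        clean1[rlo:rhi, clo:chi] += patch
        if clean2 is not None and amp2[i] > 0:
            clean2[rlo:rhi, clo:chi] += patch * (amp2[i] / amplitudes[i]) if amplitudes[i] > 0 \
                else spot_image(np.arange(rlo, rhi), np.arange(clo, chi), r0, c0, amp2[i], sigma)

    ch1 = np.clip(spec.noise.apply(clean1, rng), 0.0, opt.max_value)
    channels = {"ch1": ch1}
    if clean2 is not None:
        channels["ch2"] = np.clip(spec.noise.apply(clean2, rng), 0.0, opt.max_value)

    sat_level = opt.max_value
    truth = []
    for i in range(spec.n_spots):
        r0, c0 = positions[i]
        ri, ci = int(round(r0)), int(round(c0))
        saturated = bool(ch1[max(ri - 1, 0):ri + 2, max(ci - 1, 0):ci + 2].max() >= sat_level)
        truth.append(SpotGroundTruth(
            spot_id=i, x=float(r0), y=float(c0), amplitude=float(amplitudes[i]),
            sigma=sigma, channel2_amplitude=float(amp2[i]), saturated=saturated,
        ))
    return channels, truth


def truth_to_frame(truth: Sequence[SpotGroundTruth]) -> pd.DataFrame:
    """Ground-truth list as a DataFrame (the on-disk CSV schema)."""
    return pd.DataFrame(
        [
            {
                "spot_id": t.spot_id, "x": t.x, "y": t.y, "sigma": t.sigma,
                "amplitude": t.amplitude, "channel2_amplitude": t.channel2_amplitude,
                "saturated": t.saturated,
            }
            for t in truth
        ],
        columns=["spot_id", "x", "y", "sigma", "amplitude",
                 "channel2_amplitude", "saturated"],
    )


def render_cell_field(
    spec: CellFieldSpec, condition: str
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render one field of disjoint elliptical cells for one condition.

    Returns ``(image, label_mask, truth)``.  ``label_mask`` holds 0 outside
    cells and 1..n_cells inside; ``truth`` has one row per cell with the
    drawn raw interior mean (``true_raw_mean``) and the mean net of the
    coverslip background (``true_net_mean``).  Interior pixels are drawn as
    ``N(true_raw_mean, pixel_noise_sd)``; background pixels as
    ``N(background_level, pixel_noise_sd)``; everything is clipped to the
    camera range.
    """
    if condition not in spec.condition_means:
        raise KeyError(f"condition {condition!r} not in spec.condition_means")
    rng = derive_rng(spec.seed, f"cell_field:{condition}")
    rows, cols = spec.image_shape
    a_lo, a_hi = spec.semi_axis_range

    mask = np.zeros((rows, cols), dtype=np.int32)
    geoms: list[tuple[float, float, float, float, float]] = []
    max_tries = 400
    for label in range(1, spec.n_cells + 1):
        for _attempt in range(max_tries):
            a = rng.uniform(a_lo, a_hi)
            b = rng.uniform(a_lo, a_hi)
            theta = rng.uniform(0, np.pi)
            r0 = rng.uniform(a_hi + 2, rows - a_hi - 3)
            c0 = rng.uniform(a_hi + 2, cols - a_hi - 3)
            # 2 px clearance between cells
            if all((r0 - pr) ** 2 + (c0 - pc) ** 2 >= (a + pa + 2) ** 2
                   for pr, pc, pa in [(g[0], g[1], max(g[2], g[3])) for g in geoms]):
                rr, cc = _draw_ellipse(r0, c0, a, b, shape=(rows, cols), rotation=theta)
                if mask[rr, cc].any():
                    continue
                mask[rr, cc] = label
                geoms.append((r0, c0, a, b, theta))
                break
        else:
            raise PlacementError(
                f"could not place {spec.n_cells} disjoint cells of semi-axes "
                f"{spec.semi_axis_range} in a {rows}x{cols} field"
            )

    means = _sample_distribution(spec.condition_means[condition], spec.n_cells, rng)
    means = np.clip(means, 0.0, None)

    image = rng.normal(spec.background_level, spec.pixel_noise_sd, (rows, cols)) \
        if spec.pixel_noise_sd > 0 else np.full((rows, cols), spec.background_level)
    for label in range(1, spec.n_cells + 1):
        sel = mask == label
        mu = means[label - 1]
        if spec.pixel_noise_sd > 0:
            image[sel] = rng.normal(mu, spec.pixel_noise_sd, int(sel.sum()))
        else:
            image[sel] = mu
    image = np.clip(image, 0.0, float(2**spec.bit_depth - 1))

    truth = pd.DataFrame(
        {
            "roi_id": np.arange(1, spec.n_cells + 1),
            "condition": condition,
            "row": [g[0] for g in geoms],
            "col": [g[1] for g in geoms],
            "n_pixels": [int((mask == i).sum()) for i in range(1, spec.n_cells + 1)],
            "true_raw_mean": means,
            "true_net_mean": means - spec.background_level,
        }
    )
    return image, mask, truth


def simulate_uptake_series(spec: UptakeModelSpec) -> dict[str, pd.DataFrame]:
    """Simulate uptake time courses for the control and treated conditions.

    Returns one long-format DataFrame per condition with columns
    ``(condition, experiment_id, time_min, replicate, readout)``; replicate
    r of every condition belongs to experiment ``expN`` so paired
    per-timepoint comparisons across conditions are possible.
    """
    rng = derive_rng(spec.seed, "uptake")
    t = np.asarray(spec.timepoints, dtype=float)

    def series(slopes_after: float | None) -> np.ndarray:
        if slopes_after is None:
            mean = spec.control_slope * t
        else:
            pre = spec.control_slope * np.minimum(t, spec.onset_delay)
            post = slopes_after * np.clip(t - spec.onset_delay, 0.0, None)
            mean = pre + post
        out = np.tile(mean[:, None], (1, spec.n_replicates))
        if spec.replicate_noise_sd > 0:
            noise = rng.normal(0.0, spec.replicate_noise_sd, out.shape)
            noise[t == 0.0, :] = 0.0  # t = 0 is the assay blank
            out = out + noise
        return np.clip(out, 0.0, None)

    conditions = {"control": series(None)}
    for name, slope in spec.treated_slopes.items():
        conditions[name] = series(slope)

    frames = {}
    for name, values in conditions.items():
        frames[name] = pd.DataFrame(
            {
                "condition": name,
                "experiment_id": np.tile([f"exp{r + 1}" for r in range(spec.n_replicates)], t.size),
                "time_min": np.repeat(t, spec.n_replicates),
                "replicate": np.tile(np.arange(1, spec.n_replicates + 1), t.size),
                "readout": values.ravel(),
            }
        )
    return frames


def correlated_channels(
    shape: tuple[int, int], rho: float, rng: np.random.Generator,
    mean: float = 1000.0, sd: float = 200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two channels whose pixel intensities are bivariate normal with
    correlation ``rho`` — a minimal stand-in for a pair of stains with a
    controlled true colocalization, used to validate the Pearson stage."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    z1 = rng.standard_normal(shape)
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(shape)
    return mean + sd * z1, mean + sd * z2
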