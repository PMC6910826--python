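"""Seeded synthetic micrographs and expression tables with ground truth.

Three generators emulate the data every downstream stage consumes:

* :func:`make_longitudinal_image` — side views of indirect-flight-muscle
  myofibrils: periodic bright Z-disc bands (band extent perpendicular to
  the myofibril axis = disc diameter) over a continuous actin counterstain,
  optionally with large bright aggregate blobs.
* :func:`make_crosssection_image` — a single Z-disc seen end-on, with a
  rotationally symmetric radial profile that is either centre-peaked
  (growing-isoform-like) or ring-shaped (blocking-isoform-like).
* :func:`make_expression_timecourse` — per-transcript TPM time courses in
  which growing-class transcripts switch on earlier than blocking-class
  ones, each following a logistic onset.

Every generator is a pure function of its parameters (including the seed in
``NoiseParams`` / ``ExpressionSimParams``) and returns a ground-truth table
with exactly one row per generated object.

Rendering model: objects are drawn as exact geometric sets on the pixel-
centre grid (a pixel belongs to a band iff its centre lies in the band's
half-open physical extent), then convolved with a Gaussian point-spread
function, then degraded with Poisson photon noise and additive Gaussian
read noise. With blur and noise disabled the ground-truth diameter of a
grid-aligned band is exact in pixels, which the morphometry tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image import CalibratedImage
from .isoforms import IsoformExpressionSet

__all__ = [
    "NoiseParams",
    "LongitudinalParams",
    "AggregateParams",
    "CrossSectionParams",
    "ExpressionSimParams",
    "make_longitudinal_image",
    "make_crosssection_image",
    "make_expression_timecourse",
]

#: default µm per pixel: a 512-px field then spans ~36 µm, the field size
#: used for the tiled aggregate scoring.
DEFAULT_PIXEL_SIZE_UM = 0.0703

_TRUTH_COLUMNS = [
    "object_kind",
    "object_id",
    "true_diameter_um",
    "true_onset_h",
    "center_x_px",
    "center_y_px",
    "bbox_x",
    "bbox_y",
    "bbox_w",
    "bbox_h",
    "class_label",
]


@dataclass
class NoiseParams:
    """Photon + read noise model.

    poisson_gain
        Photons per intensity unit; the image is replaced by
        ``Poisson(I * gain) / gain``. 0 disables shot noise.
    gaussian_sd
        SD of additive zero-mean Gaussian read noise, intensity units.
    seed
        Seed for the generator's private RNG (also used for object
        placement so the whole generator is seed-deterministic).
    """

    poisson_gain: float = 0.0
    gaussian_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.poisson_gain < 0 or self.gaussian_sd < 0:
            raise ValueError("noise gains/SDs must be >= 0")


@dataclass
class LongitudinalParams:
    """Geometry and intensity of a simulated myofibril side-view field."""

    field_size_um: tuple[float, float] = (36.0, 36.0)  # (width, height)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_myofibrils: int = 6
    sarcomere_length_um: float = 3.4
    disc_diameter_um: float | Sequence[float] = 1.4
    band_thickness_um: float = 0.35
    myofibril_axis_deg: float = 0.0
    psf_sigma_um: float = 0.0
    background_level: float = 10.0
    signal_level: float = 100.0
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        w, h = self.field_size_um
        if w <= 0 or h <= 0 or self.pixel_size_um <= 0:
            raise ValueError("field_size_um and pixel_size_um must be > 0")
        if self.sarcomere_length_um <= 0 or self.band_thickness_um <= 0:
            raise ValueError("sarcomere_length_um and band_thickness_um must be > 0")
        if self.n_myofibrils < 1:
            raise ValueError("n_myofibrils must be >= 1")
        dmax = max(np.atleast_1d(np.asarray(self.disc_diameter_um, dtype=float)))
        if dmax <= 0:
            raise ValueError("disc_diameter_um must be > 0")
        if dmax > h:
            raise ValueError(
                f"disc_diameter_um ({dmax} µm) exceeds field height ({h} µm)"
            )
        if self.sarcomere_length_um > w:
            raise ValueError(
                f"sarcomere_length_um ({self.sarcomere_length_um} µm) exceeds "
                f"field width ({w} µm): no band fits"
            )
        if self.n_myofibrils * dmax > h:
            raise ValueError(
                f"n_myofibrils ({self.n_myofibrils}) myofibrils of diameter "
                f"{dmax} µm do not fit in field height {h} µm"
            )


@dataclass
class AggregateParams:
    """Large bright blobs emulating pathological Zasp aggregates."""

    n_aggregates: int = 0
    aggregate_diameter_um: float | Sequence[float] = 3.0
    intensity_factor: float = 2.0
    positions_um: Sequence[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_aggregates < 0:
            raise ValueError("n_aggregates must be >= 0")
        d = np.atleast_1d(np.asarray(self.aggregate_diameter_um, dtype=float))
        if np.any(d <= 0):
            raise ValueError("aggregate diameters must be > 0")
        if self.positions_um is not None and len(self.positions_um) != self.n_aggregates:
            raise ValueError("positions_um length must equal n_aggregates")


@dataclass
class CrossSectionParams:
    """A single end-on Z-disc with a parametric radial intensity profile.

    ``profile_kind='center_peaked'`` renders a Gaussian in radius centred
    at 0 with SD ``profile_scale_um``; ``'ring'`` renders a Gaussian in
    radius centred at ``profile_scale_um`` with SD ``ring_width_um``
    (default: a third of the ring radius).
    """

    image_size_px: tuple[int, int] = (96, 96)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    disc_center_px: tuple[float, float] | None = None  # (x, y); default image centre
    disc_radius_um: float = 2.0
    profile_kind: str = "center_peaked"
    profile_scale_um: float = 0.6
    ring_width_um: float | None = None
    background_level: float = 10.0
    signal_level: float = 100.0
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        if self.profile_kind not in ("center_peaked", "ring"):
            raise ValueError(
                f"profile_kind must be 'center_peaked' or 'ring', got {self.profile_kind!r}"
            )
        if self.disc_radius_um <= 0 or self.profile_scale_um <= 0:
            raise ValueError("disc_radius_um and profile_scale_um must be > 0")
        if self.profile_kind == "ring" and self.profile_scale_um >= self.disc_radius_um:
            raise ValueError(
                f"ring radius profile_scale_um ({self.profile_scale_um} µm) must be "
                f"< disc_radius_um ({self.disc_radius_um} µm)"
            )
        w, h = self.image_size_px
        if self.disc_center_px is None:
            self.disc_center_px = ((w - 1) / 2.0, (h - 1) / 2.0)
        cx, cy = self.disc_center_px
        r_px = self.disc_radius_um / self.pixel_size_um
        if cx - r_px < 0 or cy - r_px < 0 or cx + r_px > w - 1 or cy + r_px > h - 1:
            raise ValueError("disc does not fit inside the image")


@dataclass
class ExpressionSimParams:
    """Logistic-onset TPM time courses for growing vs blocking isoforms."""

    n_growing: int = 20
    n_blocking: int = 20
    onset_growing_h: float = 24.0
    onset_blocking_h: float = 60.0
    plateau_tpm_growing: float = 100.0
    plateau_tpm_blocking: float = 100.0
    onset_sharpness_h: float = 4.0
    timepoints_h: Sequence[float] = (16.0, 24.0, 30.0, 48.0, 72.0, 90.0)
    lognormal_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_h, dtype=float)
        if t.size == 0:
            raise ValueError("timepoints_h must not be empty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints_h must be strictly increasing")
        if self.plateau_tpm_growing < 0 or self.plateau_tpm_blocking < 0:
            raise ValueError("TPM plateaus must be >= 0")
        if self.n_growing < 0 or self.n_blocking < 0:
            raise ValueError("transcript counts must be >= 0")
        if self.lognormal_sd < 0:
            raise ValueError("lognormal_sd must be >= 0")
        if self.onset_sharpness_h <= 0:
            raise ValueError("onset_sharpness_h must be > 0")


def _snap(value_um: float, px: float) -> float:
    """Snap a physical coordinate to the nearest pixel boundary."""
    return round(value_um / px) * px


def _apply_noise(img: np.ndarray, noise: NoiseParams, rng: np.random.Generator) -> np.ndarray:
    out = img.astype(float)
    if noise.poisson_gain > 0:
        out = rng.poisson(np.clip(out, 0, None) * noise.poisson_gain) / noise.poisson_gain
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def _rect_mask(
    shape: tuple[int, int],
    px: float,
    center_um: tuple[float, float],
    axis_rad: float,
    along_um: float,
    across_um: float,
) -> np.ndarray:
    """Boolean mask of an oriented rectangle, half-open on pixel centres.

    ``along_um`` is the extent along the myofibril axis, ``across_um`` the
    extent perpendicular to it (the disc diameter).
    """
    h, w = shape
    ys = (np.arange(h) + 0.5) * px
    xs = (np.arange(w) + 0.5) * px
    X, Y = np.meshgrid(xs, ys)
    cx, cy = center_um
    c, s = np.cos(axis_rad), np.sin(axis_rad)
    u = c * (X - cx) + s * (Y - cy)
    v = -s * (X - cx) + c * (Y - cy)
    eps = 1e-6 * px  # absorb float round-off at the half-open boundaries
    return (
        (u >= -along_um / 2 - eps)
        & (u < along_um / 2 - eps)
        & (v >= -across_um / 2 - eps)
        & (v < across_um / 2 - eps)
    )


def _bbox_of(mask: np.ndarray) -> tuple[int, int, int, int]:
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return (0, 0, 0, 0)
    return (int(xs.min()), int(ys.min()), int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1))


def make_longitudinal_image(
    params: LongitudinalParams, aggregates: AggregateParams | None = None
) -> tuple[dict[str, CalibratedImage], pd.DataFrame]:
    """Render a two-channel myofibril side-view field with ground truth.

    Returns
    -------
    channels
        ``{"zdisc": CalibratedImage, "actin": CalibratedImage}``.
    truth
        One row per Z-disc band and per aggregate: kind, true diameter,
        centre and bounding box in pixels.
    """
    if aggregates is None:
        aggregates = AggregateParams()
    px = params.pixel_size_um
    w_um, h_um = params.field_size_um
    W, H = round(w_um / px), round(h_um / px)
    shape = (H, W)
    rng = np.random.default_rng(params.noise.seed)

    theta = np.deg2rad(params.myofibril_axis_deg)
    sl = params.sarcomere_length_um
    n_bands_per_fibril = int(np.floor((w_um - sl / 2) / sl)) + 1
    diam_spec = np.atleast_1d(np.asarray(params.disc_diameter_um, dtype=float))

    zdisc = np.full(shape, float(params.background_level))
    actin = np.full(shape, float(params.background_level))
    rows: list[dict] = []

    # myofibrils run along the axis through evenly spaced anchor lines
    band_index = 0
    for i in range(params.n_myofibrils):
        y_i = _snap((i + 0.5) * h_um / params.n_myofibrils, px)
        fibril_diams = []
        for k in range(n_bands_per_fibril):
            x_k = _snap(sl / 2 + k * sl, px)
            d = float(diam_spec[band_index % diam_spec.size])
            fibril_diams.append(d)
            # rotate band centre about the field centre for non-zero axes
            if theta != 0.0:
                c0x, c0y = w_um / 2, h_um / 2
                dx, dy = x_k - c0x, y_i - c0y
                cx = c0x + np.cos(theta) * dx - np.sin(theta) * dy
                cy = c0y + np.sin(theta) * dx + np.cos(theta) * dy
            else:
                cx, cy = x_k, y_i
            mask = _rect_mask(shape, px, (cx, cy), theta, params.band_thickness_um, d)
            if not mask.any():
                band_index += 1
                continue
            zdisc[mask] = params.signal_level
            bx, by, bw, bh = _bbox_of(mask)
            rows.append(
                {
                    "object_kind": "zdisc",
                    "object_id": f"band_{i}_{k}",
                    "true_diameter_um": d,
                    "true_onset_h": np.nan,
                    "center_x_px": cx / px - 0.5,
                    "center_y_px": cy / px - 0.5,
                    "bbox_x": bx,
                    "bbox_y": by,
                    "bbox_w": bw,
                    "bbox_h": bh,
                    "class_label": "",
                }
            )
            band_index += 1
        if theta != 0.0:
            c0x, c0y = w_um / 2, h_um / 2
            sy = c0y + np.sin(theta) * (w_um / 2 - c0x) + np.cos(theta) * (y_i - c0y)
            sx = c0x + np.cos(theta) * (w_um / 2 - c0x) - np.sin(theta) * (y_i - c0y)
        else:
            sx, sy = w_um / 2, y_i
        stripe = _rect_mask(
            shape, px, (sx, sy), theta, 2 * max(w_um, h_um), max(fibril_diams, default=1.0)
        )
        actin[stripe] = params.signal_level

    agg_d = np.atleast_1d(np.asarray(aggregates.aggregate_diameter_um, dtype=float))
    for j in range(aggregates.n_aggregates):
        d = float(agg_d[j % agg_d.size])
        r = d / 2
        if aggregates.positions_um is not None:
            cx, cy = aggregates.positions_um[j]
        else:
            cx = rng.uniform(r + px, w_um - r - px)
            cy = rng.uniform(r + px, h_um - r - px)
        ys = (np.arange(H) + 0.5) * px
        xs = (np.arange(W) + 0.5) * px
        X, Y = np.meshgrid(xs, ys)
        mask = (X - cx) ** 2 + (Y - cy) ** 2 <= r**2
        zdisc[mask] = params.signal_level * aggregates.intensity_factor
        bx, by, bw, bh = _bbox_of(mask)
        rows.append(
            {
                "object_kind": "aggregate",
                "object_id": f"agg_{j}",
                "true_diameter_um": d,
                "true_onset_h": np.nan,
                "center_x_px": cx / px - 0.5,
                "center_y_px": cy / px - 0.5,
                "bbox_x": bx,
                "bbox_y": by,
                "bbox_w": bw,
                "bbox_h": bh,
                "class_label": "",
            }
        )

    if params.psf_sigma_um > 0:
        sig_px = params.psf_sigma_um / px
        zdisc = gaussian_filter(zdisc, sig_px)
        actin = gaussian_filter(actin, sig_px)
    zdisc = _apply_noise(zdisc, params.noise, rng)
    actin = _apply_noise(actin, params.noise, rng)

    truth = pd.DataFrame(rows, columns=_TRUTH_COLUMNS)
    channels = {
        "zdisc": CalibratedImage(zdisc, px, channel="zdisc"),
        "actin": CalibratedImage(actin, px, channel="actin"),
    }
    return channels, truth


def make_crosssection_image(
    params: CrossSectionParams,
) -> tuple[CalibratedImage, pd.DataFrame]:
    """Render one end-on Z-disc with a rotationally symmetric profile."""
    w, h = params.image_size_px
    px = params.pixel_size_um
    cx, cy = params.disc_center_px
    Y, X = np.mgrid[0:h, 0:w]
    r_um = np.hypot(X - cx, Y - cy) * px

    if params.profile_kind == "center_peaked":
        radial = np.exp(-(r_um**2) / (2 * params.profile_scale_um**2))
    else:
        width = params.ring_width_um or params.profile_scale_um / 3.0
        radial = np.exp(-((r_um - params.profile_scale_um) ** 2) / (2 * width**2))
    img = params.background_level + params.signal_level * radial
    # confine signal to the disc
    img[r_um > params.disc_radius_um] = params.background_level

    rng = np.random.default_rng(params.noise.seed)
    img = _apply_noise(img, params.noise, rng)

    truth = pd.DataFrame(
        [
            {
                "object_kind": "zdisc",
                "object_id": "disc_0",
                "true_diameter_um": 2 * params.disc_radius_um,
                "true_onset_h": np.nan,
                "center_x_px": cx,
                "center_y_px": cy,
                "bbox_x": int(np.floor(cx - params.disc_radius_um / px)),
                "bbox_y": int(np.floor(cy - params.disc_radius_um / px)),
                "bbox_w": int(np.ceil(2 * params.disc_radius_um / px)),
                "bbox_h": int(np.ceil(2 * params.disc_radius_um / px)),
                "class_label": params.profile_kind,
            }
        ],
        columns=_TRUTH_COLUMNS,
    )
    meta = {"profile_kind": params.profile_kind, "profile_scale_um": params.profile_scale_um}
    return CalibratedImage(img, px, channel="zdisc", meta=meta), truth


def make_expression_timecourse(
    params: ExpressionSimParams,
) -> tuple[IsoformExpressionSet, pd.DataFrame]:
    """Simulate per-transcript TPM trajectories with class-specific onsets.

    Each transcript's noise-free mean is
    ``plateau / (1 + exp(-(t - onset) / sharpness))``; multiplicative
    log-normal noise is applied when ``lognormal_sd > 0``. Growing
    transcripts are assigned 2–4 LIM domains, blocking transcripts 0–1.
    """
    t = np.asarray(params.timepoints_h, dtype=float)
    rng = np.random.default_rng(params.seed)
    ids, rec_rows, tpm_rows, truth_rows = [], [], [], []
    specs = [
        ("growing", params.n_growing, params.onset_growing_h, params.plateau_tpm_growing, (2, 3, 4)),
        ("blocking", params.n_blocking, params.onset_blocking_h, params.plateau_tpm_blocking, (0, 1)),
    ]
    for label, n, onset, plateau, lim_choices in specs:
        for j in range(n):
            tid = f"{label[0].upper()}T{j:03d}"
            mean = plateau / (1.0 + np.exp(-(t - onset) / params.onset_sharpness_h))
            if params.lognormal_sd > 0:
                tpm = mean * np.exp(rng.normal(0.0, params.lognormal_sd, size=t.size))
            else:
                tpm = mean.copy()
            ids.append(tid)
            tpm_rows.append(tpm)
            rec_rows.append(
                {
                    "transcript_id": tid,
                    "gene": "Zasp52" if label == "growing" else "Zasp66",
                    "n_lim": int(lim_choices[j % len(lim_choices)]),
                    "has_zm": True,
                    "has_pdz": label == "growing",
                }
            )
            truth_rows.append(
                {
                    "object_kind": "transcript",
                    "object_id": tid,
                    "true_diameter_um": np.nan,
                    "true_onset_h": onset,
                    "center_x_px": np.nan,
                    "center_y_px": np.nan,
                    "bbox_x": np.nan,
                    "bbox_y": np.nan,
                    "bbox_w": np.nan,
                    "bbox_h": np.nan,
                    "class_label": label,
                }
            )
    tpm = pd.DataFrame(np.asarray(tpm_rows).reshape(len(ids), t.size), index=ids, columns=t)
    records = pd.DataFrame(
        rec_rows, columns=["transcript_id", "gene", "n_lim", "has_zm", "has_pdz"]
    )
    truth = pd.DataFrame(truth_rows, columns=_TRUTH_COLUMNS)
    return IsoformExpressionSet(tpm=tpm, records=records), truth
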