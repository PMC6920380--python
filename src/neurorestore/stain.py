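"""DAB/TH+ immunoreactivity quantification for brightfield histology.

The readout of interest is the fraction of each region of interest (ROI)
covered by dark DAB chromogen marking tyrosine-hydroxylase-positive (TH+)
tissue, and the ratio of that fraction between the treated (ipsilateral)
and untreated (contralateral) hemispheres.

Processing chain per section image:

1. white balance — estimate the white point I0 per channel from an upper
   intensity percentile and rescale so it maps to 255;
2. optical density transform — Beer–Lambert, ``OD_c = -log10(I_c / I0_c)``;
3. color deconvolution — invert the stain matrix (hematoxylin, DAB,
   residual) per pixel to obtain stain concentration channels;
4. grayscale conversion — affine, order-reversing map of the DAB channel
   so that *lower* gray means *more* DAB, as in threshold-below schemes;
5. adaptive threshold — per region and per section, pool the ipsilateral
   and contralateral ROI pixels and set ``T = mean - 0.5 * SD`` (sample
   SD); this adapts to section-to-section DAB development differences;
6. area fraction — count pixels strictly below T, normalized to ROI area;
7. per-mouse summary — average per-section fractions per hemisphere, then
   take the ratio of the two means (ratio of means, not mean of ratios).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "StainMatrix",
    "SectionImage",
    "RoiQuant",
    "MouseQuant",
    "white_balance",
    "rgb_to_od",
    "deconvolve",
    "dab_gray",
    "gray_to_dab",
    "pooled_threshold",
    "th_area",
    "area_ratio",
    "quantify_section",
    "mouse_summary",
    "quantify_study",
]

# Standard H-DAB optical-density stain directions (unit vectors over R,G,B).
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
DAB_OD = (0.269, 0.568, 0.778)


class DegenerateStainMatrixError(ValueError):
    """Raised when the stain basis cannot be inverted reliably."""


@dataclass(frozen=True)
class StainMatrix:
    """Orthonormal-ish stain basis for color deconvolution.

    Rows of :attr:`matrix` are the optical-density directions of
    hematoxylin, DAB and a residual stain over (R, G, B). Each vector has
    unit Euclidean norm; the two real stains are non-negative.
    """

    hematoxylin: tuple[float, float, float]
    dab: tuple[float, float, float]
    residual: tuple[float, float, float]

    def __post_init__(self) -> None:
        m = self.matrix
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"stain vectors must have unit norm, got {norms}")
        if np.any(m[:2] < -1e-12):
            raise ValueError("hematoxylin and DAB vectors must be non-negative")
        if not np.all(np.isfinite(m)):
            raise DegenerateStainMatrixError("non-finite stain vector")
        if np.linalg.cond(m) > 1e8:
            raise DegenerateStainMatrixError(
                f"stain matrix is ill-conditioned (cond={np.linalg.cond(m):.3g})"
            )

    @property
    def matrix(self) -> np.ndarray:
        """3x3 array; row i is stain i's OD direction over (R, G, B)."""
        return np.array([self.hematoxylin, self.dab, self.residual], dtype=float)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @classmethod
    def h_dab(cls) -> "StainMatrix":
        """Default hematoxylin + DAB basis with residual = normalized cross product."""
        h = np.asarray(HEMATOXYLIN_OD, dtype=float)
        d = np.asarray(DAB_OD, dtype=float)
        h = h / np.linalg.norm(h)
        d = d / np.linalg.norm(d)
        r = np.cross(h, d)
        r = r / np.linalg.norm(r)
        return cls(tuple(h), tuple(d), tuple(r))

    @classmethod
    def identity(cls) -> "StainMatrix":
        return cls((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))


@dataclass
class SectionImage:
    """One coronal section: RGB image, ROI label mask, identifiers.

    ``legend`` maps integer mask labels to ``(region, hemisphere)`` pairs,
    e.g. ``{1: ("striatum", "ipsi"), 2: ("striatum", "contra")}``.
    Hemispheres are named ``"ipsi"`` (treated) and ``"contra"``.
    """

    image: np.ndarray
    mask: np.ndarray
    legend: Mapping[int, tuple[str, str]]
    section_id: str = ""
    mouse_id: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be (H, W, 3), got {self.image.shape}")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError(
                f"mask shape {self.mask.shape} != image shape {self.image.shape[:2]}"
            )
        present = set(np.unique(self.mask)) - {0}
        unknown = present - set(int(k) for k in self.legend)
        if unknown:
            raise ValueError(f"mask labels {sorted(unknown)} missing from legend")
        for label in self.legend:
            if int(label) not in present:
                raise ValueError(f"legend label {label} has no pixels in mask")

    @property
    def regions(self) -> set[str]:
        return {region for region, _ in self.legend.values()}

    def roi_pixels(self, values: np.ndarray, region: str, hemisphere: str) -> np.ndarray:
        """Flat array of ``values`` at pixels of the given ROI."""
        labels = [
            int(lab)
            for lab, (reg, hemi) in self.legend.items()
            if reg == region and hemi == hemisphere
        ]
        if not labels:
            raise KeyError(f"no ROI labelled ({region}, {hemisphere})")
        sel = np.isin(self.mask, labels)
        return np.asarray(values)[sel]


@dataclass(frozen=True)
class RoiQuant:
    """Per-ROI quantification result for one section."""

    region: str
    hemisphere: str
    section_id: str
    mouse_id: str
    threshold: float
    th_pixels: int
    roi_pixels: int

    def __post_init__(self) -> None:
        if self.roi_pixels <= 0:
            raise ValueError("ROI must be non-empty")
        if not 0 <= self.th_pixels <= self.roi_pixels:
            raise ValueError("TH+ count must lie in [0, ROI size]")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    @property
    def fraction(self) -> float:
        return self.th_pixels / self.roi_pixels


@dataclass(frozen=True)
class MouseQuant:
    """Per-mouse, per-region summary: hemisphere means and their ratio."""

    mouse_id: str
    region: str
    ipsi_mean: float
    contra_mean: float
    n_sections: int

    @property
    def ratio(self) -> float:
        return area_ratio(self.ipsi_mean, self.contra_mean)


def white_balance(
    image: np.ndarray, percentile: float = 99.0
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale each channel so its upper ``percentile`` maps to 255.

    Returns ``(balanced, white_point)`` where ``white_point`` is the
    estimated per-channel I0 of the *input* image — feed it to
    :func:`rgb_to_od` on the original image to avoid double quantization.
    """
    if not 50.0 < percentile <= 100.0:
        raise ValueError(f"percentile must be in (50, 100], got {percentile}")
    arr = np.asarray(image, dtype=float)
    white = np.percentile(arr.reshape(-1, 3), percentile, axis=0)
    if np.any(white <= 0):
        raise ValueError("white point undefined: a channel is uniformly zero")
    balanced = np.clip(arr * (255.0 / white), 0.0, 255.0)
    return balanced, white


def rgb_to_od(
    image: np.ndarray, white_point: Sequence[float], eps: float = 1.0
) -> np.ndarray:
    """Beer–Lambert optical density, ``OD_c = -log10(max(I_c, eps) / I0_c)``.

    ``eps`` (one intensity unit by default) guards the logarithm at zero,
    so a fully dark pixel maps to the finite ``log10(I0 / eps)``.
    """
    i0 = np.asarray(white_point, dtype=float)
    if np.any(i0 <= 0):
        raise ValueError("white point must be positive per channel")
    arr = np.maximum(np.asarray(image, dtype=float), eps)
    return -np.log10(arr / i0)


def deconvolve(od_image: np.ndarray, stains: StainMatrix) -> np.ndarray:
    """Per-pixel stain concentrations (hematoxylin, DAB, residual).

    Solves ``OD = C @ M`` for C with M the stain matrix; negative
    concentrations (noise outside the stain cone) are clipped to zero.
    """
    conc = np.asarray(od_image, dtype=float) @ stains.inverse
    return np.clip(conc, 0.0, None)


def dab_gray(
    dab_channel: np.ndarray, od_max: float = 2.0, g_max: float = 255.0
) -> np.ndarray:
    """Affine, order-reversing grayscale map of the DAB channel.

    ``gray = g_max - (g_max / od_max) * dab``: zero DAB maps to ``g_max``
    and heavier DAB maps darker, so "dark DAB pixels" fall below an
    intensity threshold. The map is left unclipped to stay invertible;
    concentrations above ``od_max`` map below zero.
    """
    if od_max <= 0:
        raise ValueError("od_max must be positive")
    dab = np.asarray(dab_channel, dtype=float)
    if not np.all(np.isfinite(dab)):
        raise ValueError("DAB channel must be finite")
    return g_max - (g_max / od_max) * dab


def gray_to_dab(gray: np.ndarray, od_max: float = 2.0, g_max: float = 255.0) -> np.ndarray:
    """Exact inverse of :func:`dab_gray`."""
    return (g_max - np.asarray(gray, dtype=float)) * (od_max / g_max)


def pooled_threshold(ipsi_pixels: np.ndarray, contra_pixels: np.ndarray) -> float:
    """Adaptive ROI threshold: pooled mean minus half the pooled sample SD.

    Ipsilateral and contralateral pixels of one region in one section are
    combined; the threshold adapts to that section's DAB development.
    The SD uses the n-1 (sample) denominator.
    """
    pooled = np.concatenate(
        [np.asarray(ipsi_pixels, dtype=float).ravel(),
         np.asarray(contra_pixels, dtype=float).ravel()]
    )
    if pooled.size < 2:
        raise ValueError("pooled threshold needs at least 2 pixels")
    return float(pooled.mean() - 0.5 * pooled.std(ddof=1))


def th_area(
    roi_pixels: np.ndarray,
    threshold: float,
    *,
    region: str = "",
    hemisphere: str = "",
    section_id: str = "",
    mouse_id: str = "",
) -> RoiQuant:
    """TH+ area of one ROI: pixels strictly below the threshold.

    Boundary pixels (== threshold) are excluded ("below the threshold").
    """
    vals = np.asarray(roi_pixels, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("empty ROI")
    return RoiQuant(
        region=region,
        hemisphere=hemisphere,
        section_id=section_id,
        mouse_id=mouse_id,
        threshold=float(threshold),
        th_pixels=int(np.count_nonzero(vals < threshold)),
        roi_pixels=int(vals.size),
    )


def area_ratio(ipsi_fraction: float, contra_fraction: float) -> float:
    """Ipsilateral / contralateral TH+ area ratio."""
    if contra_fraction <= 0:
        raise ZeroDivisionError(
            "area ratio undefined: contralateral fraction is zero"
        )
    return float(ipsi_fraction) / float(contra_fraction)


def quantify_section(
    section: SectionImage,
    *,
    stains: StainMatrix | None = None,
    percentile: float = 99.0,
    od_max: float = 2.0,
    eps: float = 1.0,
) -> list[RoiQuant]:
    """Run the full chain on one section; one :class:`RoiQuant` per ROI.

    A single threshold per region is computed from the pooled
    ipsilateral + contralateral pixels, then applied to each hemisphere.
    """
    stains = stains or StainMatrix.h_dab()
    _, white = white_balance(section.image, percentile)
    od = rgb_to_od(section.image, white, eps=eps)
    dab = deconvolve(od, stains)[..., 1]
    gray = dab_gray(dab, od_max=od_max)
    out: list[RoiQuant] = []
    for region in sorted(section.regions):
        ipsi = section.roi_pixels(gray, region, "ipsi")
        contra = section.roi_pixels(gray, region, "contra")
        t = pooled_threshold(ipsi, contra)
        for hemi, pix in (("ipsi", ipsi), ("contra", contra)):
            out.append(
                th_area(
                    pix,
                    t,
                    region=region,
                    hemisphere=hemi,
                    section_id=section.section_id,
                    mouse_id=section.mouse_id,
                )
            )
    return out


def mouse_summary(quants: Sequence[RoiQuant]) -> list[MouseQuant]:
    """Per-region summary for one mouse.

    The per-section area fractions are averaged per hemisphere
    (unweighted over sections), and the ratio is the ratio of the two
    means — not the mean of per-section ratios, which is unstable when a
    contralateral fraction is small.
    """
    mice = {q.mouse_id for q in quants}
    if len(mice) != 1:
        raise ValueError(f"expected quants from exactly one mouse, got {sorted(mice)}")
    (mouse_id,) = mice
    out: list[MouseQuant] = []
    for region in sorted({q.region for q in quants}):
        ipsi = [q.fraction for q in quants if q.region == region and q.hemisphere == "ipsi"]
        contra = [
            q.fraction for q in quants if q.region == region and q.hemisphere == "contra"
        ]
        if not ipsi or not contra:
            raise ValueError(
                f"region {region!r} has sections on one hemisphere only"
            )
        out.append(
            MouseQuant(
                mouse_id=mouse_id,
                region=region,
                ipsi_mean=float(np.mean(ipsi)),
                contra_mean=float(np.mean(contra)),
                n_sections=len(ipsi),
            )
        )
    return out


def quantify_study(
    sections: Iterable[SectionImage],
    *,
    stains: StainMatrix | None = None,
    percentile: float = 99.0,
    od_max: float = 2.0,
):
    """Quantify many sections; returns (per-section, per-mouse) DataFrames."""
    import pandas as pd

    quants: list[RoiQuant] = []
    for sec in sections:
        quants.extend(
            quantify_section(sec, stains=stains, percentile=percentile, od_max=od_max)
        )
    sec_df = pd.DataFrame(
        {
            "mouse": q.mouse_id,
            "region": q.region,
            "hemisphere": q.hemisphere,
            "section": q.section_id,
            "threshold": q.threshold,
            "th_pixels": q.th_pixels,
            "roi_pixels": q.roi_pixels,
            "fraction": q.fraction,
        }
        for q in quants
    )
    rows = []
    for mouse in sorted({q.mouse_id for q in quants}):
        for mq in mouse_summary([q for q in quants if q.mouse_id == mouse]):
            rows.append(
                {
                    "mouse": mq.mouse_id,
                    "region": mq.region,
                    "ipsi_mean": mq.ipsi_mean,
                    "contra_mean": mq.contra_mean,
                    "ratio": mq.ratio,
                }
            )
    return sec_df, pd.DataFrame(rows)
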