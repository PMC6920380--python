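"""Forward simulators with exact ground truth for every pipeline stage.

Each generator builds data by the *inverse* of the corresponding analysis
model, so recovery tests have an exact oracle:

* :func:`gen_histology` — Beer–Lambert forward model of an H-DAB-stained
  section (``I_c = I0_c * 10**(-OD_c)``, OD mixed through the stain
  matrix), with an exact simulated TH+ pixel fraction per ROI;
* :func:`gen_pcd` — passive-cavitation-detection pulses as a sum of
  harmonic tones (n*f0), ultraharmonic tones ((n+1/2)*f0), band-limited
  Gaussian broadband emission (the inertial component) and white sensor
  noise, each with analytic RMS;
* :func:`gen_rotation` — heading traces completing a requested number of
  clockwise then counterclockwise full turns plus bounded jitter;
* :func:`gen_group_study` — fraction-level simulation of a multi-group
  hemisphere study with a configurable ipsilateral effect;
* :func:`session_dose` — the intranasal dosing arithmetic used to
  parameterize the study (droplet volume x concentration x schedule).

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .stain import SectionImage, StainMatrix

__all__ = [
    "StainMatrix",
    "RoiSpec",
    "HistologySimConfig",
    "HistologySample",
    "gen_histology",
    "default_rois",
    "PcdSimConfig",
    "PcdDataset",
    "gen_pcd",
    "RotationSimConfig",
    "gen_rotation",
    "gen_group_study",
    "DoseSpec",
    "DoseReport",
    "session_dose",
    "BDNF_INTRANASAL_DOSE",
]

HEMISPHERES = ("ipsi", "contra")


# --------------------------------------------------------------------------
# Histology
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiSpec:
    """Axis-aligned rectangular ROI (row/col half-open bounds)."""

    region: str
    hemisphere: str
    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError("ROI rectangle must be non-empty")

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    def overlaps(self, other: "RoiSpec") -> bool:
        return (
            self.row0 < other.row1
            and other.row0 < self.row1
            and self.col0 < other.col1
            and other.col0 < self.col1
        )


def default_rois(
    shape: tuple[int, int] = (128, 128), regions: Sequence[str] = ("striatum",)
) -> tuple[RoiSpec, ...]:
    """Stacked rectangular ROIs: ipsi in the left half, contra in the right.

    Mirrors the study's convention of the treated (ipsilateral) left
    hemisphere; with ``regions=("SNc", "SNr")`` the rectangles are stacked
    vertically within each hemisphere.
    """
    h, w = shape
    n = len(regions)
    margin_r, margin_c = max(4, h // 8), max(4, w // 8)
    band = (h - 2 * margin_r) // n
    rois = []
    for i, region in enumerate(regions):
        r0, r1 = margin_r + i * band, margin_r + (i + 1) * band - 2
        rois.append(RoiSpec(region, "ipsi", r0, r1, margin_c, w // 2 - 2))
        rois.append(RoiSpec(region, "contra", r0, r1, w // 2 + 2, w - margin_c))
    return tuple(rois)


@dataclass(frozen=True)
class HistologySimConfig:
    """Parameters of the synthetic H-DAB section.

    ``fractions`` maps ``(region, hemisphere)`` to the TH+ pixel fraction
    in [0, 1]. TH+ pixels carry ``dab_od`` optical density of DAB on top
    of a uniform hematoxylin background (``hema_od``); pixels outside all
    ROIs are clear glass at the white point. ``noise_sd`` is additive
    Gaussian noise (OD units, per channel) applied to tissue pixels only,
    modelling stain heterogeneity. ``quantize=False`` keeps float
    intensities for exact round-trip tests.
    """

    shape: tuple[int, int] = (128, 128)
    rois: tuple[RoiSpec, ...] = ()
    fractions: Mapping[tuple[str, str], float] = field(default_factory=dict)
    dab_od: float = 1.0
    hema_od: float = 0.3
    noise_sd: float = 0.0
    white_point: tuple[float, float, float] = (255.0, 255.0, 255.0)
    quantize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        rois = self.rois or default_rois(self.shape)
        object.__setattr__(self, "rois", tuple(rois))
        if not self.fractions:
            object.__setattr__(
                self,
                "fractions",
                {(r.region, r.hemisphere): 0.2 for r in rois},
            )
        h, w = self.shape
        for roi in self.rois:
            if not (0 <= roi.row0 < roi.row1 <= h and 0 <= roi.col0 < roi.col1 <= w):
                raise ValueError(f"ROI {roi} outside image bounds {self.shape}")
            if (roi.region, roi.hemisphere) not in self.fractions:
                raise ValueError(f"no fraction given for {(roi.region, roi.hemisphere)}")
        for i, a in enumerate(self.rois):
            for b in self.rois[i + 1:]:
                if a.overlaps(b):
                    raise ValueError(f"overlapping ROIs: {a} and {b}")
        for key, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction for {key} outside [0, 1]: {f}")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.dab_od < 0 or self.hema_od < 0:
            raise ValueError("OD amplitudes must be >= 0")
        if not all(0 < c <= 255 for c in self.white_point):
            raise ValueError("white point must lie in (0, 255] per channel")


@dataclass
class HistologySample:
    """Generated section plus everything needed for recovery oracles."""

    image: np.ndarray                      # (H, W, 3) uint8 or float
    mask: np.ndarray                       # (H, W) uint16, 0 = background
    legend: dict[int, tuple[str, str]]
    truth_fractions: dict[tuple[str, str], float]   # exact simulated fraction
    concentrations: np.ndarray             # (H, W, 3) noise-free stain conc.
    config: HistologySimConfig
    stains: StainMatrix
    section_id: str = ""
    mouse_id: str = ""

    def as_section(self) -> SectionImage:
        return SectionImage(
            image=self.image,
            mask=self.mask,
            legend=self.legend,
            section_id=self.section_id,
            mouse_id=self.mouse_id,
        )

    @property
    def truth_ratios(self) -> dict[str, float]:
        """Ipsi/contra ratio of the exact simulated fractions per region."""
        regions = {r for r, _ in self.truth_fractions}
        return {
            reg: self.truth_fractions[(reg, "ipsi")] / self.truth_fractions[(reg, "contra")]
            for reg in regions
            if self.truth_fractions[(reg, "contra")] > 0
        }


def gen_histology(
    config: HistologySimConfig,
    stains: StainMatrix | None = None,
    *,
    section_id: str = "",
    mouse_id: str = "",
) -> HistologySample:
    """Simulate one H-DAB section with exact per-ROI TH+ fractions.

    TH+ pixels are drawn as a spatially random subset of each ROI at the
    requested fraction (rounded to a whole pixel count, which is the
    stored exact truth). The RGB image follows the Beer–Lambert model
    with the given stain basis.
    """
    stains = stains or StainMatrix.h_dab()
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    conc = np.zeros((h, w, 3), dtype=float)      # (hema, dab, residual)
    mask = np.zeros((h, w), dtype=np.uint16)
    legend: dict[int, tuple[str, str]] = {}
    truth: dict[tuple[str, str], float] = {}

    for label, roi in enumerate(config.rois, start=1):
        rs, cs = roi.slices
        mask[rs, cs] = label
        legend[label] = (roi.region, roi.hemisphere)
        n = (roi.row1 - roi.row0) * (roi.col1 - roi.col0)
        frac = config.fractions[(roi.region, roi.hemisphere)]
        k = int(round(frac * n))
        chosen = rng.choice(n, size=k, replace=False)
        block = np.zeros(n)
        block[chosen] = config.dab_od
        conc[rs, cs, 1] = block.reshape(roi.row1 - roi.row0, roi.col1 - roi.col0)
        truth[(roi.region, roi.hemisphere)] = k / n

    tissue = mask > 0
    conc[tissue, 0] = config.hema_od

    od = conc @ stains.matrix
    if config.noise_sd > 0:
        od[tissue] += rng.normal(0.0, config.noise_sd, size=(int(tissue.sum()), 3))
    image = np.asarray(config.white_point) * np.power(10.0, -od)
    image = np.clip(image, 0.0, 255.0)
    if config.quantize:
        image = np.round(image).astype(np.uint8)
    return HistologySample(
        image=image,
        mask=mask,
        legend=legend,
        truth_fractions=truth,
        concentrations=conc,
        config=config,
        stains=stains,
        section_id=section_id,
        mouse_id=mouse_id,
    )


# --------------------------------------------------------------------------
# Passive cavitation detection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PcdSimConfig:
    """Synthetic PCD pulse train.

    ``harmonics`` maps n to the amplitude of a tone at ``n * f0``;
    ``ultraharmonics`` maps n to the amplitude at ``(n + 1/2) * f0``.
    ``broadband_sd`` sets the in-band RMS of the Gaussian broadband
    (inertial) component, band-limited to ``band``; ``sensor_sd`` is
    full-band white sensor noise.
    """

    f0: float = 1.5e6
    fs: float = 50e6
    duration: float = 2e-4
    harmonics: Mapping[int, float] = field(default_factory=dict)
    ultraharmonics: Mapping[int, float] = field(default_factory=dict)
    broadband_sd: float = 0.0
    sensor_sd: float = 0.0
    band: tuple[float, float] = (3e6, 9e6)
    n_pulses: int = 1
    microbubbles: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0 <= 0 or self.fs <= 0 or self.duration <= 0:
            raise ValueError("f0, fs and duration must be positive")
        if self.n_pulses < 1:
            raise ValueError("need at least one pulse")
        if any(a < 0 for a in self.harmonics.values()) or any(
            a < 0 for a in self.ultraharmonics.values()
        ):
            raise ValueError("tone amplitudes must be >= 0")
        if self.broadband_sd < 0 or self.sensor_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        top = max(
            [n * self.f0 for n in self.harmonics]
            + [(n + 0.5) * self.f0 for n in self.ultraharmonics]
            + [self.band[1] if self.broadband_sd > 0 else 0.0]
        or [0.0])
        if top >= self.fs / 2:
            raise ValueError(
                f"aliasing: component at {top:.3g} Hz >= Nyquist {self.fs / 2:.3g} Hz"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def tone_frequencies(self) -> dict[str, dict[float, float]]:
        """``{"harmonic": {freq: amp}, "ultraharmonic": {freq: amp}}``."""
        return {
            "harmonic": {n * self.f0: a for n, a in self.harmonics.items()},
            "ultraharmonic": {(n + 0.5) * self.f0: a for n, a in self.ultraharmonics.items()},
        }


@dataclass
class PcdDataset:
    """Generated pulse train with per-component analytic RMS ground truth."""

    pulses: list            # list[pcd.PulseRecord]
    config: PcdSimConfig

    @property
    def harmonic_rms(self) -> float:
        """Root-sum-square RMS of all harmonic tones (A/sqrt(2) each)."""
        return math.sqrt(sum(a * a / 2.0 for a in self.config.harmonics.values()))

    @property
    def ultraharmonic_rms(self) -> float:
        return math.sqrt(sum(a * a / 2.0 for a in self.config.ultraharmonics.values()))

    @property
    def broadband_rms(self) -> float:
        """Analytic in-band RMS of the broadband (inertial) component."""
        return self.config.broadband_sd

    def expected_doses(self, plan) -> dict[str, float]:
        """Analytic SCDh/SCDu/ICD for this configuration under ``plan``.

        Tone energy lands in the window containing its frequency; the
        broadband component contributes its flat spectral density to every
        window overlapping the band; sensor noise contributes its density
        over the whole Nyquist range.
        """
        lo, hi = self.config.band
        bb_density = (
            self.broadband_rms ** 2 / (hi - lo) if self.broadband_rms > 0 else 0.0
        )
        sn_density = self.config.sensor_sd ** 2 / (self.config.fs / 2)

        def window_power(windows, tones):
            power = 0.0
            for wlo, whi in windows:
                olap = max(0.0, min(whi, hi) - max(wlo, lo))
                power += bb_density * olap + sn_density * (whi - wlo)
                for f, a in tones.items():
                    if wlo <= f < whi:
                        power += a * a / 2.0
            return power

        tones = self.tone_map()
        all_tones = {**tones["harmonic"], **tones["ultraharmonic"]}
        scdh = window_power(plan.harmonic_windows, all_tones)
        scdu = window_power(plan.ultraharmonic_windows, all_tones)
        # ICD region: analysis band minus all tone windows.
        windows = sorted(list(plan.harmonic_windows) + list(plan.ultraharmonic_windows))
        covered = sum(max(0.0, min(whi, hi) - max(wlo, lo)) for wlo, whi in windows)
        icd_width = (hi - lo) - covered
        icd = bb_density * icd_width + sn_density * icd_width
        for f, a in all_tones.items():
            if lo <= f < hi and not any(wlo <= f < whi for wlo, whi in windows):
                icd += a * a / 2.0
        return {
            "scdh": math.sqrt(scdh),
            "scdu": math.sqrt(scdu),
            "icd": math.sqrt(icd),
        }

    def tone_map(self) -> dict[str, dict[float, float]]:
        return self.config.tone_frequencies()


def gen_pcd(config: PcdSimConfig) -> PcdDataset:
    """Simulate a PCD pulse train with analytic per-component RMS.

    Tones get independent random phases per pulse. The broadband
    component is white Gaussian noise band-limited to ``config.band`` by
    spectral masking and scaled so its expected in-band RMS equals
    ``broadband_sd``.
    """
    from .pcd import PulseRecord

    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    if n < 64:
        raise ValueError("pulse too short: need >= 64 samples")
    t = np.arange(n) / config.fs
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs)
    lo, hi = config.band
    band_mask = (freqs >= lo) & (freqs < hi)
    n_kept = int(band_mask.sum())

    pulses = []
    tones = config.tone_frequencies()
    for i in range(config.n_pulses):
        x = np.zeros(n)
        for fam in ("harmonic", "ultraharmonic"):
            for f, a in tones[fam].items():
                if a > 0:
                    x += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        if config.broadband_sd > 0 and n_kept > 0:
            white = rng.normal(0.0, 1.0, size=n)
            spec = np.fft.rfft(white)
            spec[~band_mask] = 0.0
            bb = np.fft.irfft(spec, n)
            bb *= config.broadband_sd / math.sqrt(2.0 * n_kept / n)
            x += bb
        if config.sensor_sd > 0:
            x += rng.normal(0.0, config.sensor_sd, size=n)
        pulses.append(
            PulseRecord(
                samples=x, fs=config.fs, index=i, microbubbles=config.microbubbles
            )
        )
    return PcdDataset(pulses=pulses, config=config)


# --------------------------------------------------------------------------
# Rotation traces
# --------------------------------------------------------------------------

MAX_JITTER_CLIP_DEG = 85.0      # keeps every excursion < 90 deg off the true path


@dataclass(frozen=True)
class RotationSimConfig:
    """Heading trace completing ``cw_turns`` then ``ccw_turns`` full turns.

    Clockwise is decreasing heading. Gaussian jitter (clipped at
    4 SD <= 85 deg) is added to the cumulative angle; jitter SDs above
    85/4 deg are rejected because they could produce spurious threshold
    crossings in the turn counter.
    """

    cw_turns: int = 0
    ccw_turns: int = 0
    duration_s: float = 60.0
    fs: float = 30.0
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cw_turns < 0 or self.ccw_turns < 0:
            raise ValueError("turn counts must be non-negative integers")
        if int(self.cw_turns) != self.cw_turns or int(self.ccw_turns) != self.ccw_turns:
            raise ValueError("turn counts must be integers")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter SD must be >= 0")
        if 4.0 * self.jitter_sd > MAX_JITTER_CLIP_DEG:
            raise ValueError(
                f"jitter SD {self.jitter_sd} deg violates the no-spurious-crossing "
                f"bound (4*SD must be <= {MAX_JITTER_CLIP_DEG} deg)"
            )


def gen_rotation(config: RotationSimConfig):
    """Simulate a heading trace; returns ``(RotationTrace, RotationCounts)``.

    With jitter the true cumulative path overshoots each turn boundary by
    (jitter clip + 5 deg) so the accumulator counter recovers the ground
    truth exactly; with zero jitter the path hits the boundaries exactly
    (a pure CW trace is monotone spanning -360 * cw_turns degrees).
    """
    from .behavior import RotationCounts, RotationTrace

    rng = np.random.default_rng(config.seed)
    n = max(int(round(config.duration_s * config.fs)), 2)
    clip = min(4.0 * config.jitter_sd, MAX_JITTER_CLIP_DEG)
    m = 0.0 if config.jitter_sd == 0 else clip + 5.0

    waypoints = [0.0]
    if config.cw_turns > 0:
        waypoints.append(-360.0 * config.cw_turns - m)
    if config.ccw_turns > 0:
        start = waypoints[-1]
        waypoints.append(start + 360.0 * config.ccw_turns + m + (m if config.cw_turns else 0))
    arcs = np.abs(np.diff(waypoints))
    total = arcs.sum()
    tt = np.linspace(0.0, 1.0, n)
    if total == 0:
        theta = np.zeros(n)
    else:
        # piecewise-linear path through the waypoints, parameterized by arc length
        knots = np.concatenate([[0.0], np.cumsum(arcs)]) / total
        theta = np.interp(tt, knots, waypoints)
    if config.jitter_sd > 0:
        theta = theta + np.clip(
            rng.normal(0.0, config.jitter_sd, size=n), -clip, clip
        )
    time_s = np.arange(n) / config.fs
    trace = RotationTrace(time_s=time_s, heading_deg=theta % 360.0)
    truth = RotationCounts(cw=int(config.cw_turns), ccw=int(config.ccw_turns))
    return trace, truth


# --------------------------------------------------------------------------
# Group-level study simulation (fraction level)
# --------------------------------------------------------------------------

def gen_group_study(
    *,
    n_per_group: Mapping[str, int] | None = None,
    treated_group: str = "IN+FUS",
    effect: float = 1.2,
    regions: Sequence[str] = ("striatum",),
    n_sections: int = 6,
    base_fraction: float = 0.20,
    mouse_sd: float = 0.03,
    section_sd: float = 0.01,
    seed: int = 0,
):
    """Simulate per-section TH+ fractions for a multi-group study.

    Each mouse draws a contralateral baseline fraction from
    ``N(base_fraction, mouse_sd)``; its ipsilateral mean is the baseline
    times ``effect`` in the treated group and identical elsewhere. Section
    readings add ``N(0, section_sd)`` noise. Group sizes default to the
    study design (MPTP-only 7, FUS-only 6, IN+FUS 7).

    Returns a tidy DataFrame with columns
    ``mouse, group, region, section, ipsi, contra``.
    """
    import pandas as pd

    if n_per_group is None:
        n_per_group = {"MPTP": 7, "FUS": 6, "IN+FUS": 7}
    if treated_group not in n_per_group:
        raise ValueError(f"treated group {treated_group!r} not in {list(n_per_group)}")
    if effect <= 0 or base_fraction <= 0:
        raise ValueError("effect and base fraction must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for group, n_mice in n_per_group.items():
        for i in range(n_mice):
            mouse = f"{group}-{i + 1:02d}"
            contra_mean = max(rng.normal(base_fraction, mouse_sd), 0.02)
            ipsi_mean = contra_mean * (effect if group == treated_group else 1.0)
            for region in regions:
                for s in range(n_sections):
                    rows.append(
                        {
                            "mouse": mouse,
                            "group": group,
                            "region": region,
                            "section": f"s{s + 1}",
                            "ipsi": float(
                                np.clip(ipsi_mean + rng.normal(0, section_sd), 0, 1)
                            ),
                            "contra": float(
                                np.clip(contra_mean + rng.normal(0, section_sd), 0, 1)
                            ),
                        }
                    )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Dosing arithmetic
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseSpec:
    """Intranasal dosing schedule.

    ``droplet_count`` overrides the schedule-derived count
    (``floor(duration / interval)``) when given; droplet timing is
    otherwise metadata only — delivered mass is volume x concentration.
    """

    droplet_volume_ul: float = 3.0
    interval_min: float = 2.0
    duration_min: float = 20.0
    concentration_mg_ml: float = 16.67
    sessions: int = 3
    droplet_count: int | None = None

    def __post_init__(self) -> None:
        if self.droplet_volume_ul < 0:
            raise ValueError("droplet volume must be >= 0")
        if min(self.interval_min, self.duration_min, self.concentration_mg_ml) <= 0:
            raise ValueError("interval, duration and concentration must be positive")
        if self.sessions <= 0:
            raise ValueError("sessions must be positive")
        if self.droplet_count is not None and self.droplet_count < 0:
            raise ValueError("droplet count must be >= 0")


@dataclass(frozen=True)
class DoseReport:
    droplets_per_session: int
    volume_per_session_ul: float
    mass_per_session_mg: float
    mass_per_study_mg: float


#: The study's schedule: 3 uL droplets to alternating nares, 24 uL total
#: per session at 16.67 mg/mL (~0.4 mg/session), three weekly sessions
#: (~1.2 mg total).
BDNF_INTRANASAL_DOSE = DoseSpec(
    droplet_volume_ul=3.0,
    interval_min=2.0,
    duration_min=20.0,
    concentration_mg_ml=16.67,
    sessions=3,
    droplet_count=8,
)


def session_dose(spec: DoseSpec) -> DoseReport:
    """Delivered protein mass per session and per study, in mg.

    mass/session = droplets x droplet volume (uL) x concentration (mg/mL)
    / 1000; droplets default to ``floor(duration / interval)``.
    """
    droplets = (
        spec.droplet_count
        if spec.droplet_count is not None
        else int(spec.duration_min // spec.interval_min)
    )
    volume_ul = droplets * spec.droplet_volume_ul
    mass_mg = volume_ul / 1000.0 * spec.concentration_mg_ml
    return DoseReport(
        droplets_per_session=droplets,
        volume_per_session_ul=volume_ul,
        mass_per_session_mg=mass_mg,
        mass_per_study_mg=mass_mg * spec.sessions,
    )
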