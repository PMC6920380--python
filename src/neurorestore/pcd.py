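"""Passive cavitation detection (PCD) dose metrics.

During focused-ultrasound blood–brain-barrier opening, circulating
microbubbles emit acoustic signatures recorded by a passive detector.
Per pulse, three metrics summarize microbubble activity in the 3–9 MHz
analysis band (fundamental f0 = 1.5 MHz):

* SCDh — harmonic stable cavitation dose: RMS of the spectral amplitudes
  in narrow windows around the harmonics n*f0;
* SCDu — ultraharmonic stable cavitation dose: same around (n+1/2)*f0;
* ICD — inertial cavitation dose: RMS of the broadband spectral amplitude
  between the harmonic and ultraharmonic windows.

"RMS over a set of bins" is the root-sum-square of RMS-equivalent bin
amplitudes, i.e. the RMS of the band-limited signal itself; over the full
band it equals the time-domain RMS (Parseval). Doses recorded with
microbubbles are normalized to a microbubble-free baseline sonication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PulseRecord",
    "Spectrum",
    "BandPlan",
    "CavitationDose",
    "pulse_spectrum",
    "band_plan",
    "scd",
    "icd",
    "pulse_doses",
    "sonication_summary",
    "normalize_doses",
]

METRICS = ("scdh", "scdu", "icd")


@dataclass
class PulseRecord:
    """One recorded RF pulse."""

    samples: np.ndarray
    fs: float
    index: int = 0
    microbubbles: bool = True

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size < 64:
            raise ValueError(f"pulse too short ({self.samples.size} < 64 samples)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("pulse contains non-finite samples")


@dataclass(frozen=True)
class Spectrum:
    """One-sided amplitude spectrum in RMS-equivalent units.

    ``amplitude[k]`` is scaled so that the root-sum-square over any bin
    set equals the RMS of the signal restricted to those frequencies; a
    sinusoid of amplitude A at a bin frequency contributes A/sqrt(2).
    """

    freqs: np.ndarray
    amplitude: np.ndarray

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def bins_in(self, windows: Sequence[tuple[float, float]]) -> np.ndarray:
        """Boolean selector of bins whose center lies in any [lo, hi)."""
        sel = np.zeros(self.freqs.size, dtype=bool)
        for lo, hi in windows:
            sel |= (self.freqs >= lo) & (self.freqs < hi)
        return sel

    def band_rms(self, windows: Sequence[tuple[float, float]]) -> float:
        return float(np.sqrt(np.sum(self.amplitude[self.bins_in(windows)] ** 2)))


def pulse_spectrum(pulse: PulseRecord, window: str = "rect") -> Spectrum:
    """FFT amplitude spectrum of one pulse.

    With the default rectangular window the spectrum satisfies Parseval
    exactly: the root-sum-square of all bins equals the time-domain RMS.
    ``window="hann"`` applies a coherent-gain-corrected Hann taper, which
    trades Parseval exactness for lower leakage of off-bin tones.
    """
    x = pulse.samples
    n = x.size
    if window == "hann":
        w = np.hanning(n)
        x = x * w / w.mean()
    elif window != "rect":
        raise ValueError(f"unknown window {window!r}")
    spec = np.fft.rfft(x) / n
    weight = np.full(spec.size, 2.0)
    weight[0] = 1.0
    if n % 2 == 0:
        weight[-1] = 1.0
    amplitude = np.sqrt(weight) * np.abs(spec)
    return Spectrum(freqs=np.fft.rfftfreq(n, d=1.0 / pulse.fs), amplitude=amplitude)


@dataclass(frozen=True)
class BandPlan:
    """Frequency windows for the three dose metrics.

    A harmonic/ultraharmonic center is included iff its full window
    [c - half_width, c + half_width] intersects the analysis band;
    windows are clipped to the band edges. ``half_width`` must stay below
    f0/4 so harmonic and ultraharmonic windows cannot touch.
    """

    f0: float = 1.5e6
    f_lo: float = 3e6
    f_hi: float = 9e6
    half_width: float = 1.5e5
    harmonic_centers: tuple[float, ...] = field(default=(), compare=False)
    ultraharmonic_centers: tuple[float, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.f_lo >= self.f_hi:
            raise ValueError("band must satisfy f_lo < f_hi")
        if not 0 < self.half_width < self.f0 / 4:
            raise ValueError(
                f"half-width must lie in (0, f0/4) = (0, {self.f0 / 4:.3g}); "
                f"got {self.half_width:.3g}"
            )
        harm = self._centers(self.f0)
        ultra = self._centers(self.f0, offset=0.5)
        object.__setattr__(self, "harmonic_centers", harm)
        object.__setattr__(self, "ultraharmonic_centers", ultra)

    def _centers(self, f0: float, offset: float = 0.0) -> tuple[float, ...]:
        out = []
        n = 1
        while (n + offset) * f0 - self.half_width < self.f_hi:
            c = (n + offset) * f0
            if c + self.half_width > self.f_lo and c - self.half_width < self.f_hi:
                out.append(c)
            n += 1
        return tuple(out)

    def _windows(self, centers: Iterable[float]) -> tuple[tuple[float, float], ...]:
        return tuple(
            (max(c - self.half_width, self.f_lo), min(c + self.half_width, self.f_hi))
            for c in centers
        )

    @property
    def harmonic_windows(self) -> tuple[tuple[float, float], ...]:
        return self._windows(self.harmonic_centers)

    @property
    def ultraharmonic_windows(self) -> tuple[tuple[float, float], ...]:
        return self._windows(self.ultraharmonic_centers)

    @property
    def band(self) -> tuple[float, float]:
        return (self.f_lo, self.f_hi)


def band_plan(
    f0: float = 1.5e6,
    f_lo: float = 3e6,
    f_hi: float = 9e6,
    half_width: float = 1.5e5,
) -> BandPlan:
    """Build the analysis plan; defaults follow the 1.5 MHz / 3–9 MHz setup."""
    return BandPlan(f0=f0, f_lo=f_lo, f_hi=f_hi, half_width=half_width)


@dataclass(frozen=True)
class CavitationDose:
    """Per-pulse dose triple (spectral-RMS units)."""

    scdh: float
    scdu: float
    icd: float
    index: int = 0
    microbubbles: bool = True

    def __post_init__(self) -> None:
        if min(self.scdh, self.scdu, self.icd) < 0:
            raise ValueError("doses must be non-negative")


def scd(spectrum: Spectrum, plan: BandPlan, kind: str) -> float:
    """Stable cavitation dose: RMS over the kind's spectral windows."""
    if kind == "harmonic":
        windows = plan.harmonic_windows
    elif kind == "ultraharmonic":
        windows = plan.ultraharmonic_windows
    else:
        raise ValueError(f"kind must be 'harmonic' or 'ultraharmonic', got {kind!r}")
    if not windows or not spectrum.bins_in(windows).any():
        raise ValueError(f"no spectral bins fall in the {kind} windows")
    return spectrum.band_rms(windows)


def icd(spectrum: Spectrum, plan: BandPlan) -> float:
    """Inertial cavitation dose: RMS over the band minus all tone windows."""
    in_band = spectrum.bins_in([plan.band])
    excluded = spectrum.bins_in(
        list(plan.harmonic_windows) + list(plan.ultraharmonic_windows)
    )
    sel = in_band & ~excluded
    if not sel.any():
        raise ValueError("harmonic/ultraharmonic windows cover the whole band")
    return float(np.sqrt(np.sum(spectrum.amplitude[sel] ** 2)))


def pulse_doses(pulse: PulseRecord, plan: BandPlan, window: str = "rect") -> CavitationDose:
    spectrum = pulse_spectrum(pulse, window=window)
    return CavitationDose(
        scdh=scd(spectrum, plan, "harmonic"),
        scdu=scd(spectrum, plan, "ultraharmonic"),
        icd=icd(spectrum, plan),
        index=pulse.index,
        microbubbles=pulse.microbubbles,
    )


def sonication_summary(doses: Sequence[CavitationDose]) -> dict[str, float]:
    """Per-sonication aggregate: mean of each metric over pulses."""
    if not doses:
        raise ValueError("no pulses to aggregate")
    return {m: float(np.mean([getattr(d, m) for d in doses])) for m in METRICS}


def normalize_doses(
    with_mb: Sequence[CavitationDose], baseline: Sequence[CavitationDose]
) -> dict[str, float]:
    """Microbubble dose relative to the microbubble-free baseline.

    Per metric: mean over with-microbubble pulses divided by the mean
    over baseline pulses.
    """
    agg_with = sonication_summary(with_mb)
    agg_base = sonication_summary(baseline)
    out = {}
    for m in METRICS:
        if agg_base[m] <= 0:
            raise ZeroDivisionError(f"baseline aggregate for {m} is zero")
        out[m] = agg_with[m] / agg_base[m]
    return out
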