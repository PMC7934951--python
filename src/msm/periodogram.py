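"""Lomb-Scargle analysis of 1-D spatial intensity profiles.

Quantifies salt-and-pepper periodicity in brightness-versus-position
profiles (e.g. pErk staining intensity along the anterior-posterior axis).
Frequencies are *angular* spatial frequencies (radians per length unit),
so the dominant period is ``P = 2 * pi / f``; a control-like profile with
bumps every ~90 length units peaks near f ~ 0.07.

The near-DC band — periods spanning most of the profile — is excluded
from dominant-peak extraction: such a mode is merely the equivalent of a
constant offset term in the sinusoidal fit.

A synthetic profile generator stands in for image quantification: a train
of Gaussian bumps at a fixed spacing with tunable amplitude noise,
positional jitter and bump dropout, emulating "control" versus
"filopodia-loss" (diffuse) patterning.  The generator output is synthetic
data; it emulates the shape of real staining profiles, not their biology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import lombscargle as _scipy_lombscargle


@dataclass
class Profile1D:
    """1-D intensity profile (positions need not be evenly spaced)."""

    positions: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def span(self) -> float:
        return float(self.positions[-1] - self.positions[0])


@dataclass
class PeriodogramSpectrum:
    frequencies: np.ndarray  # angular, rad / length unit
    power: np.ndarray
    dc_period_cutoff: float  # periods above this are treated as offset

    @property
    def peak(self):
        """(frequency, power, period) of the dominant non-DC mode, or
        None when all usable power sits at the noise floor."""
        periods = 2 * np.pi / self.frequencies
        usable = periods <= self.dc_period_cutoff
        if not np.any(usable):
            return None
        p = np.where(usable, self.power, -np.inf)
        i = int(np.argmax(p))
        if self.power[i] <= 0:
            return None
        f = float(self.frequencies[i])
        return f, float(self.power[i]), 2 * np.pi / f

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"frequency": self.frequencies, "power": self.power})


def default_frequency_grid(profile: Profile1D, n: int = 500) -> np.ndarray:
    """Log-spaced angular frequencies from the full span to the Nyquist-like
    limit ``pi / min spacing``."""
    lo = 2 * np.pi / profile.span
    hi = np.pi / np.min(np.diff(profile.positions))
    return np.geomspace(lo, hi, n)


def lomb_scargle(
    profile: Profile1D,
    frequencies: Optional[np.ndarray] = None,
    dc_exclusion: float = 0.8,
) -> PeriodogramSpectrum:
    """Lomb-Scargle periodogram of a profile over an angular-frequency grid.

    The profile is mean-subtracted first, so the power is invariant to a
    constant offset and a constant profile yields an (numerically) zero
    spectrum.  Scargle normalisation as provided by scipy.

    Parameters
    ----------
    dc_exclusion : float
        Periods longer than this fraction of the profile span are treated
        as offset-like and never reported as the dominant mode.
    """
    if len(profile.values) < 4:
        raise ValueError("need at least 4 samples")
    freqs = (
        np.asarray(frequencies, dtype=float)
        if frequencies is not None
        else default_frequency_grid(profile)
    )
    if np.any(freqs <= 0):
        raise ValueError("frequency grid must be positive")
    y = profile.values - profile.values.mean()
    power = _scipy_lombscargle(profile.positions, y, freqs)
    return PeriodogramSpectrum(
        frequencies=freqs,
        power=np.maximum(power, 0.0),
        dc_period_cutoff=dc_exclusion * profile.span,
    )


def dominant_period(spectrum_or_frequency) -> Optional[float]:
    """Spatial period of the dominant mode, ``P = 2 pi / f``.

    Accepts either a :class:`PeriodogramSpectrum` (DC band excluded) or a
    bare peak frequency.  Returns None when no dominant peak exists.
    """
    if isinstance(spectrum_or_frequency, PeriodogramSpectrum):
        pk = spectrum_or_frequency.peak
        if pk is None:
            return None
        return pk[2]
    f = float(spectrum_or_frequency)
    if f <= 0:
        raise ValueError("frequency must be positive")
    return 2 * np.pi / f


def synth_profile(
    period: float = 90.0,
    n_bumps: int = 10,
    amplitude_noise: float = 0.1,
    position_jitter: float = 2.0,
    dropout: float = 0.0,
    bump_width: Optional[float] = None,
    baseline: float = 0.2,
    noise_floor: float = 0.05,
    sample_spacing: float = 1.0,
    seed: int = 0,
    label: str = "",
) -> Profile1D:
    """Synthetic pErk-like profile: periodic Gaussian bumps plus noise.

    Bumps are centred at ``k * period`` (k = 0 .. n_bumps - 1) with
    multiplicative amplitude noise, additive positional jitter (length
    units) and optional bump dropout; high jitter/dropout mimics the
    diffuse patterning of filopodia-loss conditions.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if n_bumps < 2:
        raise ValueError("need at least two bumps")
    rng = np.random.default_rng(seed)
    width = bump_width if bump_width is not None else period / 6.0
    x = np.arange(0.0, n_bumps * period, sample_spacing)
    y = np.full_like(x, baseline)
    for k in range(n_bumps):
        if dropout and rng.random() < dropout:
            continue
        center = k * period + rng.normal(0.0, position_jitter)
        amp = max(0.0, 1.0 + rng.normal(0.0, amplitude_noise))
        y += amp * np.exp(-0.5 * ((x - center) / width) ** 2)
    if noise_floor:
        y += rng.normal(0.0, noise_floor, size=len(x))
    return Profile1D(positions=x, values=y, label=label)


def control_preset(seed: int = 0) -> Profile1D:
    """Control-like profile: regular ~90-unit spacing, low jitter."""
    return synth_profile(
        period=90.0, n_bumps=10, amplitude_noise=0.1, position_jitter=2.0,
        dropout=0.0, seed=seed, label="control",
    )


def latb_preset(seed: int = 0) -> Profile1D:
    """Filopodia-loss-like profile: heavy jitter and 50% bump dropout give
    markedly more diffuse patterning."""
    return synth_profile(
        period=90.0, n_bumps=10, amplitude_noise=0.3, position_jitter=27.0,
        dropout=0.5, seed=seed, label="latb",
    )


def read_profile_csv(path) -> Profile1D:
    """CSV with columns position,value[,label]."""
    import pandas as pd

    df = pd.read_csv(path)
    label = str(df["label"].iloc[0]) if "label" in df.columns else ""
    return Profile1D(
        positions=df.iloc[:, 0].to_numpy(),
        values=df.iloc[:, 1].to_numpy(),
        label=label,
    )
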