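"""Reed-bank construction: frequency profiles, damping calibration, coupling.

A reed bank is a chain of passive damped harmonic oscillators with
nearest-neighbour elastic coupling.  Each oscillator obeys

    x_j'' + gamma * w_j * x_j' + w_j**2 * x_j
        = f0 * mask_j * sin(w t)
          + k_left * (x_{j-1} - x_j) + k_right * (x_{j+1} - x_j)

where ``w_j = 2 pi f_j`` is the natural angular frequency, ``gamma`` the
dimensionless damping ratio (quality factor Q = 1/gamma), and the coupling
constants ``k`` (units (rad/s)^2) sit on the n-1 links between adjacent
reeds.  Missing links at the two free ends contribute nothing, which for
uniform coupling reduces the end terms to ``k (x_2 - x_1)`` and
``k (x_{n-1} - x_n)``.

Frequency profiles provided:

* Wilson bank -- 21 reeds descending 55.0, 54.5, ..., 45.0 Hz, the classic
  Frahm frequency-meter layout (reed 1 = 55 Hz).
* Greenwood bank -- natural frequencies from the human frequency-position
  map F(x) = A (10**(a x) - k) over a span of basilar-membrane positions,
  ascending with index.
* Linear bank -- equally spaced frequencies between two endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ReedBank",
    "GreenwoodMapParams",
    "HUMAN_GREENWOOD",
    "gamma_for_kappa",
    "greenwood_frequency",
    "build_wilson_bank",
    "build_greenwood_bank",
    "build_linear_bank",
    "tapered_coupling_profile",
]

#: Slope and intercept of the empirical damping-vs-coupling calibration
#: gamma(kappa) = GAMMA_SLOPE * kappa + GAMMA_INTERCEPT, obtained by matching
#: simulated profiles to the analogue reed-meter measurements (a rubber band
#: supplies both coupling and damping, so the two co-vary).
GAMMA_SLOPE = 3.37e-6
GAMMA_INTERCEPT = 0.00553

#: Conversion factor from (rad/ms)^2 to (rad/s)^2.  The kilohertz-range
#: experiments quote coupling constants in millisecond time units (the
#: natural nondimensionalization when frequencies are expressed in kHz);
#: multiply those values by this factor to obtain the SI coupling stored
#: in :class:`ReedBank`.  The 21-reed Wilson experiments quote kappa in
#: (rad/s)^2 directly.
KAPPA_MS2 = 1.0e6


@dataclass(frozen=True)
class GreenwoodMapParams:
    """Constants of the Greenwood frequency-position map F = A(10**(a x) - k).

    ``x`` is measured in mm from the apex.  Defaults are the standard human
    fit: A = 165.4 Hz, a = 0.06 /mm, k = 0.88.
    """

    A: float = 165.4
    a: float = 0.06
    k: float = 0.88

    def __post_init__(self) -> None:
        if self.A <= 0 or self.a < 0:
            raise ValueError("Greenwood map requires A > 0 and a >= 0")
        if self.k < 0:
            raise ValueError("Greenwood offset k must be non-negative")


HUMAN_GREENWOOD = GreenwoodMapParams()


@dataclass(frozen=True)
class ReedBank:
    """A chain of coupled damped harmonic oscillators.

    Attributes
    ----------
    natural_freq_hz
        Vector of n natural frequencies f_j in Hz (n >= 2).
    gamma
        Dimensionless damping ratio, shared by all reeds; Q = 1/gamma.
    coupling
        Vector of n-1 per-link coupling constants in (rad/s)^2; entry j
        couples reed j and reed j+1 (0-based).
    f0
        Forcing amplitude (arbitrary units; the system is linear).
    forcing_mask
        Per-reed weight in [0, 1] multiplying f0.  All-ones is parallel
        forcing of the whole array; a one-hot mask drives a single reed.
    """

    natural_freq_hz: np.ndarray
    gamma: float
    coupling: np.ndarray
    f0: float = 1000.0
    forcing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        freqs = np.asarray(self.natural_freq_hz, dtype=float)
        object.__setattr__(self, "natural_freq_hz", freqs)
        if freqs.ndim != 1 or freqs.size < 2:
            raise ValueError("bank needs at least 2 oscillators")
        if np.any(freqs <= 0):
            raise ValueError("natural frequencies must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        coupling = np.asarray(self.coupling, dtype=float)
        if coupling.ndim == 0:
            coupling = np.full(freqs.size - 1, float(coupling))
        object.__setattr__(self, "coupling", coupling)
        if coupling.shape != (freqs.size - 1,):
            raise ValueError(
                f"coupling must have n-1 = {freqs.size - 1} entries, "
                f"got {coupling.shape}"
            )
        if np.any(coupling < 0):
            raise ValueError("coupling constants must be non-negative")
        mask = self.forcing_mask
        if mask is None:
            mask = np.ones(freqs.size)
        mask = np.asarray(mask, dtype=float)
        object.__setattr__(self, "forcing_mask", mask)
        if mask.shape != freqs.shape:
            raise ValueError("forcing_mask must have one entry per reed")
        if np.any(mask < 0) or np.any(mask > 1):
            raise ValueError("forcing_mask entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.natural_freq_hz.size

    @property
    def omega(self) -> np.ndarray:
        """Natural angular frequencies 2 pi f_j in rad/s."""
        return 2.0 * np.pi * self.natural_freq_hz

    @property
    def q(self) -> float:
        """Quality factor of an uncoupled reed, Q = 1/gamma."""
        return np.inf if self.gamma == 0 else 1.0 / self.gamma

    def with_forcing_mask(self, mask: np.ndarray) -> "ReedBank":
        return replace(self, forcing_mask=np.asarray(mask, dtype=float))

    def with_single_reed_forcing(self, index: int) -> "ReedBank":
        """Bank driving only reed ``index`` (0-based)."""
        if not 0 <= index < self.n:
            raise IndexError(f"reed index {index} out of range [0, {self.n})")
        mask = np.zeros(self.n)
        mask[index] = 1.0
        return self.with_forcing_mask(mask)

    def to_frame(self):
        """Per-reed table: index, natural frequency, left/right link coupling."""
        import pandas as pd

        left = np.concatenate([[np.nan], self.coupling])
        right = np.concatenate([self.coupling, [np.nan]])
        return pd.DataFrame(
            {
                "reed_index": np.arange(1, self.n + 1),
                "natural_freq_hz": self.natural_freq_hz,
                "kappa_left": left,
                "kappa_right": right,
            }
        )


def gamma_for_kappa(kappa: float) -> float:
    """Damping ratio calibrated to the coupling strength.

    The analogue instrument's rubber band supplies coupling and damping
    together; the empirical co-variation is the affine law
    gamma = 3.37e-6 * kappa + 0.00553.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    return GAMMA_SLOPE * kappa + GAMMA_INTERCEPT


def greenwood_frequency(
    x_mm: float | np.ndarray, params: GreenwoodMapParams = HUMAN_GREENWOOD
) -> float | np.ndarray:
    """Characteristic frequency at distance ``x_mm`` from the apex (Hz)."""
    x = np.asarray(x_mm, dtype=float)
    freq = params.A * (10.0 ** (params.a * x) - params.k)
    if np.any(freq <= 0):
        raise ValueError(
            "Greenwood parameterization yields non-positive frequency "
            f"over the requested range (min {np.min(freq):.3g} Hz)"
        )
    return float(freq) if np.isscalar(x_mm) else freq


def _resolve_gamma(gamma: float | str, kappa: float) -> float:
    if isinstance(gamma, str):
        if gamma != "auto":
            raise ValueError(f"gamma must be a number or 'auto', got {gamma!r}")
        return gamma_for_kappa(kappa)
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return float(gamma)


def build_wilson_bank(
    kappa: float, gamma: float | str = 0.014, f0: float = 1000.0
) -> ReedBank:
    """The 21-reed Frahm frequency-meter bank, 55 Hz down to 45 Hz.

    Reed 1 has the highest natural frequency (55 Hz); frequencies descend
    in 0.5 Hz steps to 45 Hz at reed 21.  Coupling is uniform.  With
    ``gamma="auto"`` the damping follows :func:`gamma_for_kappa`.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    g = _resolve_gamma(gamma, kappa)
    freqs = np.arange(55.0, 44.9, -0.5)
    return ReedBank(
        natural_freq_hz=freqs,
        gamma=g,
        coupling=np.full(freqs.size - 1, float(kappa)),
        f0=f0,
    )


def build_greenwood_bank(
    kappa: float,
    gamma: float | str = 0.025,
    x_start_mm: float = 16.5,
    x_end_mm: float = 18.5,
    dx_mm: float = 0.01,
    params: GreenwoodMapParams = HUMAN_GREENWOOD,
    f0: float = 1000.0,
) -> ReedBank:
    """Oscillator bank on the Greenwood map, one reed per hair-cell width.

    Defaults place 201 oscillators at 16.5-18.5 mm from the apex in 0.01 mm
    steps, giving a nearly linear frequency ramp from about 1.5 to 2 kHz in
    roughly 2.5 Hz increments, ascending with index.  Default gamma = 0.025
    corresponds to Q = 40.
    """
    if x_end_mm <= x_start_mm:
        raise ValueError("x_end_mm must exceed x_start_mm")
    if dx_mm <= 0:
        raise ValueError("dx_mm must be positive")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    g = _resolve_gamma(gamma, kappa)
    n_steps = round((x_end_mm - x_start_mm) / dx_mm)
    x = x_start_mm + dx_mm * np.arange(n_steps + 1)
    freqs = greenwood_frequency(x, params)
    return ReedBank(
        natural_freq_hz=freqs,
        gamma=g,
        coupling=np.full(freqs.size - 1, float(kappa)),
        f0=f0,
    )


def build_linear_bank(
    f_start_hz: float,
    f_end_hz: float,
    n: int,
    kappa: float,
    gamma: float,
    f0: float = 1000.0,
) -> ReedBank:
    """``n`` oscillators with equally spaced frequencies, endpoints included."""
    if n < 2:
        raise ValueError("need at least 2 oscillators")
    if f_start_hz >= f_end_hz:
        raise ValueError("f_start_hz must be below f_end_hz")
    if kappa < 0 or gamma < 0:
        raise ValueError("kappa and gamma must be non-negative")
    freqs = np.linspace(f_start_hz, f_end_hz, n)
    return ReedBank(
        natural_freq_hz=freqs,
        gamma=float(gamma),
        coupling=np.full(n - 1, float(kappa)),
        f0=f0,
    )


def tapered_coupling_profile(
    n: int, kappa_max: float, ramp_len: int = 10
) -> np.ndarray:
    """Per-link coupling that vanishes at the free ends of the chain.

    The outermost link on each side carries zero coupling; the next
    ``ramp_len`` links rise linearly to ``kappa_max``, which holds over the
    interior.  Used to test sensitivity of the response to boundary
    conditions.  ``ramp_len=0`` gives a uniform profile.
    """
    if n < 2:
        raise ValueError("need at least 2 oscillators")
    if kappa_max < 0:
        raise ValueError("kappa_max must be non-negative")
    if ramp_len < 0:
        raise ValueError("ramp_len must be non-negative")
    n_links = n - 1
    if ramp_len == 0:
        return np.full(n_links, float(kappa_max))
    if n_links < 2 * (ramp_len + 1):
        raise ValueError(
            f"ramp of {ramp_len} links needs at least {2 * (ramp_len + 1)} links; "
            f"bank has {n_links}"
        )
    profile = np.full(n_links, float(kappa_max))
    ramp = kappa_max * np.arange(ramp_len + 1) / ramp_len
    profile[: ramp_len + 1] = ramp
    profile[n_links - ramp_len - 1 :] = ramp[::-1]
    return profile
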