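"""Population arterial input functions (AIFs).

The kinetic model needs the plasma contrast concentration Cp(t). Without
patient-specific AIF sampling the standard choice is a population model;
two are provided:

* :class:`WeinmannAIF` — the classic biexponential decay fitted by
  Weinmann et al. to plasma samples after a bolus of Gd-DTPA. Because it
  is a sum of exponentials, its convolution with the Tofts exponential
  kernel has a closed form, which the fitting path exploits.
* :class:`ParkerAIF` — the mixed Gaussian + sigmoidal-exponential
  population form of Parker et al.; evaluated numerically.

Both are zero before a configurable bolus-arrival time so that Cp(0) = 0.
Internally, rates are per minute and times are supplied in seconds.
"""

from __future__ import annotations

import numpy as np


class WeinmannAIF:
    """Biexponential population AIF: Cp(t) = dose·(a1·e^{-m1 t} + a2·e^{-m2 t}).

    Parameters
    ----------
    dose:
        Contrast dose in mmol per kg body weight (default 0.1).
    a1, a2:
        Amplitudes in kg/L (Weinmann values 3.99 and 4.78).
    m1, m2:
        Decay rates in min⁻¹ (Weinmann values 0.144 and 0.0111).
    onset_s:
        Bolus arrival time in seconds; Cp(t) = 0 for t ≤ onset.
    """

    def __init__(
        self,
        dose: float = 0.1,
        a1: float = 3.99,
        a2: float = 4.78,
        m1: float = 0.144,
        m2: float = 0.0111,
        onset_s: float = 19.0,
    ) -> None:
        self.dose = float(dose)
        self.a1, self.a2 = float(a1), float(a2)
        self.m1, self.m2 = float(m1), float(m2)
        self.onset_s = float(onset_s)

    @property
    def name(self) -> str:
        return "weinmann"

    def exp_terms(self) -> tuple[np.ndarray, np.ndarray]:
        """Amplitudes (mmol/L) and rates (min⁻¹) of the exponential mixture."""
        amps = np.array([self.dose * self.a1, self.dose * self.a2])
        rates = np.array([self.m1, self.m2])
        return amps, rates

    def cp(self, t_s: np.ndarray) -> np.ndarray:
        """Plasma concentration in mmol/L at times ``t_s`` (seconds)."""
        t_s = np.asarray(t_s, dtype=float)
        u_min = np.clip(t_s - self.onset_s, 0.0, None) / 60.0
        amps, rates = self.exp_terms()
        out = np.zeros_like(u_min)
        active = t_s > self.onset_s
        out[active] = sum(a * np.exp(-m * u_min[active]) for a, m in zip(amps, rates))
        return out


class ParkerAIF:
    """Parker population AIF: two Gaussian bolus passes plus a sigmoidal washout.

    Cp(t) = Σ_n A_n/(σ_n√(2π)) exp(−(t−T_n)²/2σ_n²) + α e^{−βt}/(1+e^{−s(t−τ)})
    with t in minutes from bolus arrival; published population parameters.
    """

    A = (0.809, 0.330)        # mmol·min
    T = (0.17046, 0.365)      # min
    SIGMA = (0.0563, 0.132)   # min
    ALPHA = 1.050             # mmol
    BETA = 0.1685             # min^-1
    S = 38.078                # min^-1
    TAU = 0.483               # min

    def __init__(self, onset_s: float = 19.0) -> None:
        self.onset_s = float(onset_s)

    @property
    def name(self) -> str:
        return "parker"

    def cp(self, t_s: np.ndarray) -> np.ndarray:
        t_s = np.asarray(t_s, dtype=float)
        u = np.clip(t_s - self.onset_s, 0.0, None) / 60.0
        out = np.zeros_like(u)
        active = t_s > self.onset_s
        ua = u[active]
        val = np.zeros_like(ua)
        for A, T, sig in zip(self.A, self.T, self.SIGMA):
            val += A / (sig * np.sqrt(2 * np.pi)) * np.exp(-((ua - T) ** 2) / (2 * sig**2))
        val += self.ALPHA * np.exp(-self.BETA * ua) / (1 + np.exp(-self.S * (ua - self.TAU)))
        out[active] = val
        return out


def make_aif(name: str = "weinmann", **kwargs) -> WeinmannAIF | ParkerAIF:
    """AIF factory used by the config layer."""
    if name == "weinmann":
        return WeinmannAIF(**kwargs)
    if name == "parker":
        return ParkerAIF(**kwargs)
    raise ValueError(f"unknown AIF model {name!r}")
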