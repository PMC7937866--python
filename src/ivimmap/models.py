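"""Closed-form IVIM signal models and the corrected AIC statistic.

The intravoxel incoherent motion (IVIM) signal is modelled as a
two-compartment sum: an extravascular (tissue diffusion) compartment with
attenuation ``E(b; D, K)`` and an intravascular (capillary pseudo-diffusion)
compartment decaying as ``exp(-b * D*)``:

    S(b) = Se0 * E(b; D, K) + Sv0 * exp(-b * Dstar)

Three candidate diffusion models are supported for ``E``:

* Gaussian      — mono-exponential, ``exp(-b D)`` (free water, CSF)
* Kurtosis      — ``exp(-b D + b^2 D^2 K / 6)`` (restricted diffusion, WM)
* Gamma         — ``(1 + b D K / 3) ** (-3/K)``, the Laplace transform of a
                  gamma distribution of compartment diffusivities (GM)

Both non-Gaussian models reduce exactly to the Gaussian model at K = 0.
Model comparison uses the small-sample corrected Akaike information
criterion (cAIC).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelId",
    "DiffusionParams",
    "PerfusionParams",
    "GammaDistParams",
    "CaicInput",
    "N_PARAMS",
    "attenuation",
    "ivim_signal",
    "perfusion_fraction",
    "caic",
    "kurtosis_to_gamma_params",
    "validity_bounds",
]


class ModelId(enum.IntEnum):
    """Candidate diffusion models; integer codes are stable in all outputs.

    0 is reserved for background / unfitted voxels in model maps.
    """

    GAUSSIAN = 1
    KURTOSIS = 2
    GAMMA = 3


#: Number of free parameters of the high-b diffusion fit per model:
#: (Se0, D) for Gaussian; (Se0, D, K) for Kurtosis and Gamma.
N_PARAMS = {ModelId.GAUSSIAN: 2, ModelId.KURTOSIS: 3, ModelId.GAMMA: 3}


@dataclass(frozen=True)
class DiffusionParams:
    """Extravascular compartment parameters.

    Attributes
    ----------
    se0 : float
        Non-diffusion-weighted extravascular signal (arbitrary units, >= 0).
    d : float
        Diffusion coefficient in mm^2/s (> 0).
    k : float
        Diffusional kurtosis (dimensionless, >= 0); identically 0 for the
        Gaussian model.
    """

    se0: float
    d: float
    k: float = 0.0

    def __post_init__(self) -> None:
        if self.se0 < 0:
            raise ValueError(f"se0 must be >= 0, got {self.se0}")
        if self.d <= 0:
            raise ValueError(f"d must be > 0, got {self.d}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")


@dataclass(frozen=True)
class PerfusionParams:
    """Intravascular compartment parameters.

    Attributes
    ----------
    sv0 : float
        Non-diffusion-weighted intravascular signal (>= 0).
    dstar : float
        Pseudo-diffusion coefficient in mm^2/s (> 0); NaN when undefined
        (e.g. a voxel with no detectable perfusion signal).
    fp : float
        Perfusion fraction, ``sv0 / (sv0 + se0_mean)``, in [0, 1].
    """

    sv0: float
    dstar: float
    fp: float

    def __post_init__(self) -> None:
        if self.sv0 < 0:
            raise ValueError(f"sv0 must be >= 0, got {self.sv0}")
        if not (0.0 <= self.fp <= 1.0):
            raise ValueError(f"fp must be in [0, 1], got {self.fp}")


@dataclass(frozen=True)
class GammaDistParams:
    """Shape/rate parameterisation of the gamma diffusivity distribution.

    alpha = 3/K and beta = 3/(K D), so the distribution mean alpha/beta
    equals D and the variance alpha/beta^2 equals K D^2 / 3 (consistent with
    K = 3 sigma^2 / D^2).
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")

    @property
    def mean(self) -> float:
        return self.alpha / self.beta

    @property
    def variance(self) -> float:
        return self.alpha / self.beta**2


@dataclass(frozen=True)
class CaicInput:
    """Inputs of the corrected AIC: n data points, P parameters, RSS."""

    n: int
    p: int
    rss: float

    def __post_init__(self) -> None:
        if self.n <= self.p + 1:
            raise ValueError(
                f"need n > P + 1 for the cAIC correction term (n={self.n}, P={self.p})"
            )
        if self.rss <= 0:
            raise ValueError(f"RSS must be > 0, got {self.rss}")


def _check_attenuation_args(b, d: float, k: float) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be >= 0")
    if d <= 0:
        raise ValueError(f"D must be > 0, got {d}")
    if k < 0:
        raise ValueError(f"K must be >= 0, got {k}")
    return b


def attenuation(model: ModelId, b, d: float, k: float = 0.0):
    """Dimensionless diffusion attenuation E(b) of the chosen model.

    Parameters
    ----------
    model : ModelId
    b : float or array_like
        b-value(s) in s/mm^2, >= 0.
    d : float
        Diffusion coefficient in mm^2/s, > 0.
    k : float, optional
        Diffusional kurtosis, >= 0. Ignored by the Gaussian model. For
        K = 0 the Kurtosis and Gamma models return the Gaussian value
        exactly.

    Returns
    -------
    float or ndarray
        E(b), with E(0) = 1 for every model.
    """
    b = _check_attenuation_args(b, d, k)
    model = ModelId(model)
    if model is ModelId.GAUSSIAN or k == 0.0:
        out = np.exp(-b * d)
    elif model is ModelId.KURTOSIS:
        out = np.exp(-b * d + (b * b) * (d * d) * k / 6.0)
    else:  # GAMMA: exp(-(3/K) log1p(bDK/3)) is stable down to K -> 0+
        out = np.exp(-(3.0 / k) * np.log1p(b * d * k / 3.0))
    return out if out.ndim else float(out)


def ivim_signal(
    b,
    diffusion: DiffusionParams,
    perfusion: PerfusionParams | None,
    model: ModelId,
):
    """Two-compartment IVIM signal S(b) = Se0 E(b) + Sv0 exp(-b D*)."""
    b = np.asarray(b, dtype=float)
    out = diffusion.se0 * attenuation(model, b, diffusion.d, diffusion.k)
    if perfusion is not None and perfusion.sv0 > 0:
        out = out + perfusion.sv0 * np.exp(-b * perfusion.dstar)
    return out if np.ndim(out) else float(out)


def perfusion_fraction(sv0: float, se0_mean: float) -> float:
    """Perfusion fraction fp = Sv0 / (Sv0 + Se0)."""
    if sv0 < 0:
        raise ValueError(f"sv0 must be >= 0, got {sv0}")
    if se0_mean <= 0:
        raise ValueError(f"se0_mean must be > 0, got {se0_mean}")
    return sv0 / (sv0 + se0_mean)


def caic(inp: CaicInput) -> float:
    """Corrected Akaike information criterion.

    cAIC = 2P + n ln(RSS/n) + 2P(P+1)/(n - P - 1)

    Only differences between models fitted to the same points are
    meaningful; rescaling the data by alpha shifts every cAIC by
    2 n ln(alpha) without changing the ranking.
    """
    n, p, rss = inp.n, inp.p, inp.rss
    return 2.0 * p + n * math.log(rss / n) + 2.0 * p * (p + 1) / (n - p - 1)


def kurtosis_to_gamma_params(d: float, k: float) -> GammaDistParams:
    """Map (D, K) to the gamma-distribution shape/rate (alpha, beta).

    alpha = 3/K, beta = 3/(K D). Raises for K = 0, where the distribution
    degenerates to a point mass (use the Gaussian model instead).
    """
    if d <= 0:
        raise ValueError(f"D must be > 0, got {d}")
    if k <= 0:
        raise ValueError("K must be > 0 (K = 0 is the Gaussian reduction)")
    return GammaDistParams(alpha=3.0 / k, beta=3.0 / (k * d))


def validity_bounds(d: float, k: float) -> tuple[float, float]:
    """Model-validity b-value bounds for a given (D, K).

    Returns
    -------
    (kurtosis_bound, gamma_similarity_bound) : tuple of float, in s/mm^2
        ``3/(D K)``: largest b at which the Kurtosis expansion remains
        monotonically decreasing; ``27/(6 D K)``: the scale below which the
        Kurtosis and Gamma curves are practically indistinguishable. Both
        are +inf when D*K == 0 (a diagnostic flag, not an error).
    """
    dk = d * k
    if dk < 0:
        raise ValueError("D*K must be >= 0")
    if dk == 0:
        return math.inf, math.inf
    return 3.0 / dk, 27.0 / (6.0 * dk)
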