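"""Per-voxel two-step asymptotic IVIM fitting with cAIC model selection.

Step 1 (diffusion): for each of the six MPG directions, only the high
b-value part of the series (b = 600-2,500 s/mm^2, 11 points) is fitted,
where the perfusion term of the two-compartment signal is negligible:

    S(b) ~ Se0 * E(b; D, K)

Each candidate model (Gaussian, Kurtosis, Gamma) is fitted per direction by
bounded trust-region nonlinear least squares, and the optimal model is the
one with the minimal mean cAIC over the six directions.

Step 2 (perfusion): the fitted extravascular component of the selected
model is subtracted from the full series in each direction, and — assuming
isotropic capillary perfusion — the six residual series are fitted
simultaneously by a single mono-exponential

    Sv(b) = Sv0 * exp(-b * Dstar)

The perfusion fraction follows as fp = Sv0 / (Sv0 + mean(Se0)).

Numerical notes: every fit normalises its signals by their maximum before
optimisation and restores the scale afterwards, making the whole pipeline
exactly equivariant under rescaling of the input data (cAIC values shift by
2 n ln(alpha), nothing else changes). For the cAIC, RSS is floored at
``n * (1e-9 * scale)^2`` so that models which fit noiseless data to machine
precision tie on RSS and the parsimony penalty decides.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .models import (
    N_PARAMS,
    CaicInput,
    DiffusionParams,
    ModelId,
    PerfusionParams,
    caic,
    perfusion_fraction,
    validity_bounds,
)
from .scheme import HIGH_B_THRESHOLD

__all__ = [
    "DirectionSeries",
    "DiffusionFit",
    "PerfusionFit",
    "VoxelRecord",
    "FitConfig",
    "FitFlags",
    "ModelSelectionError",
    "fit_diffusion_direction",
    "select_optimal_model",
    "extract_perfusion_series",
    "fit_perfusion",
    "fit_voxel",
]

#: Relative RSS floor used when computing the cAIC (see module docstring).
RSS_FLOOR_REL = 1e-9

#: Model tie-break precedence on exactly equal mean cAIC: fewest parameters
#: first, then this fixed order.
TIE_ORDER = (ModelId.GAUSSIAN, ModelId.KURTOSIS, ModelId.GAMMA)


class ModelSelectionError(RuntimeError):
    """No candidate model converged in every direction."""


class FitFlags(enum.IntFlag):
    """Bitmask of per-voxel quality/diagnostic flags."""

    OK = 0
    UNFIT = 1            # no model converged; parameter outputs are NaN
    PERFUSION_BOUNDARY = 2   # perfusion optimiser pinned at a bound
    LOW_QUALITY = 4      # >= 2 zero-floored/non-finite high-b points
    VALIDITY_BOUND = 8   # b_max exceeds the Kurtosis bound 3/(D K)
    NO_PERFUSION = 16    # residuals all <= 0: Sv0 = 0, D* undefined


@dataclass(frozen=True)
class DirectionSeries:
    """Signal series of one MPG direction.

    ``b_values`` must be strictly increasing and the same length as
    ``signals`` (noise-corrected magnitudes).
    """

    direction_index: int
    b_values: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if b.shape != s.shape or b.ndim != 1:
            raise ValueError("b_values and signals must be equal-length 1-D arrays")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be strictly increasing")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "signals", s)

    def restrict(self, b_min: float, b_max: float = math.inf) -> "DirectionSeries":
        """Sub-series with b in [b_min, b_max]."""
        keep = (self.b_values >= b_min) & (self.b_values <= b_max)
        return DirectionSeries(
            self.direction_index, self.b_values[keep], self.signals[keep]
        )


@dataclass(frozen=True)
class DiffusionFit:
    """High-b diffusion fit of one model along one direction."""

    model: ModelId
    params: DiffusionParams
    rss: float
    caic: float
    n_points: int
    converged: bool


@dataclass(frozen=True)
class PerfusionFit:
    """Joint mono-exponential fit of the six perfusion residual series."""

    sv0: float
    dstar: float
    rss: float
    converged: bool
    at_boundary: bool = False
    no_signal: bool = False


@dataclass
class FitConfig:
    """Tunable settings of the two-step fit.

    ``mode`` is ``"optimal"`` (fit all three models, select by cAIC) or one
    of ``"gaussian"``, ``"kurtosis"``, ``"gamma"`` to force a single model
    (the conventional single-model analysis). Bounds encode physiological
    ranges wide enough to cover CSF; units are mm^2/s for diffusivities.
    """

    mode: str = "optimal"
    high_b_threshold: float = HIGH_B_THRESHOLD
    d_bounds: tuple[float, float] = (1e-5, 5e-3)
    k_bounds: tuple[float, float] = (0.0, 5.0)
    dstar_bounds: tuple[float, float] = (1e-4, 0.5)
    k_init: float = 0.8
    dstar_init: float = 10e-3
    max_nfev: int = 200
    tol: float = 1e-12
    #: extra alternating rounds of the two steps: the fitted perfusion
    #: component is subtracted from the high-b window and the selected
    #: model refitted, removing the residual perfusion contamination of
    #: the asymptotic step (see docs/methods.md)
    refine_iterations: int = 16
    refine_rtol: float = 1e-7

    def models_to_fit(self) -> tuple[ModelId, ...]:
        if self.mode == "optimal":
            return tuple(TIE_ORDER)
        try:
            return (ModelId[self.mode.upper()],)
        except KeyError:
            raise ValueError(f"unknown fitting mode {self.mode!r}") from None


def _atten_and_grads(model: ModelId, b: np.ndarray, d: float, k: float):
    """E(b) and its partial derivatives wrt D and K (vectorised over b)."""
    if model is ModelId.GAUSSIAN:
        e = np.exp(-b * d)
        return e, -b * e, np.zeros_like(b)
    if model is ModelId.KURTOSIS or k < 1e-8:
        # second-order expansion; for Gamma this is its own K->0 limit
        e = np.exp(-b * d + (b * b) * (d * d) * k / 6.0)
        de_dd = e * (-b + (b * b) * d * k / 3.0)
        de_dk = e * (b * b) * (d * d) / 6.0
        return e, de_dd, de_dk
    u = b * d * k / 3.0
    log1pu = np.log1p(u)
    e = np.exp(-(3.0 / k) * log1pu)
    de_dd = -e * b / (1.0 + u)
    de_dk = e * ((3.0 / (k * k)) * log1pu - (b * d / k) / (1.0 + u))
    return e, de_dd, de_dk


def fit_diffusion_direction(
    series: DirectionSeries,
    model: ModelId,
    config: FitConfig | None = None,
    se0_max: float | None = None,
    init: DiffusionParams | None = None,
) -> DiffusionFit:
    """Fit ``Se0 * E(b; D, K)`` to a high-b series by bounded least squares.

    Parameters
    ----------
    series : DirectionSeries
        Already restricted to the high-b window; needs >= 5 points.
    model : ModelId
    config : FitConfig, optional
    se0_max : float, optional
        Upper bound for Se0; callers that know the voxel's S(0) pass
        ``2 * S(0)``. Defaults to 20x the series maximum (enough to cover
        CSF-like extrapolation from b = 600).
    init : DiffusionParams, optional
        Warm start (used by the refinement rounds of :func:`fit_voxel`);
        default initialisation is a log-linear fit of the leading points.

    Returns
    -------
    DiffusionFit
        With ``caic`` computed from the (RSS-floored) residual sum of
        squares; ``caic = +inf`` and ``converged = False`` if the optimiser
        failed.
    """
    cfg = config or FitConfig()
    model = ModelId(model)
    b = series.b_values
    y = series.signals
    n = len(b)
    if n < 5:
        raise ValueError(f"need >= 5 high-b points, got {n}")
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise ValueError("signals must be finite and >= 0")
    s_norm = float(y.max())
    if s_norm <= 0:
        raise ValueError("all-zero series cannot be fitted")
    yn = y / s_norm
    se0_hi = (se0_max / s_norm) if se0_max is not None else 20.0

    if init is not None:
        d0 = float(np.clip(init.d, cfg.d_bounds[0] * 1.01, cfg.d_bounds[1] * 0.99))
        se0_0 = float(np.clip(init.se0 / s_norm, 1e-6, se0_hi * 0.99))
        k0 = float(np.clip(init.k, cfg.k_bounds[0], cfg.k_bounds[1] * 0.999))
    else:
        # init: log-linear decay over the first points of the window
        pos = yn > 0
        lead = pos & (b <= b[pos][0] + 400.0) if pos.any() else pos
        if lead.sum() >= 2:
            slope, intercept = np.polyfit(b[lead], np.log(yn[lead]), 1)
            d0 = float(np.clip(-slope, cfg.d_bounds[0] * 1.01, cfg.d_bounds[1] * 0.99))
            se0_0 = float(np.clip(np.exp(intercept), 1e-6, se0_hi * 0.99))
        else:
            d0, se0_0 = 1e-3, min(2.0, se0_hi * 0.99)
        k0 = cfg.k_init

    gaussian = model is ModelId.GAUSSIAN

    def residual(x):
        se0, d = x[0], x[1]
        k = 0.0 if gaussian else x[2]
        e, _, _ = _atten_and_grads(model, b, d, k)
        return se0 * e - yn

    def jacobian(x):
        se0, d = x[0], x[1]
        k = 0.0 if gaussian else x[2]
        e, de_dd, de_dk = _atten_and_grads(model, b, d, k)
        cols = [e, se0 * de_dd] if gaussian else [e, se0 * de_dd, se0 * de_dk]
        return np.stack(cols, axis=1)

    if gaussian:
        x0 = [se0_0, d0]
        lo = [0.0, cfg.d_bounds[0]]
        hi = [se0_hi, cfg.d_bounds[1]]
        x_scale = [1.0, 1e-3]
    else:
        x0 = [se0_0, d0, k0]
        lo = [0.0, cfg.d_bounds[0], cfg.k_bounds[0]]
        hi = [se0_hi, cfg.d_bounds[1], cfg.k_bounds[1]]
        x_scale = [1.0, 1e-3, 1.0]

    res = least_squares(
        residual, x0, jac=jacobian, bounds=(lo, hi), method="trf",
        x_scale=x_scale,
        xtol=cfg.tol, ftol=cfg.tol, gtol=cfg.tol, max_nfev=cfg.max_nfev,
    )
    converged = bool(res.success)
    se0 = float(res.x[0]) * s_norm
    d = float(res.x[1])
    k = 0.0 if gaussian else float(res.x[2])
    rss_raw = float(np.sum(res.fun**2)) * s_norm**2
    rss = max(rss_raw, n * (RSS_FLOOR_REL * s_norm) ** 2)
    p = N_PARAMS[model]
    score = caic(CaicInput(n=n, p=p, rss=rss)) if converged else math.inf
    return DiffusionFit(
        model=model,
        params=DiffusionParams(se0=se0, d=d, k=k),
        rss=rss,
        caic=score,
        n_points=n,
        converged=converged,
    )


def select_optimal_model(fits: dict[ModelId, list[DiffusionFit]]) -> ModelId:
    """Model with the minimal mean per-direction cAIC.

    A model is eligible only if it converged in every direction. Exact ties
    are broken by parameter count, then by the fixed precedence
    Gaussian > Kurtosis > Gamma.

    Raises
    ------
    ModelSelectionError
        If no candidate converged in all directions.
    """
    best: ModelId | None = None
    best_key: tuple[float, int, int] | None = None
    for rank, model in enumerate(TIE_ORDER):
        if model not in fits:
            continue
        model_fits = fits[model]
        if not all(f.converged for f in model_fits):
            continue
        mean_caic = float(np.mean([f.caic for f in model_fits]))
        key = (mean_caic, N_PARAMS[model], rank)
        if best_key is None or key < best_key:
            best, best_key = model, key
    if best is None:
        raise ModelSelectionError("no candidate model converged in all directions")
    return best


def extract_perfusion_series(
    series: list[DirectionSeries], fits: list[DiffusionFit]
) -> list[np.ndarray]:
    """Remove the fitted extravascular component from each full series.

    Returns one residual array per direction on the full b-grid (residuals
    may be negative; they are kept as-is for the least-squares step).
    """
    if len(series) != len(fits):
        raise ValueError("one diffusion fit per direction series is required")
    out = []
    for s, f in zip(series, fits):
        e, _, _ = _atten_and_grads(f.model, s.b_values, f.params.d, f.params.k)
        out.append(s.signals - f.params.se0 * e)
    return out


def fit_perfusion(
    b_values: np.ndarray,
    residuals: list[np.ndarray],
    config: FitConfig | None = None,
    sv0_max: float | None = None,
) -> PerfusionFit:
    """Jointly fit ``Sv0 * exp(-b * Dstar)`` to all residual series.

    A single (Sv0, Dstar) is shared across directions (isotropic capillary
    perfusion). If every residual is <= 0 the voxel has no detectable
    perfusion signal: Sv0 = 0, Dstar = NaN, ``no_signal`` set.
    """
    cfg = config or FitConfig()
    b = np.concatenate([np.asarray(b_values, dtype=float) for _ in residuals])
    y = np.concatenate([np.asarray(r, dtype=float) for r in residuals])
    if np.all(y <= 0):
        return PerfusionFit(
            sv0=0.0, dstar=math.nan, rss=float(np.sum(y**2)),
            converged=True, no_signal=True,
        )
    s_norm = float(np.abs(y).max())
    yn = y / s_norm
    hi_sv0 = (sv0_max / s_norm) if sv0_max is not None else 10.0
    at0 = b == 0
    sv0_0 = float(np.clip(yn[at0].mean() if at0.any() else yn.max(), 1e-6, hi_sv0 * 0.99))
    x0 = [sv0_0, cfg.dstar_init]
    lo = [0.0, cfg.dstar_bounds[0]]
    hi = [hi_sv0, cfg.dstar_bounds[1]]

    def residual(x):
        return x[0] * np.exp(-b * x[1]) - yn

    def jacobian(x):
        e = np.exp(-b * x[1])
        return np.stack([e, -b * x[0] * e], axis=1)

    res = least_squares(
        residual, x0, jac=jacobian, bounds=(lo, hi), method="trf",
        x_scale=[1.0, 1e-2],
        xtol=cfg.tol, ftol=cfg.tol, gtol=cfg.tol, max_nfev=cfg.max_nfev,
    )
    sv0 = float(res.x[0]) * s_norm
    dstar = float(res.x[1])
    rss = float(np.sum(res.fun**2)) * s_norm**2
    span = cfg.dstar_bounds[1] - cfg.dstar_bounds[0]
    at_boundary = (
        dstar <= cfg.dstar_bounds[0] + 1e-6 * span
        or dstar >= cfg.dstar_bounds[1] - 1e-6 * span
        or res.x[0] >= hi_sv0 * (1 - 1e-9)
    )
    if sv0 == 0.0:
        return PerfusionFit(
            sv0=0.0, dstar=math.nan, rss=rss,
            converged=bool(res.success), no_signal=True,
        )
    return PerfusionFit(
        sv0=sv0, dstar=dstar, rss=rss,
        converged=bool(res.success), at_boundary=at_boundary,
    )


def _aitken(history: list[tuple[float, float]]) -> tuple[float, float] | None:
    """Aitken extrapolation of the last three (Sv0, D*) iterates.

    Returns None unless both components contract geometrically with a
    stable ratio in (0, 0.95).
    """
    (a0, b0), (a1, b1), (a2, b2) = history[-3:]
    out = []
    for x0, x1, x2 in ((a0, a1, a2), (b0, b1, b2)):
        d1, d2 = x1 - x0, x2 - x1
        if d1 == 0 or d2 == 0:
            return None
        g = d2 / d1
        if not 0.0 < g < 0.95:
            return None
        out.append(x2 + d2 * g / (1.0 - g))
    if out[0] <= 0 or out[1] <= 0:
        return None
    return out[0], out[1]


@dataclass
class VoxelRecord:
    """Complete per-voxel output of the two-step fit.

    ``fits`` maps each fitted model to its six per-direction diffusion
    fits. Scalar summaries are direction averages of the selected model's
    estimates; Gaussian-selected voxels contribute K = 0 to ``kapp_mean``.
    """

    fits: dict[ModelId, list[DiffusionFit]] = field(default_factory=dict)
    selected_model: ModelId | None = None
    se0_mean: float = math.nan
    md: float = math.nan
    kapp_mean: float = math.nan
    perfusion: PerfusionParams | None = None
    flags: FitFlags = FitFlags.OK

    @property
    def fp(self) -> float:
        return self.perfusion.fp if self.perfusion is not None else math.nan

    @property
    def dstar(self) -> float:
        return self.perfusion.dstar if self.perfusion is not None else math.nan


def fit_voxel(series: list[DirectionSeries], config: FitConfig | None = None) -> VoxelRecord:
    """Run the full two-step asymptotic fit on one voxel.

    Parameters
    ----------
    series : list of DirectionSeries
        One full-b-grid series per MPG direction (noise-corrected).
    config : FitConfig, optional
        ``mode="optimal"`` fits all three candidates and selects by mean
        cAIC; a forced mode skips selection.

    Returns
    -------
    VoxelRecord
        Fit failures are reported via ``flags`` (never raised), so a
        whole-volume run is never aborted by a single voxel.
    """
    cfg = config or FitConfig()
    record = VoxelRecord()
    models = cfg.models_to_fit()

    high = [s.restrict(cfg.high_b_threshold) for s in series]
    n_bad = sum(int(((h.signals <= 0) | ~np.isfinite(h.signals)).sum()) for h in high)
    if n_bad >= 2:
        record.flags |= FitFlags.LOW_QUALITY

    fits: dict[ModelId, list[DiffusionFit]] = {}
    for model in models:
        per_dir = []
        for s, h in zip(series, high):
            b0 = s.signals[s.b_values == 0]
            se0_max = 2.0 * float(b0[0]) if b0.size and b0[0] > 0 else None
            try:
                f = fit_diffusion_direction(h, model, cfg, se0_max=se0_max)
            except ValueError:
                f = DiffusionFit(
                    model=model,
                    params=DiffusionParams(se0=0.0, d=1e-3, k=0.0),
                    rss=math.inf, caic=math.inf, n_points=len(h.b_values),
                    converged=False,
                )
            per_dir.append(f)
        fits[model] = per_dir
    record.fits = fits

    if cfg.mode == "optimal":
        try:
            selected = select_optimal_model(fits)
        except ModelSelectionError:
            record.flags |= FitFlags.UNFIT
            return record
    else:
        selected = models[0]
        if not all(f.converged for f in fits[selected]):
            record.flags |= FitFlags.UNFIT
            return record
    record.selected_model = selected
    sel = fits[selected]

    b0 = series[0].signals[series[0].b_values == 0]
    sv0_max = 2.0 * float(np.mean([s.signals[s.b_values == 0].mean() for s in series])) \
        if b0.size else None

    def perfusion_step(sel_fits):
        residuals = extract_perfusion_series(series, sel_fits)
        return fit_perfusion(series[0].b_values, residuals, cfg, sv0_max=sv0_max)

    pf = perfusion_step(sel)

    # Alternate the two steps: subtracting the fitted perfusion component
    # from the high-b window removes its residual contamination of the
    # asymptotic diffusion fit (on noise-free data this converges to the
    # exact generating parameters). The alternation contracts geometrically,
    # so an Aitken extrapolation of (Sv0, D*) is applied once three
    # consecutive iterates are available, which roughly halves the rounds
    # needed for a given precision.
    history: list[tuple[float, float]] = [(pf.sv0, pf.dstar)]
    for _ in range(cfg.refine_iterations):
        if pf.no_signal or not pf.converged or pf.sv0 == 0:
            break
        new_sel = []
        for s, h, f in zip(series, high, sel):
            perf = pf.sv0 * np.exp(-h.b_values * pf.dstar)
            adj = DirectionSeries(
                h.direction_index, h.b_values, np.maximum(h.signals - perf, 0.0)
            )
            b0v = s.signals[s.b_values == 0]
            se0_max = 2.0 * float(b0v[0]) if b0v.size and b0v[0] > 0 else None
            try:
                nf = fit_diffusion_direction(
                    adj, selected, cfg, se0_max=se0_max, init=f.params
                )
            except ValueError:
                nf = f
            new_sel.append(nf if nf.converged else f)
        new_pf = perfusion_step(new_sel)
        changes = [
            abs(np.mean([f.params.d for f in new_sel])
                - np.mean([f.params.d for f in sel]))
            / max(np.mean([f.params.d for f in sel]), 1e-30),
            abs(new_pf.sv0 - pf.sv0) / max(pf.sv0, 1e-30),
        ]
        sel, pf = new_sel, new_pf
        if max(changes) < cfg.refine_rtol:
            break
        history.append((pf.sv0, pf.dstar))
        if len(history) >= 3 and not pf.no_signal and math.isfinite(pf.dstar):
            accel = _aitken(history)
            if accel is not None:
                pf = PerfusionFit(
                    sv0=accel[0], dstar=accel[1], rss=pf.rss,
                    converged=True, at_boundary=pf.at_boundary,
                )
                history = [accel]

    record.se0_mean = float(np.mean([f.params.se0 for f in sel]))
    record.md = float(np.mean([f.params.d for f in sel]))
    record.kapp_mean = float(np.mean([f.params.k for f in sel]))

    if record.kapp_mean > 0:
        kurt_bound, _ = validity_bounds(record.md, record.kapp_mean)
        if max(s.b_values.max() for s in series) > kurt_bound:
            record.flags |= FitFlags.VALIDITY_BOUND

    if pf.no_signal:
        record.flags |= FitFlags.NO_PERFUSION
    if pf.at_boundary:
        record.flags |= FitFlags.PERFUSION_BOUNDARY
    if record.se0_mean > 0:
        fp = perfusion_fraction(pf.sv0, record.se0_mean)
    else:
        fp = 0.0
    record.perfusion = PerfusionParams(sv0=pf.sv0, dstar=pf.dstar, fp=fp)
    return record
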