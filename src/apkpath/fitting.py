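"""Parameter estimation and screening-library arithmetic.

Three estimation tasks live here:

* Michaelis-Menten fits of initial-rate assays (rate vs. substrate
  concentration, typically 0-110 mM in triplicate), returning kcat and
  Km with confidence intervals and an explicit reliability flag;
* catalytic-efficiency fold changes (kcat/Km ratios) between enzyme
  variants;
* calibration of cascade parameters against time-course data by
  least squares over the ODE solution, with multi-start initialization.

Plus the saturation-mutagenesis arithmetic: how many clones an NNK
(32-codon) single-site library needs for a target coverage probability,
rounded up to whole 96-well plates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
from lmfit import Model
from scipy.optimize import least_squares

from .kinetics import (
    KineticParameterSet,
    TimecourseDataset,
    simulate,
)
from .network import PathwayDesign
from .species import SpeciesRegistry

DEFAULT_ASSAY_RANGE = (0.0, 110.0)  # mM
MIN_DISTINCT_CONCENTRATIONS = 5
NNK_CODONS = 32
PLATE_SIZE = 96

#: free-parameter key: (enzyme, substrate, "kcat" | "km")
FreeParam = tuple[str, str, str]


class UnreliableFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class InitialRateAssay:
    """An initial-rate (v vs. S) assay for one enzyme on one substrate.

    ``rates`` has shape (replicates, n_concentrations) in mM/min.
    ``enzyme_loading`` is mg/mL and ``molar_mass`` kDa, so kcat can be
    recovered from the fitted Vmax.
    """

    substrate: str
    concentrations: np.ndarray  # mM
    rates: np.ndarray  # (replicates, n) mM/min
    enzyme_loading: float
    molar_mass: Optional[float] = None
    assay_range: tuple[float, float] = DEFAULT_ASSAY_RANGE
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        if rates.shape[1] != conc.shape[0]:
            raise ValueError("rates must be (replicates, n_concentrations)")
        lo, hi = self.assay_range
        if conc.min() < lo or conc.max() > hi:
            raise ValueError(
                f"concentrations outside declared assay range [{lo}, {hi}] mM"
            )
        if self.enzyme_loading <= 0:
            raise ValueError("enzyme_loading must be > 0")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "metadata", dict(self.metadata))

    @property
    def n_distinct(self) -> int:
        return len(np.unique(self.concentrations))


@dataclass(frozen=True)
class FitResult:
    """Point estimates with 95% intervals and an explicit reliability flag."""

    kcat: Optional[float]
    km: float
    vmax: float  # mM/min
    kcat_ci: Optional[tuple[float, float]]
    km_ci: Optional[tuple[float, float]]
    rmse: float
    n_obs: int
    converged: bool
    unreliable: bool
    reasons: tuple[str, ...] = ()

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat/Km (s^-1 mM^-1)."""
        if self.kcat is None:
            raise ValueError("kcat unavailable (no molar mass supplied)")
        return self.kcat / self.km


def michaelis_menten(s: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * s / (km + s)


def fit_michaelis_menten(assay: InitialRateAssay) -> FitResult:
    """Nonlinear least-squares fit of v = Vmax S / (Km + S).

    Residuals are weighted relatively (proportional error model),
    matching multiplicative assay scatter.  The result is flagged
    unreliable — never silently returned as good — when the optimizer
    fails, the rates carry no signal, the concentration grid is too
    sparse, or Km runs beyond 10x the largest assayed concentration.
    """
    s = np.tile(assay.concentrations, assay.rates.shape[0])
    v = assay.rates.ravel()
    reasons: list[str] = []
    if assay.n_distinct < MIN_DISTINCT_CONCENTRATIONS:
        reasons.append(
            f"only {assay.n_distinct} distinct concentrations "
            f"(need >= {MIN_DISTINCT_CONCENTRATIONS})"
        )
    vscale = float(np.max(np.abs(v))) if v.size else 0.0
    if vscale <= 0:
        reasons.append("rates carry no signal (all zero)")
        return FitResult(
            kcat=None, km=float("nan"), vmax=0.0, kcat_ci=None, km_ci=None,
            rmse=0.0, n_obs=v.size, converged=False, unreliable=True,
            reasons=tuple(reasons),
        )

    model = Model(michaelis_menten)
    pars = model.make_params(
        vmax=dict(value=1.2 * vscale, min=0.0),
        km=dict(value=float(np.median(assay.concentrations)) or 1.0, min=1e-9),
    )
    weights = 1.0 / np.maximum(np.abs(v), 1e-3 * vscale)
    out = model.fit(v, pars, s=s, weights=weights)

    vmax_hat = float(out.params["vmax"].value)
    km_hat = float(out.params["km"].value)
    converged = bool(out.success)
    if not converged:
        reasons.append("optimizer did not converge")
    smax = float(np.max(assay.concentrations))
    if km_hat > 10.0 * smax:
        reasons.append(f"Km estimate {km_hat:.3g} mM beyond 10x max concentration")
    if vmax_hat <= 0 or km_hat <= 0:
        reasons.append("non-positive parameter estimate")

    def ci(par) -> Optional[tuple[float, float]]:
        if par.stderr is None or not math.isfinite(par.stderr):
            return None
        return (par.value - 1.96 * par.stderr, par.value + 1.96 * par.stderr)

    kcat = kcat_ci = None
    if assay.molar_mass is not None:
        e_mm = assay.enzyme_loading / assay.molar_mass
        scale = 1.0 / (e_mm * 60.0)  # mM/min -> s^-1
        kcat = vmax_hat * scale
        vci = ci(out.params["vmax"])
        kcat_ci = (vci[0] * scale, vci[1] * scale) if vci else None
    rmse = float(np.sqrt(np.mean(out.residual**2)))
    return FitResult(
        kcat=kcat,
        km=km_hat,
        vmax=vmax_hat,
        kcat_ci=kcat_ci,
        km_ci=ci(out.params["km"]),
        rmse=rmse,
        n_obs=v.size,
        converged=converged,
        unreliable=bool(reasons),
        reasons=tuple(reasons),
    )


@dataclass(frozen=True)
class FoldChange:
    """A catalytic-efficiency ratio carrying its reliability flag."""

    value: float
    reliable: bool

    def __float__(self) -> float:
        return self.value


def efficiency_fold_change(mutant: FitResult, wildtype: FitResult) -> FoldChange:
    """(kcat/Km)_mutant / (kcat/Km)_wildtype.

    The ratio is loading-scale invariant and propagates the inputs'
    unreliability flags rather than raising.
    """
    if not (mutant.converged and wildtype.converged):
        raise UnreliableFitError("fold change requires two converged fits")
    value = mutant.efficiency / wildtype.efficiency
    return FoldChange(value=value, reliable=not (mutant.unreliable or wildtype.unreliable))


# ---------------------------------------------------------------------
# Cascade calibration
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class CascadeFitResult:
    """Estimates per freed parameter plus diagnostics."""

    estimates: Mapping[FreeParam, float]
    params: KineticParameterSet
    cost: float
    converged: bool
    nonidentifiable: tuple[FreeParam, ...] = ()
    n_starts: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "estimates", dict(self.estimates))


def _apply_free(
    params: KineticParameterSet, free: Sequence[FreeParam], values: np.ndarray
) -> KineticParameterSet:
    for (enzyme, substrate, which), val in zip(free, values):
        params = params.with_constants(enzyme, substrate, **{which: float(val)})
    return params


def fit_cascade(
    design: PathwayDesign,
    params: KineticParameterSet,
    datasets: Sequence[TimecourseDataset],
    free_params: Sequence[FreeParam],
    *,
    n_starts: int = 20,
    seed: int = 1729,
    registry: Optional[SpeciesRegistry] = None,
    sim_rtol: float = 1e-6,
    sim_atol: float = 1e-9,
    spread_decades: float = 1.0,
) -> CascadeFitResult:
    """Least-squares calibration of named cascade parameters.

    All parameters other than ``free_params`` stay fixed at their values
    in ``params``.  The optimizer works in log10 space (positivity for
    free), with residuals scaled per species by the data's dynamic range.
    ``n_starts`` initial guesses are drawn log-uniformly around the
    provided values with a fixed seed; the best final cost wins.
    Freed parameters whose profile is flat at the optimum are reported
    as non-identifiable.
    """
    for key in free_params:
        enzyme, substrate, which = key
        if which not in ("kcat", "km"):
            raise ValueError(f"free parameter kind must be kcat or km, got {which!r}")
        params.get(enzyme, substrate)  # raises MissingParameterError early
    if not free_params:
        return CascadeFitResult(
            estimates={}, params=params, cost=0.0, converged=True, n_starts=0
        )

    obs_blocks = []
    scales = []
    for ds in datasets:
        obs_blocks.append(ds.conc)
        scales.append(np.maximum(np.abs(ds.conc).max(axis=1, keepdims=True), 1e-6))

    def residuals(log10_vals: np.ndarray) -> np.ndarray:
        trial = _apply_free(params, free_params, 10.0**log10_vals)
        res = []
        for ds, obs, scale in zip(datasets, obs_blocks, scales):
            try:
                with warnings.catch_warnings():
                    # wild multi-start trials may stress the integrator
                    warnings.simplefilter("ignore")
                    sim = simulate(
                        design,
                        trial,
                        {s: float(c) for s, c in zip(ds.species, ds.conc[:, 0])},
                        grid=ds.time,
                        registry=registry,
                        rtol=sim_rtol,
                        atol=sim_atol,
                    )
            except Exception:
                return np.full(sum(o.size for o in obs_blocks), 1e3)
            # datasets sampled on the design's own species order
            res.append(((sim.conc - obs) / scale).ravel())
        return np.concatenate(res)

    def value_of(key: FreeParam) -> float:
        enzyme, substrate, which = key
        return getattr(params.get(enzyme, substrate), which)

    x_center = np.log10([value_of(k) for k in free_params])
    rng = np.random.default_rng(seed)
    starts = [x_center]
    for _ in range(max(0, n_starts - 1)):
        starts.append(
            x_center + rng.uniform(-spread_decades, spread_decades, len(free_params))
        )

    best = None
    for x0 in starts:
        sol = least_squares(residuals, x0, method="lm", xtol=1e-12, ftol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None

    fitted_vals = 10.0**best.x
    fitted_params = _apply_free(params, free_params, fitted_vals)
    cost = float(best.cost)

    # flat-profile detection: perturbing a parameter by 1.5x must move cost
    nonident: list[FreeParam] = []
    for i, key in enumerate(free_params):
        bumps = []
        for delta in (math.log10(1.5), -math.log10(1.5)):
            x = best.x.copy()
            x[i] += delta
            r = residuals(x)
            bumps.append(0.5 * float(r @ r) - cost)
        if max(bumps) < 1e-8 * (1.0 + cost):
            nonident.append(key)

    return CascadeFitResult(
        estimates={k: float(v) for k, v in zip(free_params, fitted_vals)},
        params=fitted_params,
        cost=cost,
        converged=bool(best.success),
        nonidentifiable=tuple(nonident),
        n_starts=len(starts),
    )


# ---------------------------------------------------------------------
# NNK saturation-library arithmetic
# ---------------------------------------------------------------------

class NNKScreenSize(NamedTuple):
    clones_per_library: int
    total_clones: int
    raw_clones: int


def nnk_screen_size(
    sites: int,
    coverage: float,
    *,
    mode: str = "codon",
    plate_size: int = PLATE_SIZE,
) -> NNKScreenSize:
    """Clones needed to cover an NNK single-site saturation library.

    ``raw_clones`` is the smallest N with 1 - (1 - p)^N >= coverage where
    p is the rarest variant's probability (1/32 per NNK codon in the
    default per-codon mode; 1/20 in the approximate per-residue mode).
    ``clones_per_library`` rounds that up to whole microtiter plates and
    ``total_clones`` multiplies by the number of sites.
    """
    if sites < 1:
        raise ValueError("sites must be >= 1")
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must be in (0, 1)")
    if mode == "codon":
        miss = (NNK_CODONS - 1) / NNK_CODONS
    elif mode == "residue":
        miss = 19 / 20
    else:
        raise ValueError(f"mode must be 'codon' or 'residue', got {mode!r}")
    raw = math.ceil(math.log(1.0 - coverage) / math.log(miss))
    per_library = math.ceil(raw / plate_size) * plate_size
    return NNKScreenSize(per_library, sites * per_library, raw)
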