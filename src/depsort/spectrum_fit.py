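"""Extraction of whole-cell membrane properties from DEP spectra.

A well-plate DEP analyzer reports, per sample, a *relative* DEP force at
~20 applied frequencies.  The instrument signal is modeled as

    r_i = A * Re[CM(f_i; Cspec, Gspec, sigma_cyto)]

with a single positive scale ``A`` per spectrum (absolute field-gradient
factors are unidentifiable from a relative force) and zero offset.  Fitting
this forward model by weighted least squares recovers the membrane specific
capacitance ``Cspec``, specific conductance ``Gspec``, and — from the
fitted curve — the midpoint membrane and midpoint cytoplasm frequencies.

Midpoint definitions (a documented choice of this package, recorded in the
fit metadata): the membrane midpoint is the half-rise frequency between the
low-frequency plateau (fitted Re[CM] at the bottom of the band) and the
curve maximum, on the rising branch; the cytoplasm midpoint is the
half-fall frequency between the maximum and the value at the top of the
band, on the falling branch.  The cytoplasm midpoint is flagged
*unavailable* when the maximum lies in the top decade of the band or when
the decline from maximum to band top is less than 10% of the rise
amplitude — the spectrum then does not decrease enough at high frequency
to locate a half-fall reliably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dielectric import (
    DEFAULT_CYTOPLASM,
    DEFAULT_RADIUS_M,
    DielectricMaterial,
    FrequencyGrid,
    ShelledCell,
    clausius_mossotti,
    mf_m2_to_f_m2,
)

# Multi-start bounds, lab units where noted.
CSPEC_BOUNDS_MF_M2 = (1.0, 100.0)
GSPEC_BOUNDS_S_M2 = (0.0, 5000.0)
#: Seed for placing multi-start initial values (start placement only; the
#: fit itself is deterministic given data and starts).
START_SEED = 20240
#: Flag value carried in results when the cytoplasm midpoint cannot be read
#: off the fitted band.
UNAVAILABLE = "unavailable"

MIN_POINTS = 8
MIN_DECADES = 2.5


@dataclass(frozen=True)
class DEPSpectrum:
    """One measured or synthetic DEP spectrum: relative force vs frequency."""

    grid: FrequencyGrid
    relative_force: np.ndarray
    per_point_sd: np.ndarray | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        force = np.asarray(self.relative_force, dtype=float)
        if force.shape != self.grid.frequencies.shape:
            raise ValueError("relative_force must match grid length")
        bad = np.flatnonzero(~np.isfinite(force))
        if bad.size:
            raise ValueError(f"non-finite force values at indices {bad.tolist()}")
        object.__setattr__(self, "relative_force", force)
        if self.per_point_sd is not None:
            sd = np.asarray(self.per_point_sd, dtype=float)
            if sd.shape != force.shape or np.any(sd < 0) or not np.all(np.isfinite(sd)):
                raise ValueError("per_point_sd must be finite, >= 0, same length as grid")
            object.__setattr__(self, "per_point_sd", sd)

    def check_fittable(self) -> None:
        if len(self.grid) < MIN_POINTS:
            raise ValueError(f"need >= {MIN_POINTS} points to fit, got {len(self.grid)}")
        if self.grid.decades < MIN_DECADES:
            raise ValueError(
                f"need >= {MIN_DECADES} decades of frequency coverage, "
                f"got {self.grid.decades:.2f}"
            )


@dataclass
class SpectrumFitResult:
    """Whole-cell electrophysiological properties recovered from one spectrum.

    ``cspec`` is in mF/m^2 and ``gspec`` in S/m^2 (lab reporting units).
    ``midpoint_cytoplasm_frequency`` is a frequency in Hz or ``None`` with
    ``cytoplasm_midpoint_unavailable`` set — the two are mutually exclusive.
    """

    sample_id: str
    cspec: float
    gspec: float
    cytoplasm_conductivity: float
    scale: float
    offset: float
    midpoint_membrane_frequency: float | None
    midpoint_cytoplasm_frequency: float | None
    cytoplasm_midpoint_unavailable: bool
    residual_rms: float
    converged: bool
    n_starts: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.converged:
            if not self.cspec > 0:
                raise ValueError("cspec must be > 0 for a converged fit")
            if self.gspec < 0:
                raise ValueError("gspec must be >= 0")
        if self.cytoplasm_midpoint_unavailable and self.midpoint_cytoplasm_frequency is not None:
            raise ValueError("unavailable flag and numeric cytoplasm midpoint are exclusive")

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "cspec_mf_m2": self.cspec,
            "gspec_s_m2": self.gspec,
            "cytoplasm_conductivity_s_m": self.cytoplasm_conductivity,
            "scale": self.scale,
            "offset": self.offset,
            "midpoint_membrane_frequency_hz": self.midpoint_membrane_frequency,
            "midpoint_cytoplasm_frequency_hz": self.midpoint_cytoplasm_frequency,
            "cytoplasm_midpoint_unavailable": self.cytoplasm_midpoint_unavailable,
            "residual_rms": self.residual_rms,
            "converged": self.converged,
            "n_starts": self.n_starts,
            **{f"meta_{k}": v for k, v in self.metadata.items()},
        }


def _forward(
    freqs: np.ndarray,
    cspec_mf: float,
    gspec: float,
    sigma_cyto: float,
    scale: float,
    radius: float,
    medium: DielectricMaterial,
    cyto_epsr: float,
) -> np.ndarray:
    cell = ShelledCell(
        radius=radius,
        cspec=mf_m2_to_f_m2(cspec_mf),
        gspec=gspec,
        cytoplasm=DielectricMaterial(cyto_epsr, sigma_cyto),
    )
    return scale * clausius_mossotti(cell, medium, freqs).real


def fit_spectrum(
    spectrum: DEPSpectrum,
    medium: DielectricMaterial,
    radius: float = DEFAULT_RADIUS_M,
    cytoplasm: DielectricMaterial = DEFAULT_CYTOPLASM,
    float_params: Sequence[str] = ("cspec", "gspec", "scale"),
    n_starts: int = 8,
    compute_midpoints: bool = True,
) -> SpectrumFitResult:
    """Fit the single-shell forward model to a DEP spectrum.

    Parameters
    ----------
    spectrum : DEPSpectrum
        Must have >= 8 points over >= 2.5 decades.
    medium : DielectricMaterial
        Suspending-medium properties (known from the experiment).
    radius : float
        Cell radius in meters.  Supplied, not fitted: size is measured
        independently, and floating it would confound Cspec (the first
        crossover constrains only the product r*Cspec).
    cytoplasm : DielectricMaterial
        Cytoplasm defaults; its conductivity can be floated via
        ``float_params`` containing ``"sigma_cyto"``.
    float_params : sequence of {"cspec", "gspec", "sigma_cyto", "scale"}
        Which parameters vary in the fit.
    n_starts : int
        Number of multi-start local fits (log-uniform starts, fixed seed).

    Returns
    -------
    SpectrumFitResult
        Best-of-starts weighted least-squares solution.  ``converged`` is
        False (never an exception) when no start satisfies the optimizer
        tolerance.
    """
    spectrum.check_fittable()
    allowed = {"cspec", "gspec", "sigma_cyto", "scale"}
    bad = set(float_params) - allowed
    if bad:
        raise ValueError(f"unknown float parameters {sorted(bad)}; allowed {sorted(allowed)}")

    freqs = spectrum.grid.frequencies
    force = spectrum.relative_force
    weights = None
    if spectrum.per_point_sd is not None:
        sd = np.where(spectrum.per_point_sd > 0, spectrum.per_point_sd, np.inf)
        weights = 1.0 / sd

    # A positive scale start from the data amplitude; Re[CM] peaks near 1.
    amp = float(np.max(np.abs(force)))
    amp = amp if amp > 0 else 1.0

    rng = np.random.default_rng(START_SEED)
    lo_c, hi_c = CSPEC_BOUNDS_MF_M2
    starts = []
    for k in range(n_starts):
        starts.append(
            {
                "cspec_mf": float(10 ** rng.uniform(np.log10(lo_c), np.log10(hi_c))),
                "gspec": 0.0 if k % 2 == 0 else float(10 ** rng.uniform(0, np.log10(GSPEC_BOUNDS_S_M2[1]))),
                "sigma_cyto": cytoplasm.conductivity,
                "scale": amp,
            }
        )

    def residual(params: lmfit.Parameters) -> np.ndarray:
        model = _forward(
            freqs,
            params["cspec_mf"].value,
            params["gspec"].value,
            params["sigma_cyto"].value,
            params["scale"].value,
            radius,
            medium,
            cytoplasm.relative_permittivity,
        )
        r = model - force
        return r * weights if weights is not None else r

    best = None
    best_cost = np.inf
    any_converged = False
    for start in starts:
        params = lmfit.Parameters()
        params.add("cspec_mf", value=start["cspec_mf"], min=lo_c, max=hi_c,
                   vary="cspec" in float_params)
        params.add("gspec", value=start["gspec"], min=GSPEC_BOUNDS_S_M2[0],
                   max=GSPEC_BOUNDS_S_M2[1], vary="gspec" in float_params)
        params.add("sigma_cyto", value=start["sigma_cyto"], min=1e-3, max=5.0,
                   vary="sigma_cyto" in float_params)
        params.add("scale", value=start["scale"], min=1e-12, max=1e12,
                   vary="scale" in float_params)
        try:
            out = lmfit.minimize(residual, params, method="least_squares")
        except Exception:
            continue
        cost = float(np.sum(np.asarray(out.residual) ** 2))
        if out.success:
            any_converged = True
        if cost < best_cost and out.success:
            best_cost = cost
            best = out

    if best is None:
        return SpectrumFitResult(
            sample_id=spectrum.sample_id,
            cspec=float("nan"), gspec=float("nan"),
            cytoplasm_conductivity=cytoplasm.conductivity,
            scale=float("nan"), offset=0.0,
            midpoint_membrane_frequency=None,
            midpoint_cytoplasm_frequency=None,
            cytoplasm_midpoint_unavailable=False,
            residual_rms=float("nan"), converged=False, n_starts=n_starts,
            metadata={"note": "no start converged"},
        )

    p = best.params
    resid = np.asarray(best.residual)
    result = SpectrumFitResult(
        sample_id=spectrum.sample_id,
        cspec=float(p["cspec_mf"].value),
        gspec=float(p["gspec"].value),
        cytoplasm_conductivity=float(p["sigma_cyto"].value),
        scale=float(p["scale"].value),
        offset=0.0,
        midpoint_membrane_frequency=None,
        midpoint_cytoplasm_frequency=None,
        cytoplasm_midpoint_unavailable=False,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=any_converged,
        n_starts=n_starts,
        metadata={
            "radius_m": radius,
            "medium_conductivity_s_m": medium.conductivity,
            "midpoint_definition": "half-rise/half-fall of fitted Re[CM] over the band",
            "unavailability_rule": "peak in top decade or decline < 10% of rise",
        },
    )
    if compute_midpoints:
        f_mem, f_cyt, unavailable = midpoint_frequencies(
            result, spectrum.grid, medium=medium, radius=radius,
            cyto_epsr=cytoplasm.relative_permittivity,
        )
        result.midpoint_membrane_frequency = f_mem
        result.midpoint_cytoplasm_frequency = f_cyt
        result.cytoplasm_midpoint_unavailable = unavailable
    return result


def fitted_curve(
    fit: SpectrumFitResult,
    freqs: np.ndarray,
    medium: DielectricMaterial,
    radius: float | None = None,
    cyto_epsr: float = DEFAULT_CYTOPLASM.relative_permittivity,
) -> np.ndarray:
    """Evaluate the fitted forward model (scaled Re[CM]) at ``freqs``."""
    r = radius if radius is not None else fit.metadata.get("radius_m", DEFAULT_RADIUS_M)
    return _forward(
        np.asarray(freqs, dtype=float),
        fit.cspec, fit.gspec, fit.cytoplasm_conductivity, fit.scale,
        r, medium, cyto_epsr,
    )


def midpoint_frequencies(
    fit: SpectrumFitResult,
    band: FrequencyGrid,
    medium: DielectricMaterial,
    radius: float | None = None,
    cyto_epsr: float = DEFAULT_CYTOPLASM.relative_permittivity,
    points_per_decade: int = 400,
) -> tuple[float | None, float | None, bool]:
    """Locate the half-rise (membrane) and half-fall (cytoplasm) midpoints
    of the fitted curve over ``band``.

    Returns ``(f_mid_membrane, f_mid_cytoplasm, cytoplasm_unavailable)``.
    The cytoplasm midpoint is unavailable when the curve maximum falls in
    the top decade of the band or the high-frequency decline is under 10%
    of the rise amplitude.  Raises if the fit did not converge.
    """
    if not fit.converged:
        raise RuntimeError("midpoints require a converged fit")
    lo, hi = np.log10(band.f_min), np.log10(band.f_max)
    n = max(int(np.ceil((hi - lo) * points_per_decade)) + 1, 256)
    logf = np.linspace(lo, hi, n)
    curve = fitted_curve(fit, 10.0**logf, medium, radius, cyto_epsr)
    if fit.scale < 0:  # normalize orientation; scale is positive by construction
        curve = -curve
    i_max = int(np.argmax(curve))
    plateau = float(curve[0])
    peak = float(curve[i_max])
    top = float(curve[-1])
    rise = peak - plateau

    sign_flip = -1.0 if fit.scale < 0 else 1.0

    def locate(target: float, i0: int, i1: int) -> float | None:
        seg = curve[i0 : i1 + 1] - target
        sgn = np.sign(seg)
        idx = np.flatnonzero(sgn[:-1] * sgn[1:] < 0)
        if idx.size == 0:
            return None
        j = i0 + int(idx[0])

        def g(x: float) -> float:
            val = sign_flip * fitted_curve(fit, np.array([10.0**x]), medium, radius, cyto_epsr)[0]
            return val - target

        return float(10.0 ** brentq(g, logf[j], logf[j + 1], xtol=1e-12))

    f_mem = None
    if rise > 0 and i_max > 0:
        f_mem = locate(plateau + 0.5 * rise, 0, i_max)

    # Unavailability: maximum in the top decade, or insufficient decline.
    in_top_decade = logf[i_max] > hi - 1.0
    decline = peak - top
    unavailable = in_top_decade or (rise <= 0) or (decline < 0.10 * rise)
    f_cyt = None
    if not unavailable and i_max < n - 1:
        f_cyt = locate(peak - 0.5 * decline, i_max, n - 1)
        if f_cyt is None:
            unavailable = True
    return f_mem, f_cyt, unavailable


def compare_samples(fits: Mapping[str, Iterable[SpectrumFitResult]]) -> pd.DataFrame:
    """Per-group mean/SD/SEM/n of the fitted properties (no hypothesis tests).

    ``fits`` maps a group label to its fit results; each group needs at
    least one fit.  With n = 1 the SD and SEM are reported as NaN.
    """
    rows = []
    for label, group in fits.items():
        group = list(group)
        if not group:
            raise ValueError(f"group {label!r} is empty")
        for var, getter in [
            ("cspec_mf_m2", lambda g: g.cspec),
            ("gspec_s_m2", lambda g: g.gspec),
            ("midpoint_membrane_frequency_hz", lambda g: g.midpoint_membrane_frequency),
            ("midpoint_cytoplasm_frequency_hz", lambda g: g.midpoint_cytoplasm_frequency),
        ]:
            vals = np.array([getter(g) for g in group if getter(g) is not None], dtype=float)
            n = vals.size
            mean = float(np.mean(vals)) if n else math.nan
            sd = float(np.std(vals, ddof=1)) if n > 1 else math.nan
            rows.append(
                {
                    "group": label,
                    "variable": var,
                    "mean": mean,
                    "sd": sd,
                    "sem": sd / math.sqrt(n) if n > 1 else math.nan,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)
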