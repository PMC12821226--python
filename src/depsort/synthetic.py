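"""Seeded generators for every input the pipeline consumes.

The generators emulate the study conditions of a DEP-based glioma sorting
experiment: cell populations whose membrane specific capacitance follows a
truncated normal within printed bounds, instrument-like DEP spectra
(scaled Re[CM] with multiplicative and additive noise), variable-slope
logistic dose-responses, and log-normal lectin fluorescence intensities
with a downward shift for drug-resistant presets.

Presets
-------
``D54``      control glioblastoma line, Cspec bounded 14.2-27.5 mF/m^2
``D54-TR``   its temozolomide-resistant derivative, 5.1-19.8 mF/m^2
``GBM1``     point archetype at 20 mF/m^2 (control-like)
``GBM2``     point archetype at 10 mF/m^2 (resistant-like)

The truncated-normal shape uses mean = range midpoint and sd = range/4; the
bounded ranges are measured, the shape within them is an assumption of this
package.  Every generator takes its own integer seed, so streams are
independent: adding one generator call never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .assays import DoseResponse, IntensitySample, logistic_response
from .dielectric import (
    DEFAULT_CYTOPLASM,
    DielectricMaterial,
    FrequencyGrid,
    ShelledCell,
    clausius_mossotti,
    mf_m2_to_f_m2,
    um_to_m,
)
from .sorting import CellPopulation
from .spectrum_fit import DEPSpectrum

#: Default instrument grid: 20 log-spaced points, 10 kHz - 45 MHz.
DEFAULT_GRID = FrequencyGrid.log_spaced(1e4, 4.5e7, 20)


@dataclass(frozen=True)
class PopulationPreset:
    """Distributional description of one cell population archetype.

    Cspec values are drawn from a normal(cspec_mean, cspec_sd) truncated to
    [cspec_low, cspec_high]; radii from a normal truncated to positive
    (and to the physical sanity bounds of :class:`ShelledCell`).
    """

    name: str
    cspec_low: float  # mF/m^2
    cspec_high: float
    cspec_mean: float
    cspec_sd: float
    radius_mean: float = 8.0  # um
    radius_sd: float = 1.0
    gspec: float = 0.0  # S/m^2
    cytoplasm: DielectricMaterial = DEFAULT_CYTOPLASM

    def __post_init__(self) -> None:
        if not self.cspec_low <= self.cspec_mean <= self.cspec_high:
            raise ValueError(
                f"preset {self.name!r}: mean {self.cspec_mean} outside bounds "
                f"[{self.cspec_low}, {self.cspec_high}]"
            )
        if self.cspec_low > self.cspec_high:
            raise ValueError("cspec_low must not exceed cspec_high")


def _range_preset(name: str, low: float, high: float, **kw) -> PopulationPreset:
    return PopulationPreset(
        name=name, cspec_low=low, cspec_high=high,
        cspec_mean=(low + high) / 2, cspec_sd=(high - low) / 4, **kw
    )


PRESETS: dict[str, PopulationPreset] = {
    "D54": _range_preset("D54", 14.2, 27.5),
    "D54-TR": _range_preset("D54-TR", 5.1, 19.8),
    "GBM1": PopulationPreset("GBM1", 20.0, 20.0, 20.0, 0.0, radius_sd=0.0),
    "GBM2": PopulationPreset("GBM2", 10.0, 10.0, 10.0, 0.0, radius_sd=0.0),
}


@dataclass(frozen=True)
class NoiseModel:
    """Instrument noise: multiplicative CV plus additive Gaussian floor."""

    multiplicative_cv: float = 0.0
    additive_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_cv < 0 or self.additive_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")


def preset_cell(preset: PopulationPreset | str) -> ShelledCell:
    """The archetype cell at a preset's mean Cspec and mean radius."""
    p = PRESETS[preset] if isinstance(preset, str) else preset
    return ShelledCell(
        radius=um_to_m(p.radius_mean),
        cspec=mf_m2_to_f_m2(p.cspec_mean),
        gspec=p.gspec,
        cytoplasm=p.cytoplasm,
    )


def _truncated_normal(rng, mean, sd, low, high, n):
    if sd == 0 or low == high:
        return np.full(n, mean)
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def gen_population(
    preset: PopulationPreset | str, n: int, seed: int, label: str | None = None
) -> CellPopulation:
    """Draw ``n`` cells from a preset; deterministic under ``seed``."""
    p = PRESETS[preset] if isinstance(preset, str) else preset
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    cspec = _truncated_normal(rng, p.cspec_mean, p.cspec_sd, p.cspec_low, p.cspec_high, n)
    radius = _truncated_normal(rng, p.radius_mean, p.radius_sd, 0.6, 49.0, n)
    cells = [
        ShelledCell(
            radius=um_to_m(r),
            cspec=mf_m2_to_f_m2(c),
            gspec=p.gspec,
            cytoplasm=p.cytoplasm,
        )
        for c, r in zip(cspec, radius)
    ]
    lab = label if label is not None else p.name
    return CellPopulation(
        cells=cells,
        labels=[lab] * n,
        provenance={"preset": p.name, "seed": seed, "n": n},
    )


def gen_spectrum(
    cell: ShelledCell,
    medium: DielectricMaterial,
    grid: FrequencyGrid = DEFAULT_GRID,
    noise: NoiseModel = NoiseModel(),
    scale: float = 1.0,
    sample_id: str = "",
) -> DEPSpectrum:
    """Instrument-like DEP spectrum of one cell.

    ``r_i = scale * Re[CM(f_i)] * (1 + cv * z_i) + additive_sd * w_i`` with
    z, w independent standard normals from the seeded stream.  Zero noise
    reproduces the forward model bit-exactly.
    """
    clean = scale * clausius_mossotti(cell, medium, grid.frequencies).real
    if noise.multiplicative_cv == 0 and noise.additive_sd == 0:
        return DEPSpectrum(grid=grid, relative_force=clean, sample_id=sample_id)
    rng = np.random.default_rng(noise.seed)
    z = rng.standard_normal(len(grid))
    w = rng.standard_normal(len(grid))
    force = clean * (1.0 + noise.multiplicative_cv * z) + noise.additive_sd * w
    return DEPSpectrum(grid=grid, relative_force=force, sample_id=sample_id)


def gen_dose_response(
    true_ic50: float,
    hill_slope: float,
    concentrations: np.ndarray,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> DoseResponse:
    """Forward variable-slope dose-response with multiplicative noise.

    At zero noise the response at ``X = log10(true_ic50)`` is exactly 50%.
    """
    if not true_ic50 > 0:
        raise ValueError(f"true_ic50 must be > 0 uM, got {true_ic50}")
    conc = np.asarray(concentrations, dtype=float)
    clean = logistic_response(conc, np.log10(true_ic50), hill_slope)
    if noise_cv == 0:
        return DoseResponse(conc, clean)
    rng = np.random.default_rng(seed)
    noisy = clean * (1.0 + noise_cv * rng.standard_normal(conc.size))
    return DoseResponse(conc, noisy)


def gen_lectin_intensities(
    control_logmean: float,
    tr_shift: float,
    logsd: float,
    n: int,
    seed: int,
    lectin: str = "lectin",
) -> tuple[IntensitySample, IntensitySample]:
    """Log-normal control and resistant (TR) intensity samples.

    The TR sample's log-mean is ``control_logmean + tr_shift``; a negative
    shift models reduced lectin binding in resistant cells.  Returns
    ``(control, tr)``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not logsd > 0:
        raise ValueError(f"logsd must be > 0, got {logsd}")
    rng = np.random.default_rng(seed)
    control = rng.lognormal(mean=control_logmean, sigma=logsd, size=n)
    tr = rng.lognormal(mean=control_logmean + tr_shift, sigma=logsd, size=n)
    return (
        IntensitySample(control, label=f"control:{lectin}"),
        IntensitySample(tr, label=f"TR:{lectin}"),
    )
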