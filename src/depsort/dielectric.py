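"""Single-shell dielectric model of a cell and its Clausius-Mossotti factor.

A cell in a non-uniform AC field experiences a dielectrophoretic (DEP) force
whose direction is set by the sign of the real part of the Clausius-Mossotti
(CM) factor,

    CM(f) = (eps*_p - eps*_m) / (eps*_p + 2 eps*_m),

where ``eps*_p`` is the effective complex permittivity of the particle and
``eps*_m`` that of the suspending medium.  The cell is idealized as a
conductive cytoplasm sphere bounded by a thin, poorly conducting membrane
described by its specific capacitance ``Cspec`` (F/m^2) and specific
conductance ``Gspec`` (S/m^2).  In this thin-shell parameterization the
effective particle permittivity is

    eps*_p = r C*_spec eps*_cyto / (r C*_spec + eps*_cyto),

with ``C*_spec(w) = Cspec - j Gspec / w`` and ``r`` the cell radius.

All quantities are SI internally (m, F/m^2, S/m^2, S/m, Hz).  Convenience
converters for the laboratory units (mF/m^2, uS/cm, um) live at the bottom
of this module and are the only place unit conversion happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.optimize import brentq

#: Vacuum permittivity, F/m.
EPS0 = 8.8541878128e-12

# Radius sanity bounds for a mammalian cell, meters.
_RADIUS_MIN = 0.5e-6
_RADIUS_MAX = 50e-6

_DEGENERACY_FLOOR = 1e-30


class DegenerateModelError(ArithmeticError):
    """Raised when a denominator in the shell model is numerically zero,
    signalling a nonphysical parameter combination."""


@dataclass(frozen=True)
class DielectricMaterial:
    """A homogeneous lossy dielectric: relative permittivity and conductivity.

    Parameters
    ----------
    relative_permittivity : float
        Dimensionless relative permittivity, > 0.
    conductivity : float
        Conductivity in S/m, >= 0.
    """

    relative_permittivity: float
    conductivity: float

    def __post_init__(self) -> None:
        if not (self.relative_permittivity > 0 and np.isfinite(self.relative_permittivity)):
            raise ValueError(
                f"relative_permittivity must be finite and > 0, got {self.relative_permittivity}"
            )
        if not (self.conductivity >= 0 and np.isfinite(self.conductivity)):
            raise ValueError(f"conductivity must be finite and >= 0, got {self.conductivity}")


@dataclass(frozen=True)
class ShelledCell:
    """Single-shell cell: radius, membrane Cspec/Gspec and cytoplasm dielectric.

    Parameters
    ----------
    radius : float
        Cell radius in meters; must lie in (0.5e-6, 50e-6).
    cspec : float
        Specific membrane capacitance in F/m^2 (lab values in mF/m^2 must be
        converted with :func:`mf_m2_to_f_m2`), > 0.
    gspec : float
        Specific membrane conductance in S/m^2, >= 0.
    cytoplasm : DielectricMaterial
        Cytoplasm permittivity and conductivity.
    """

    radius: float
    cspec: float
    gspec: float
    cytoplasm: DielectricMaterial

    def __post_init__(self) -> None:
        if not (_RADIUS_MIN < self.radius < _RADIUS_MAX):
            raise ValueError(
                f"radius must be in ({_RADIUS_MIN}, {_RADIUS_MAX}) m, got {self.radius}"
            )
        if not (self.cspec > 0 and np.isfinite(self.cspec)):
            raise ValueError(f"cspec must be finite and > 0 F/m^2, got {self.cspec}")
        if not (self.gspec >= 0 and np.isfinite(self.gspec)):
            raise ValueError(f"gspec must be finite and >= 0 S/m^2, got {self.gspec}")


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly ascending grid of positive applied-field frequencies (Hz)."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(f)) or not np.all(f > 0):
            raise ValueError("all frequencies must be finite and > 0 Hz")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly ascending")
        object.__setattr__(self, "frequencies", f)

    @classmethod
    def log_spaced(cls, f_lo: float, f_hi: float, n: int) -> "FrequencyGrid":
        """``n`` log-spaced points between ``f_lo`` and ``f_hi`` inclusive."""
        if not (0 < f_lo < f_hi):
            raise ValueError(f"need 0 < f_lo < f_hi, got ({f_lo}, {f_hi})")
        return cls(np.logspace(np.log10(f_lo), np.log10(f_hi), n))

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def f_min(self) -> float:
        return float(self.frequencies[0])

    @property
    def f_max(self) -> float:
        return float(self.frequencies[-1])

    @property
    def decades(self) -> float:
        return float(np.log10(self.f_max / self.f_min))


@dataclass(frozen=True)
class CMSpectrum:
    """Clausius-Mossotti factor evaluated on a frequency grid."""

    grid: FrequencyGrid
    cm_values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        cm = np.asarray(self.cm_values, dtype=complex)
        if cm.shape != self.grid.frequencies.shape:
            raise ValueError("cm_values must match grid length")
        object.__setattr__(self, "cm_values", cm)

    @property
    def re_cm(self) -> np.ndarray:
        return self.cm_values.real


def complex_permittivity(material: DielectricMaterial, frequency) -> complex:
    """Complex permittivity ``eps0*eps_r - j sigma/(2 pi f)`` in F/m.

    ``frequency`` may be a scalar or array of positive values in Hz.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0) or not np.all(np.isfinite(f)):
        bad = f[~(np.isfinite(f) & (f > 0))].ravel()
        raise ValueError(f"frequency must be finite and > 0 Hz, got {bad[:5]}")
    omega = 2.0 * np.pi * f
    out = EPS0 * material.relative_permittivity - 1j * material.conductivity / omega
    return complex(out) if np.isscalar(frequency) else out


def effective_cell_permittivity(cell: ShelledCell, frequency) -> complex:
    """Effective complex permittivity of the shelled cell (F/m).

    Thin-shell closed form: ``eps*_p = r C* eps*_c / (r C* + eps*_c)`` with
    complex specific membrane capacitance ``C* = Cspec - j Gspec/omega``.
    At low frequency with an insulating membrane this tends to the real
    value ``r * Cspec``.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0) or not np.all(np.isfinite(f)):
        raise ValueError(f"frequency must be finite and > 0 Hz, got {frequency}")
    omega = 2.0 * np.pi * f
    c_star = cell.cspec - 1j * cell.gspec / omega
    eps_cyto = complex_permittivity(cell.cytoplasm, frequency)
    denom = cell.radius * c_star + eps_cyto
    if np.any(np.abs(denom) < _DEGENERACY_FLOOR):
        raise DegenerateModelError(
            "shell-model denominator vanished; nonphysical parameter combination"
        )
    out = cell.radius * c_star * eps_cyto / denom
    return complex(out) if np.isscalar(frequency) else out


def clausius_mossotti(cell: ShelledCell, medium: DielectricMaterial, frequency) -> complex:
    """Clausius-Mossotti factor ``(eps*_p - eps*_m)/(eps*_p + 2 eps*_m)``.

    ``Re[CM] > 0`` means positive DEP (attraction to high-field regions);
    ``Re[CM] <= 0`` is treated as negative DEP everywhere downstream.
    For physical inputs Re[CM] lies in [-0.5, 1].
    """
    eps_p = effective_cell_permittivity(cell, frequency)
    eps_m = complex_permittivity(medium, frequency)
    denom = eps_p + 2.0 * eps_m
    if np.any(np.abs(denom) < _DEGENERACY_FLOOR):
        raise DegenerateModelError("CM denominator vanished")
    out = (eps_p - eps_m) / denom
    return complex(out) if np.isscalar(frequency) else out


def cm_spectrum(cell: ShelledCell, medium: DielectricMaterial, grid: FrequencyGrid) -> CMSpectrum:
    """Evaluate the CM factor on every grid point."""
    return CMSpectrum(grid=grid, cm_values=clausius_mossotti(cell, medium, grid.frequencies))


def _re_cm_func(cell: ShelledCell, medium: DielectricMaterial):
    def f(log10_freq: float) -> float:
        return clausius_mossotti(cell, medium, 10.0**log10_freq).real

    return f


def crossover_frequencies(
    cell: ShelledCell,
    medium: DielectricMaterial,
    search_band: FrequencyGrid,
    points_per_decade: int = 60,
    rtol: float = 1e-6,
) -> list[float]:
    """Frequencies in the band where Re[CM] changes sign, ascending.

    Sign-scan on a log grid (``points_per_decade`` resolution) followed by
    bisection (Brent) to relative tolerance ``rtol``.  Tangencies without a
    sign change are not reported.  An all-positive or all-negative band
    yields an empty list.
    """
    if search_band.decades < 2:
        raise ValueError(
            f"search band must span >= 2 decades, got {search_band.decades:.2f}"
        )
    lo, hi = np.log10(search_band.f_min), np.log10(search_band.f_max)
    n = max(int(np.ceil((hi - lo) * points_per_decade)) + 1, 16)
    logf = np.linspace(lo, hi, n)
    re = clausius_mossotti(cell, medium, 10.0**logf).real
    g = _re_cm_func(cell, medium)
    roots: list[float] = []
    for i in range(n - 1):
        if re[i] == 0.0:  # grid point exactly on a zero: tangency handling below
            continue
        if re[i] * re[i + 1] < 0:
            x = brentq(g, logf[i], logf[i + 1], xtol=1e-12, rtol=max(rtol, 4e-16))
            roots.append(10.0**x)
    return sorted(roots)


def separation_window(
    cell_a: ShelledCell,
    cell_b: ShelledCell,
    medium: DielectricMaterial,
    band: FrequencyGrid,
    points_per_decade: int = 200,
) -> tuple[float, float] | None:
    """Maximal frequency interval where ``cell_a`` is in positive DEP and
    ``cell_b`` in negative DEP.

    By convention ``cell_a`` is the higher-Cspec candidate.  The band is
    refined to ``points_per_decade`` and the widest contiguous interval with
    Re[CM_a] > 0 and Re[CM_b] < 0 is returned, with endpoints tightened to
    the nearest sign-change roots.  ``None`` means no such window exists —
    a valid outcome, not an error.
    """
    lo, hi = np.log10(band.f_min), np.log10(band.f_max)
    n = max(int(np.ceil((hi - lo) * points_per_decade)) + 1, 64)
    logf = np.linspace(lo, hi, n)
    freqs = 10.0**logf
    re_a = clausius_mossotti(cell_a, medium, freqs).real
    re_b = clausius_mossotti(cell_b, medium, freqs).real
    ok = (re_a > 0) & (re_b < 0)
    if not ok.any():
        return None
    # widest contiguous run of True
    idx = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
    starts, ends = idx[0::2], idx[1::2] - 1
    widths = logf[ends] - logf[starts]
    k = int(np.argmax(widths))
    i0, i1 = int(starts[k]), int(ends[k])

    ga, gb = _re_cm_func(cell_a, medium), _re_cm_func(cell_b, medium)

    def refine(i_edge: int, outward: int) -> float:
        """Tighten a window edge to the sign-change root in the grid cell
        just outside the run; the edge is the root closest to the run."""
        j = i_edge + outward
        if j < 0 or j >= n:
            return logf[i_edge]
        a, b = sorted((logf[i_edge], logf[j]))
        roots = [
            brentq(gfun, a, b, xtol=1e-12)
            for gfun in (ga, gb)
            if gfun(a) * gfun(b) < 0
        ]
        if not roots:
            return logf[i_edge]
        return max(roots) if outward < 0 else min(roots)

    f_lo = 10.0 ** refine(i0, -1)
    f_hi = 10.0 ** refine(i1, +1)
    if f_lo >= f_hi:
        f_lo, f_hi = float(freqs[i0]), float(freqs[i1])
    return (float(f_lo), float(f_hi))


# ---------------------------------------------------------------------------
# Unit conversions (the only place lab units meet SI).

def mf_m2_to_f_m2(cspec_mf: float) -> float:
    """mF/m^2 -> F/m^2 (exact: 20 mF/m^2 = 0.02 F/m^2)."""
    return cspec_mf * 1e-3


def f_m2_to_mf_m2(cspec_f: float) -> float:
    return cspec_f * 1e3


def us_cm_to_s_m(sigma_us_cm: float) -> float:
    """uS/cm -> S/m (exact: 100 uS/cm = 0.01 S/m)."""
    return sigma_us_cm * 1e-4


def s_m_to_us_cm(sigma_s_m: float) -> float:
    return sigma_s_m * 1e4


def um_to_m(r_um: float) -> float:
    return r_um * 1e-6


# Literature-typical defaults for quantities the model needs but a DEP
# spectrum alone does not pin down; surfaced here so callers can override.
DEFAULT_RADIUS_M = 8e-6
DEFAULT_CYTOPLASM = DielectricMaterial(relative_permittivity=60.0, conductivity=0.5)
DEFAULT_MEDIUM_EPSR = 78.0


def make_cell(
    cspec_mf_m2: float,
    gspec_s_m2: float = 0.0,
    radius_um: float = DEFAULT_RADIUS_M * 1e6,
    cytoplasm: DielectricMaterial = DEFAULT_CYTOPLASM,
) -> ShelledCell:
    """Build a :class:`ShelledCell` from lab units (mF/m^2, um)."""
    return ShelledCell(
        radius=um_to_m(radius_um),
        cspec=mf_m2_to_f_m2(cspec_mf_m2),
        gspec=gspec_s_m2,
        cytoplasm=cytoplasm,
    )


def make_medium(
    conductivity_us_cm: float, relative_permittivity: float = DEFAULT_MEDIUM_EPSR
) -> DielectricMaterial:
    """Build a suspending medium from lab units (uS/cm)."""
    return DielectricMaterial(
        relative_permittivity=relative_permittivity,
        conductivity=us_cm_to_s_m(conductivity_us_cm),
    )
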