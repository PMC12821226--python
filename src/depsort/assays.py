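"""Drug-resistance and lectin-binding readouts.

Resistance to a chemotherapeutic is quantified as the IC50 of a
dose-response curve, fitted with the log-inhibitor versus normalized
response, variable-slope logistic model:

    Y = 100 / (1 + 10^((logIC50 - X) * h)),   X = log10(concentration)

with top/bottom fixed at 100/0 (the normalized-response variant).  The
hill slope ``h`` may take either sign; a falling dose-response fits with
h < 0 under this parameterization, and the fitted sign is reported as-is.

Lectin-binding flow-cytometry statistics: mean fluorescence intensity
(MFI), a 50% gate placed at the median of the control sample, and the
percentage of a test sample strictly above that gate.  Values equal to
the threshold count as low — a deterministic tie rule (so an all-identical
sample reads 0% high against its own gate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


@dataclass(frozen=True)
class DoseResponse:
    """Normalized viability (%) versus drug concentration (uM, ascending)."""

    concentrations: np.ndarray
    responses: np.ndarray
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if c.shape != r.shape or c.ndim != 1:
            raise ValueError("concentrations and responses must be equal-length 1-D")
        if np.any(c <= 0) or not np.all(np.isfinite(c)):
            raise ValueError("concentrations must be finite and > 0 uM")
        if not np.all(np.diff(c) > 0):
            raise ValueError("concentrations must be strictly ascending")
        if not np.all(np.isfinite(r)):
            raise ValueError("responses must be finite")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", r)

    def check_fittable(self) -> None:
        if np.unique(self.concentrations).size < 5:
            raise ValueError("need >= 5 distinct concentrations to fit")
        span = np.log10(self.concentrations[-1] / self.concentrations[0])
        if span < 2.0:
            raise ValueError(f"need >= 2 log units of concentration span, got {span:.2f}")


@dataclass(frozen=True)
class IC50Fit:
    """Variable-slope logistic fit: log10 IC50, hill slope, diagnostics."""

    log_ic50: float
    hill_slope: float
    residual_rms: float
    converged: bool
    diagnostic: str = ""

    @property
    def ic50(self) -> float:
        return 10.0**self.log_ic50


@dataclass(frozen=True)
class IntensitySample:
    """Fluorescence intensities (arbitrary units, >= 0) for one stain/sample."""

    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.intensities, dtype=float)
        if x.ndim != 1 or x.size == 0:
            raise ValueError("intensities must be a non-empty 1-D array")
        if not np.all(np.isfinite(x)) or np.any(x < 0):
            raise ValueError("intensities must be finite and >= 0")
        object.__setattr__(self, "intensities", x)


@dataclass(frozen=True)
class GateStats:
    threshold: float
    percent_high: float
    mfi: float
    degenerate: bool = False  # all control intensities identical

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_high <= 100.0):
            raise ValueError("percent_high must lie in [0, 100]")


def normalize_response(raw_treated, raw_untreated: float, raw_blank: float):
    """Map absorbance to percent viability: untreated -> 100, blank -> 0.

    ``100 * (A_treated - A_blank) / (A_untreated - A_blank)``; linear in
    between.  An untreated signal at or below blank indicates assay failure.
    """
    if not raw_untreated > raw_blank:
        raise ValueError(
            f"untreated absorbance ({raw_untreated}) must exceed blank ({raw_blank})"
        )
    return 100.0 * (np.asarray(raw_treated, dtype=float) - raw_blank) / (
        raw_untreated - raw_blank
    )


def logistic_response(concentrations, log_ic50: float, hill_slope: float):
    """Forward variable-slope model, top/bottom fixed at 100/0."""
    x = np.log10(np.asarray(concentrations, dtype=float))
    return 100.0 / (1.0 + 10.0 ** ((log_ic50 - x) * hill_slope))


def fit_ic50(dr: DoseResponse, n_starts: int = 7) -> IC50Fit:
    """Least-squares fit of the variable-slope model.

    Multi-start over log IC50 values spanning the measured concentration
    range crossed with rising/falling slope starts; the best (lowest-SSE)
    converged start wins.  A dose-response flat across all doses is
    non-identifiable and returns ``converged=False`` with a diagnostic,
    never an exception.
    """
    dr.check_fittable()
    x = np.log10(dr.concentrations)
    y = dr.responses
    if np.ptp(y) < 1e-9:
        return IC50Fit(
            log_ic50=float("nan"), hill_slope=float("nan"),
            residual_rms=float("nan"), converged=False,
            diagnostic="responses constant across doses; IC50 not identifiable",
        )

    def resid(p):
        return logistic_response(dr.concentrations, p[0], p[1]) - y

    log_starts = np.linspace(x[0], x[-1], n_starts)
    best = None
    best_cost = np.inf
    for lx in log_starts:
        for h0 in (-1.0, 1.0):
            sol = least_squares(resid, x0=[lx, h0], method="lm", xtol=1e-14, ftol=1e-14)
            if sol.success and sol.cost < best_cost:
                best_cost = sol.cost
                best = sol
    if best is None:
        return IC50Fit(
            log_ic50=float("nan"), hill_slope=float("nan"),
            residual_rms=float("nan"), converged=False,
            diagnostic="no start converged",
        )
    r = best.fun
    return IC50Fit(
        log_ic50=float(best.x[0]),
        hill_slope=float(best.x[1]),
        residual_rms=float(np.sqrt(np.mean(r**2))),
        converged=True,
    )


def fold_change_ic50(sample: IC50Fit, reference: IC50Fit) -> float:
    """IC50 fold change of ``sample`` relative to ``reference`` (dimensionless)."""
    if not (sample.converged and reference.converged):
        raise RuntimeError("fold change requires two converged fits")
    return sample.ic50 / reference.ic50


def bootstrap_ic50_ci(
    dr: DoseResponse, n_boot: int = 1000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Seeded case-resampling bootstrap percentile CI for the IC50 (uM)."""
    rng = np.random.default_rng(seed)
    n = dr.concentrations.size
    est = []
    for _ in range(n_boot):
        idx = np.sort(rng.integers(0, n, size=n))
        idx = np.unique(idx)
        if np.unique(dr.concentrations[idx]).size < 5:
            continue
        try:
            sub = DoseResponse(dr.concentrations[idx], dr.responses[idx])
            fit = fit_ic50(sub)
        except ValueError:
            continue
        if fit.converged:
            est.append(fit.ic50)
    if len(est) < 10:
        raise RuntimeError("too few successful bootstrap fits for a CI")
    a = (1 - level) / 2
    lo, hi = np.quantile(est, [a, 1 - a])
    return float(lo), float(hi)


def mfi(sample: IntensitySample) -> float:
    """Mean fluorescence intensity: the arithmetic mean of the sample."""
    return float(np.mean(sample.intensities))


def gate_fifty_percent(control: IntensitySample) -> float:
    """50% gate for a control sample: its median intensity.

    With an even number of distinct values exactly half the control lies
    strictly above the gate; ties at the gate count as low.
    """
    if control.intensities.size < 2:
        raise ValueError("need >= 2 control intensities to place a 50% gate")
    return float(np.median(control.intensities))


def percent_high(sample: IntensitySample, threshold: float) -> float:
    """Percent of intensities strictly above ``threshold``."""
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    return float(100.0 * np.mean(sample.intensities > threshold))


def gate_stats(sample: IntensitySample, control: IntensitySample) -> GateStats:
    """MFI plus percent-high of ``sample`` against the control's 50% gate."""
    thr = gate_fifty_percent(control)
    return GateStats(
        threshold=thr,
        percent_high=percent_high(sample, thr),
        mfi=mfi(sample),
        degenerate=bool(np.ptp(control.intensities) == 0),
    )
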