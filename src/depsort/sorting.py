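"""Virtual DEP sorting of cell populations.

Microfluidic DEP sorters direct cells by the sign (and, with a graded
electrode array, the magnitude) of the real part of the Clausius-Mossotti
factor at the applied frequency: positive-DEP cells focus along the
electrodes into an inner channel, negative-DEP cells stay unfocused and
exit the outer channels.  The virtual sorter classifies by Re[CM] alone;
drive voltage and flow rate are recorded as metadata because the induced
force's sign, not the device hydrodynamics, is the separation principle
modeled here.

Two modes:

* two-way ("focused"/"unfocused"): Re[CM] > 0 -> focused, else unfocused.
* three-way (outlets "1"/"2"/"3"): Re[CM] >= tau -> outlet 1 (strong
  positive DEP), 0 < Re[CM] < tau -> outlet 2 (weak positive DEP),
  Re[CM] <= 0 -> outlet 3 (no net force or negative DEP).

Re[CM] exactly 0 classifies as negative DEP (unfocused / outlet 3) — a
deterministic, conservative tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dielectric import DielectricMaterial, FrequencyGrid, ShelledCell, clausius_mossotti, f_m2_to_mf_m2

TWO_WAY_OUTLETS = ("focused", "unfocused")
THREE_WAY_OUTLETS = ("1", "2", "3")


@dataclass
class CellPopulation:
    """A list of single-shell cells with per-cell class labels."""

    cells: list[ShelledCell]
    labels: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.labels):
            raise ValueError("cells and labels must have equal length")

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def cspec_mf_m2(self) -> np.ndarray:
        return np.array([f_m2_to_mf_m2(c.cspec) for c in self.cells])

    def require_nonempty(self) -> None:
        if not self.cells:
            raise ValueError("population is empty")

    @staticmethod
    def concatenate(*pops: "CellPopulation") -> "CellPopulation":
        cells: list[ShelledCell] = []
        labels: list[str] = []
        for p in pops:
            cells.extend(p.cells)
            labels.extend(p.labels)
        return CellPopulation(cells=cells, labels=labels,
                              provenance={"concatenated": [p.provenance for p in pops]})


@dataclass(frozen=True)
class SortConfig:
    """Applied frequency and mode of a virtual sort.

    ``voltage_vpp`` and ``flow_ul_min`` are recorded for provenance and do
    not enter the classification.
    """

    applied_frequency: float
    mode: str = "two_way"
    tau: float = 0.1
    capture_probability: float = 1.0
    capture_seed: int | None = None
    voltage_vpp: float | None = None
    flow_ul_min: float | None = None

    def __post_init__(self) -> None:
        if not (self.applied_frequency > 0):
            raise ValueError(f"applied_frequency must be > 0 Hz, got {self.applied_frequency}")
        if self.mode not in ("two_way", "three_way"):
            raise ValueError(f"mode must be 'two_way' or 'three_way', got {self.mode!r}")
        if self.mode == "three_way" and not (0 < self.tau < 1):
            raise ValueError(f"tau must be in (0, 1) for three-way sorting, got {self.tau}")
        if not (0 < self.capture_probability <= 1):
            raise ValueError("capture_probability must be in (0, 1]")


@dataclass
class SortResult:
    """Per-cell outlet assignment plus per-outlet composition and enrichment."""

    per_cell: pd.DataFrame  # columns: cell_index, label, re_cm, outlet
    outlets: tuple[str, ...]
    fractions: dict[str, float]
    counts: dict[str, int]
    per_outlet_mean_cspec: dict[str, float]  # mF/m^2; NaN for empty outlets
    enrichment: dict[str, dict[str, float]]  # outlet -> label -> fold
    config: SortConfig

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"outlet fractions must sum to 1, got {total}")


def assign_dep_response(
    population: CellPopulation, medium: DielectricMaterial, frequency: float
) -> pd.DataFrame:
    """Per-cell Re[CM] at ``frequency`` with its positive/negative DEP class.

    Re[CM] > 0 classifies as ``"positive"``; Re[CM] <= 0 as ``"negative"``.
    """
    population.require_nonempty()
    if not frequency > 0:
        raise ValueError(f"frequency must be > 0 Hz, got {frequency}")
    re_cm = np.array(
        [clausius_mossotti(c, medium, frequency).real for c in population.cells]
    )
    return pd.DataFrame(
        {
            "cell_index": np.arange(len(population)),
            "label": population.labels,
            "re_cm": re_cm,
            "dep_class": np.where(re_cm > 0, "positive", "negative"),
        }
    )


def _outlet_two_way(re_cm: np.ndarray) -> np.ndarray:
    return np.where(re_cm > 0, "focused", "unfocused")


def _outlet_three_way(re_cm: np.ndarray, tau: float) -> np.ndarray:
    out = np.full(re_cm.shape, "3", dtype=object)
    out[re_cm > 0] = "2"
    out[re_cm >= tau] = "1"
    return out


def _build_result(
    population: CellPopulation,
    table: pd.DataFrame,
    outlet: np.ndarray,
    outlets: tuple[str, ...],
    config: SortConfig,
) -> SortResult:
    table = table.copy()
    table["outlet"] = outlet
    n = len(table)
    counts = {o: int((table["outlet"] == o).sum()) for o in outlets}
    fractions = {o: counts[o] / n for o in outlets}
    cspec = population.cspec_mf_m2
    mean_cspec = {
        o: float(np.mean(cspec[table["outlet"].to_numpy() == o])) if counts[o] else float("nan")
        for o in outlets
    }
    input_props = {lab: population.labels.count(lab) / n for lab in set(population.labels)}
    enrichment: dict[str, dict[str, float]] = {}
    for o in outlets:
        sub = table.loc[table["outlet"] == o, "label"]
        if len(sub) == 0:
            enrichment[o] = {lab: float("nan") for lab in input_props}
            continue
        enrichment[o] = {
            lab: (sub == lab).mean() / input_props[lab] for lab in input_props
        }
    return SortResult(
        per_cell=table,
        outlets=outlets,
        fractions=fractions,
        counts=counts,
        per_outlet_mean_cspec=mean_cspec,
        enrichment=enrichment,
        config=config,
    )


def _apply_capture(re_cm: np.ndarray, config: SortConfig) -> np.ndarray:
    """Optional partial-capture inefficiency: each positive-DEP cell is
    actually captured with probability ``capture_probability``; escapees
    behave as unfocused (Re[CM] coerced to 0)."""
    if config.capture_probability >= 1.0:
        return re_cm
    rng = np.random.default_rng(config.capture_seed)
    escaped = (re_cm > 0) & (rng.random(re_cm.shape) > config.capture_probability)
    out = re_cm.copy()
    out[escaped] = 0.0
    return out


def sort_two_way(
    population: CellPopulation, medium: DielectricMaterial, config: SortConfig
) -> SortResult:
    """Two-fraction virtual sort: positive DEP -> focused, else unfocused."""
    if config.mode != "two_way":
        raise ValueError("config.mode must be 'two_way'")
    table = assign_dep_response(population, medium, config.applied_frequency)
    re_cm = _apply_capture(table["re_cm"].to_numpy(), config)
    return _build_result(population, table, _outlet_two_way(re_cm), TWO_WAY_OUTLETS, config)


def sort_three_way(
    population: CellPopulation, medium: DielectricMaterial, config: SortConfig
) -> SortResult:
    """Three-outlet virtual sort graded by Re[CM] magnitude.

    Outlet 1 collects strong positive DEP (Re[CM] >= tau), outlet 2 weaker
    positive DEP, outlet 3 no net force or negative DEP.
    """
    if config.mode != "three_way":
        raise ValueError("config.mode must be 'three_way'")
    table = assign_dep_response(population, medium, config.applied_frequency)
    re_cm = _apply_capture(table["re_cm"].to_numpy(), config)
    return _build_result(
        population, table, _outlet_three_way(re_cm, config.tau), THREE_WAY_OUTLETS, config
    )


def choose_sorting_frequency(
    pop_a: CellPopulation,
    pop_b: CellPopulation,
    medium: DielectricMaterial,
    band: FrequencyGrid,
    points_per_decade: int = 30,
) -> tuple[float, float]:
    """Frequency maximizing the separation objective
    ``J(f) = fraction_positive(pop_a, f) - fraction_positive(pop_b, f)``
    over a log grid of the band; ties resolve to the lowest frequency.

    Returns ``(frequency, J_at_frequency)``.  ``J <= 0`` everywhere is a
    valid, reported outcome.
    """
    pop_a.require_nonempty()
    pop_b.require_nonempty()
    lo, hi = np.log10(band.f_min), np.log10(band.f_max)
    n = max(int(np.ceil((hi - lo) * points_per_decade)) + 1, 16)
    freqs = 10.0 ** np.linspace(lo, hi, n)

    def frac_positive(pop: CellPopulation) -> np.ndarray:
        re = np.array(
            [clausius_mossotti(c, medium, freqs).real for c in pop.cells]
        )
        return (re > 0).mean(axis=0)

    j = frac_positive(pop_a) - frac_positive(pop_b)
    k = int(np.argmax(j))  # argmax returns the first (lowest-frequency) maximizer
    return float(freqs[k]), float(j[k])


def enrichment_metrics(result: SortResult, target_label: str) -> dict[str, float]:
    """Per-outlet fold-enrichment of ``target_label`` relative to the input
    mixture; empty outlets report NaN."""
    labels = result.per_cell["label"]
    if target_label not in set(labels):
        raise ValueError(f"label {target_label!r} absent from the input population")
    return {o: result.enrichment[o][target_label] for o in result.outlets}
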