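"""CSV/JSON readers and writers for the pipeline's table dialects.

All CSVs have a header row; lines starting with ``#`` carry provenance
(preset name, seed, package version) and are ignored on read.  Unit
conversion to SI happens here and only here: files carry lab units
(mF/m^2, uS/cm, um), the in-memory objects are SI.

Dialects
--------
spectrum       ``frequency_hz,relative_force[,sd]``
population     ``cell_id,label,cspec_mf_m2,gspec_s_m2,radius_um,cyto_sigma_s_m,cyto_epsr``
dose-response  ``concentration_um,response_pct[,replicate]``
intensity      ``intensity,label``
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .assays import DoseResponse, IntensitySample
from .dielectric import DielectricMaterial, FrequencyGrid, ShelledCell, f_m2_to_mf_m2, mf_m2_to_f_m2, um_to_m
from .sorting import CellPopulation, SortResult
from .spectrum_fit import DEPSpectrum, SpectrumFitResult


class FormatError(ValueError):
    """A file does not match its expected dialect."""


def _read_table(path, expected: list[str], optional: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse as CSV ({exc})") from exc
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing column(s) {missing}; expected header "
            f"{','.join(expected + ['[' + c + ']' for c in (optional or [])])}"
        )
    keep = expected + [c for c in (optional or []) if c in df.columns]
    df = df[keep]
    for col in keep:
        if df[col].dtype == object and col not in ("label", "replicate", "cell_id"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise FormatError(f"{path}: non-numeric value in column {col!r} at row {bad[0] + 2}")
            df[col] = coerced
    return df


def _provenance_header(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def read_spectrum_csv(path) -> DEPSpectrum:
    df = _read_table(path, ["frequency_hz", "relative_force"], ["sd"])
    freqs = df["frequency_hz"].to_numpy(dtype=float)
    if not np.all(np.diff(freqs) > 0):
        raise FormatError(f"{path}: frequencies must be strictly ascending")
    sd = df["sd"].to_numpy(dtype=float) if "sd" in df.columns else None
    return DEPSpectrum(
        grid=FrequencyGrid(freqs),
        relative_force=df["relative_force"].to_numpy(dtype=float),
        per_point_sd=sd,
        sample_id=Path(path).stem,
    )


def write_spectrum_csv(spectrum: DEPSpectrum, path, provenance: dict | None = None) -> None:
    df = pd.DataFrame(
        {"frequency_hz": spectrum.grid.frequencies, "relative_force": spectrum.relative_force}
    )
    if spectrum.per_point_sd is not None:
        df["sd"] = spectrum.per_point_sd
    Path(path).write_text(
        _provenance_header(provenance) + df.to_csv(index=False, float_format="%.17g")
    )


_POP_COLS = ["cell_id", "label", "cspec_mf_m2", "gspec_s_m2", "radius_um",
             "cyto_sigma_s_m", "cyto_epsr"]


def read_population_csv(path) -> CellPopulation:
    df = _read_table(path, _POP_COLS)
    cells = [
        ShelledCell(
            radius=um_to_m(row.radius_um),
            cspec=mf_m2_to_f_m2(row.cspec_mf_m2),
            gspec=row.gspec_s_m2,
            cytoplasm=DielectricMaterial(row.cyto_epsr, row.cyto_sigma_s_m),
        )
        for row in df.itertuples()
    ]
    return CellPopulation(cells=cells, labels=df["label"].astype(str).tolist(),
                          provenance={"source": str(path)})


def write_population_csv(pop: CellPopulation, path, provenance: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i:06d}" for i in range(len(pop))],
            "label": pop.labels,
            "cspec_mf_m2": [f_m2_to_mf_m2(c.cspec) for c in pop.cells],
            "gspec_s_m2": [c.gspec for c in pop.cells],
            "radius_um": [c.radius * 1e6 for c in pop.cells],
            "cyto_sigma_s_m": [c.cytoplasm.conductivity for c in pop.cells],
            "cyto_epsr": [c.cytoplasm.relative_permittivity for c in pop.cells],
        }
    )
    merged = dict(pop.provenance)
    merged.update(provenance or {})
    Path(path).write_text(_provenance_header(merged) + df.to_csv(index=False, float_format="%.17g"))


def read_dose_response_csv(path) -> DoseResponse:
    df = _read_table(path, ["concentration_um", "response_pct"], ["replicate"])
    return DoseResponse(
        concentrations=df["concentration_um"].to_numpy(dtype=float),
        responses=df["response_pct"].to_numpy(dtype=float),
    )


def write_dose_response_csv(dr: DoseResponse, path, provenance: dict | None = None) -> None:
    df = pd.DataFrame(
        {"concentration_um": dr.concentrations, "response_pct": dr.responses}
    )
    Path(path).write_text(
        _provenance_header(provenance) + df.to_csv(index=False, float_format="%.17g")
    )


def read_intensity_csv(path) -> IntensitySample:
    df = _read_table(path, ["intensity"], ["label"])
    label = str(df["label"].iloc[0]) if "label" in df.columns and len(df) else ""
    return IntensitySample(df["intensity"].to_numpy(dtype=float), label=label)


def write_intensity_csv(sample: IntensitySample, path, provenance: dict | None = None) -> None:
    df = pd.DataFrame({"intensity": sample.intensities, "label": sample.label})
    Path(path).write_text(
        _provenance_header(provenance) + df.to_csv(index=False, float_format="%.17g")
    )


def write_fit_results_json(fits: Iterable[SpectrumFitResult], path) -> None:
    Path(path).write_text(json.dumps([f.to_dict() for f in fits], indent=2, default=_json_default))


def write_sort_result(result: SortResult, json_path, per_cell_csv_path) -> None:
    payload = {
        "outlets": list(result.outlets),
        "fractions": result.fractions,
        "counts": result.counts,
        "per_outlet_mean_cspec_mf_m2": result.per_outlet_mean_cspec,
        "enrichment": result.enrichment,
        "config": {
            "applied_frequency_hz": result.config.applied_frequency,
            "mode": result.config.mode,
            "tau": result.config.tau,
            "voltage_vpp": result.config.voltage_vpp,
            "flow_ul_min": result.config.flow_ul_min,
        },
    }
    Path(json_path).write_text(json.dumps(payload, indent=2, default=_json_default))
    df = result.per_cell[["cell_index", "re_cm", "outlet"]].rename(
        columns={"cell_index": "cell_id"}
    )
    Path(per_cell_csv_path).write_text(df.to_csv(index=False, float_format="%.17g"))


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
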