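"""Physiological calculations: Evans blue viability and spectrophotometric
pigment quantification.

Viability: Evans blue is excluded by living cells; dye solubilized from
a stained culture, read at 600 nm and normalized to a matched
heat-killed control (≈100% mortality), gives percent mortality.

Pigments: chlorophyll a/b and total carotenoids in an 80% acetone
extract from absorbances at 663, 646 and 470 nm, after subtracting the
720 nm reading from each analytical wavelength as a turbidity/colored-
compound baseline correction. The default coefficient set is the
standard 80%-acetone table (Lichtenthaler-type):

    chl_a = 12.21·A663′ − 2.81·A646′            (µg/mL extract)
    chl_b = 20.13·A646′ − 5.03·A663′
    carotenoids = (1000·A470′ − 3.27·chl_a − 104·chl_b) / 198

Alternative published coefficient tables can be swapped in via the
``coefficients`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ViabilityReading", "ViabilityResult", "mortality_percent",
    "PigmentReading", "PigmentResult", "PigmentCoefficients",
    "DEFAULT_COEFFICIENTS", "pigment_concentrations", "pigment_yield",
    "pigment_table",
]


@dataclass(frozen=True)
class ViabilityReading:
    a600_sample: float
    a600_heatkilled: float

    def __post_init__(self) -> None:
        if self.a600_sample < 0 or self.a600_heatkilled < 0:
            raise ValueError("absorbances must be non-negative")
        if self.a600_heatkilled == 0:
            raise ValueError("heat-killed control absorbance must be > 0")


@dataclass(frozen=True)
class ViabilityResult:
    mortality_raw: float   # can exceed 100 when staining beats the control
    mortality: float       # clipped to [0, 100]
    viability: float       # 100 − mortality (clipped scale)
    clipped: bool          # QC flag: raw value fell outside [0, 100]


def mortality_percent(r: ViabilityReading) -> ViabilityResult:
    """Percent mortality relative to the heat-killed (≈100% dead) control."""
    raw = 100.0 * r.a600_sample / r.a600_heatkilled
    clipped = not (0.0 <= raw <= 100.0)
    mort = min(max(raw, 0.0), 100.0)
    return ViabilityResult(
        mortality_raw=raw, mortality=mort, viability=100.0 - mort, clipped=clipped
    )


@dataclass(frozen=True)
class PigmentCoefficients:
    """Coefficients of the linear pigment equations (80% acetone default)."""

    chl_a_663: float = 12.21
    chl_a_646: float = -2.81
    chl_b_646: float = 20.13
    chl_b_663: float = -5.03
    car_470: float = 1000.0
    car_chl_a: float = -3.27
    car_chl_b: float = -104.0
    car_denom: float = 198.0


DEFAULT_COEFFICIENTS = PigmentCoefficients()


@dataclass(frozen=True)
class PigmentReading:
    """Absorbances of the 80% acetone extract plus culture metadata."""

    a470: float
    a646: float
    a663: float
    a720: float = 0.0
    culture_volume_ml: float | None = None
    cell_density: float | None = None  # cells/mL, optional

    def __post_init__(self) -> None:
        for name in ("a470", "a646", "a663", "a720"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class PigmentResult:
    chl_a: float       # µg/mL extract
    chl_b: float
    chl_total: float
    carotenoids: float
    qc_flags: tuple[str, ...] = ()


def pigment_concentrations(
    r: PigmentReading, coefficients: PigmentCoefficients = DEFAULT_COEFFICIENTS
) -> PigmentResult:
    """Pigment concentrations (µg/mL extract) with 720 nm baseline correction.

    Each analytical wavelength is corrected by subtracting A720 before
    the equations, so a uniform absorbance offset cancels exactly.
    Negative corrected absorbances are QC-flagged, not fatal: they occur
    with near-blank extracts.
    """
    c = coefficients
    a663 = r.a663 - r.a720
    a646 = r.a646 - r.a720
    a470 = r.a470 - r.a720
    flags = []
    if min(a663, a646, a470) < 0:
        flags.append("negative_corrected_absorbance")
    chl_a = c.chl_a_663 * a663 + c.chl_a_646 * a646
    chl_b = c.chl_b_646 * a646 + c.chl_b_663 * a663
    car = (c.car_470 * a470 + c.car_chl_a * chl_a + c.car_chl_b * chl_b) / c.car_denom
    if min(chl_a, chl_b, car) < 0:
        flags.append("negative_concentration")
    return PigmentResult(
        chl_a=chl_a, chl_b=chl_b, chl_total=chl_a + chl_b,
        carotenoids=car, qc_flags=tuple(flags),
    )


def pigment_yield(
    result: PigmentResult,
    extract_to_culture_factor: float,
    cell_density: float | None = None,
) -> dict[str, float]:
    """Yields per culture volume (µg/mL culture) and, optionally, per cell.

    ``extract_to_culture_factor`` is extract volume / culture volume
    (1.0 when 1 mL of culture is extracted into 1 mL of acetone).
    """
    if extract_to_culture_factor <= 0:
        raise ValueError("extract_to_culture_factor must be > 0")
    out = {
        "chl_a_yield": result.chl_a * extract_to_culture_factor,
        "chl_b_yield": result.chl_b * extract_to_culture_factor,
        "chl_total_yield": result.chl_total * extract_to_culture_factor,
        "carotenoid_yield": result.carotenoids * extract_to_culture_factor,
    }
    if cell_density is not None:
        if cell_density <= 0:
            raise ValueError("cell_density must be > 0")
        for k in list(out):
            out[k + "_per_cell"] = out[k] / cell_density
    return out


def pigment_table(
    readings: pd.DataFrame,
    coefficients: PigmentCoefficients = DEFAULT_COEFFICIENTS,
    extract_to_culture_factor: float = 1.0,
) -> pd.DataFrame:
    """Batch helper: per-row pigment concentrations and yields.

    ``readings`` needs columns a470, a646, a663 and optionally a720
    (default 0) and cell_density.
    """
    rows = []
    for _, row in readings.iterrows():
        density = row.get("cell_density")
        if density is not None and pd.isna(density):
            density = None
        r = PigmentReading(
            a470=row["a470"], a646=row["a646"], a663=row["a663"],
            a720=row.get("a720", 0.0),
            cell_density=density,
        )
        res = pigment_concentrations(r, coefficients)
        rec = {
            "chl_a": res.chl_a, "chl_b": res.chl_b,
            "chl_total": res.chl_total, "carotenoids": res.carotenoids,
            "qc_flags": ";".join(res.qc_flags),
        }
        rec.update(pigment_yield(res, extract_to_culture_factor, density))
        rows.append(rec)
    out = pd.DataFrame(rows, index=readings.index)
    return pd.concat([readings.reset_index(drop=True),
                      out.reset_index(drop=True)], axis=1)
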