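"""Synthetic LFQ and physiology fixtures with full ground truth.

The generator emulates the study design the pipeline targets: three
*Chlamydomonas* isolates × two conditions (control vs 10 µM
norflurazon, 48 h) × three biological replicates. Per protein, true
log2 abundances are Gaussian around a log-normal baseline (baseline
log2 ~ N(20, 2), mimicking LFQ dynamic range), a minority of proteins
carry planted treatment effects, and cells drop out
missing-not-at-random with logistic probability decreasing in true
abundance — the structure the down-shifted-Gaussian imputation model
assumes. Everything is reproducible from a single seed and the planted
truth is returned for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .physiology import (DEFAULT_COEFFICIENTS, PigmentCoefficients)
from .tables_io import IntensityMatrix, SampleDesign

__all__ = ["SyntheticTruth", "generate_lfq", "generate_go_map",
           "generate_physiology", "DEFAULT_ISOLATES"]

DEFAULT_ISOLATES = ("4A+", "CC-1009", "CC-2931")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for one generated LFQ data set.

    ``table`` has one row per protein: baseline log2 abundance,
    within-group SDs for control/treated, and one ``effect_<isolate>``
    column per isolate (0 for null proteins). ``dropout_midpoint`` /
    ``dropout_slope`` parameterize the logistic MNAR dropout on the
    log2 scale.
    """

    table: pd.DataFrame
    dropout_midpoint: float
    dropout_slope: float
    seed: int

    def de_accessions(self, isolate: str) -> frozenset:
        col = f"effect_{isolate}"
        return frozenset(self.table.index[self.table[col] != 0])

    def null_accessions(self, isolate: str) -> frozenset:
        col = f"effect_{isolate}"
        return frozenset(self.table.index[self.table[col] == 0])


def _make_design(isolates: Sequence[str], reps: int, dose: float) -> SampleDesign:
    rows = []
    for iso in isolates:
        for trt, d in (("control", 0.0), ("treated", dose)):
            for r in range(1, reps + 1):
                rows.append({
                    "sample_id": f"{iso}_{trt}_r{r}",
                    "isolate": iso, "treatment": trt,
                    "dose": d, "replicate": r,
                })
    return SampleDesign(pd.DataFrame(rows))


def generate_lfq(
    n_proteins: int = 2000,
    isolates: Sequence[str] = DEFAULT_ISOLATES,
    reps: int = 3,
    de_fraction: float = 0.05,
    effect_size: float = 2.0,
    group_sds: float | tuple[float, float] = 0.3,
    dropout_midpoint: float = 16.5,
    dropout_slope: float = 1.0,
    dose: float = 10.0,
    seed: int = 0,
    venn_design: Mapping[tuple[str, ...], int] | None = None,
) -> tuple[IntensityMatrix, SampleDesign, SyntheticTruth]:
    """Generate a raw LFQ intensity matrix with planted effects and MNAR
    dropout.

    ``de_fraction`` of proteins get a treatment effect of magnitude
    ``effect_size`` (random sign, shared sign across isolates) in every
    isolate, unless ``venn_design`` maps isolate subsets to protein
    counts (e.g. ``{("A",): 5, ("A", "B"): 3}``) to plant shared /
    exclusive structure. ``group_sds`` may be a single within-group SD
    or a (control, treated) pair to exercise the heteroscedastic branch.
    Dropout probability for a cell with true log2 abundance *a* is
    ``logistic(−slope·(a − midpoint))`` — non-increasing in abundance.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must be in [0, 1]")
    if dropout_slope < 0:
        raise ValueError("dropout_slope must be >= 0")
    rng = np.random.default_rng(seed)
    isolates = tuple(isolates)
    sd_control, sd_treated = (
        (group_sds, group_sds) if np.isscalar(group_sds) else tuple(group_sds)
    )

    accessions = [f"SYN{i:05d}" for i in range(n_proteins)]
    baseline = rng.normal(20.0, 2.0, n_proteins)

    effects = pd.DataFrame(
        0.0, index=accessions, columns=[f"effect_{iso}" for iso in isolates]
    )
    if venn_design is not None:
        total = sum(venn_design.values())
        if total > n_proteins:
            raise ValueError("venn_design plants more proteins than exist")
        order = rng.permutation(n_proteins)
        pos = 0
        for subset, count in venn_design.items():
            unknown = set(subset) - set(isolates)
            if unknown:
                raise ValueError(f"venn_design names unknown isolates {unknown}")
            for idx in order[pos:pos + count]:
                sign = rng.choice([-1.0, 1.0])
                for iso in subset:
                    effects.iloc[idx, effects.columns.get_loc(f"effect_{iso}")] = (
                        sign * effect_size
                    )
            pos += count
    elif de_fraction > 0:
        n_de = int(round(de_fraction * n_proteins))
        de_idx = rng.choice(n_proteins, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        for idx, sign in zip(de_idx, signs):
            effects.iloc[idx] = sign * effect_size

    design = _make_design(isolates, reps, dose)
    sample_ids = design.sample_ids
    meta = design.table.set_index("sample_id")

    true_log2 = np.empty((n_proteins, len(sample_ids)))
    for j, s in enumerate(sample_ids):
        iso = meta.loc[s, "isolate"]
        trt = meta.loc[s, "treatment"]
        mean = baseline + (effects[f"effect_{iso}"].to_numpy() if trt == "treated" else 0.0)
        sd = sd_treated if trt == "treated" else sd_control
        true_log2[:, j] = rng.normal(mean, sd)

    p_missing = expit(-dropout_slope * (true_log2 - dropout_midpoint))
    dropped = rng.random(true_log2.shape) < p_missing
    all_missing = dropped.all(axis=0)
    if all_missing.any():
        bad = [sample_ids[j] for j in np.flatnonzero(all_missing)]
        raise ValueError(
            f"dropout parameters left sample(s) {bad} with no valid values; "
            "lower dropout_midpoint or dropout_slope"
        )

    intensities = np.power(2.0, true_log2)
    intensities[dropped] = np.nan
    values = pd.DataFrame(intensities, index=accessions, columns=sample_ids)
    matrix = IntensityMatrix(values, design)

    truth_table = pd.DataFrame(
        {"baseline_log2": baseline,
         "sd_control": sd_control, "sd_treated": sd_treated},
        index=pd.Index(accessions, name="accession"),
    ).join(effects)
    truth = SyntheticTruth(
        table=truth_table, dropout_midpoint=dropout_midpoint,
        dropout_slope=dropout_slope, seed=seed,
    )
    return matrix, design, truth


def generate_go_map(
    accessions: Sequence[str],
    n_terms_per_aspect: int = 5,
    annotation_prob: float = 0.8,
    seed: int = 0,
):
    """Small synthetic GO map over the given accessions (testing aid).

    Each accession is annotated, with probability ``annotation_prob``
    per aspect, to one random term of that aspect. Term IDs are
    synthetic (``GO:SYNB001`` etc.), not real ontology identifiers.
    """
    from .tables_io import GOAnnotationMap, GO_ASPECTS

    rng = np.random.default_rng(seed)
    rows = []
    for acc in accessions:
        for aspect in GO_ASPECTS:
            if rng.random() < annotation_prob:
                k = int(rng.integers(1, n_terms_per_aspect + 1))
                rows.append({
                    "accession": acc,
                    "go_id": f"GO:SYN{aspect}{k:03d}",
                    "aspect": aspect,
                    "term_name": f"synthetic {aspect} term {k}",
                })
    return GOAnnotationMap(pd.DataFrame(
        rows, columns=["accession", "go_id", "aspect", "term_name"]
    ))


def generate_physiology(
    design: SampleDesign,
    seed: int = 0,
    noise_sd: float = 0.005,
    coefficients: PigmentCoefficients = DEFAULT_COEFFICIENTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic pigment-absorbance readings with known true concentrations.

    True chlorophyll a/b and carotenoid concentrations are drawn per
    sample (treated samples bleached relative to controls, emulating
    herbicide-driven pigment loss), inverted through the forward pigment
    equations to corrected absorbances, a small 720 nm baseline is
    added to every wavelength, and Gaussian read noise of SD
    ``noise_sd`` (absorbance units) is applied. Returns
    ``(readings, truth)`` DataFrames indexed by sample_id; at
    ``noise_sd=0`` the pigment equations recover the truth exactly.
    """
    rng = np.random.default_rng(seed)
    c = coefficients
    # invert the 2×2 chlorophyll system: [chl_a, chl_b] = M @ [A663', A646']
    M = np.array([[c.chl_a_663, c.chl_a_646], [c.chl_b_663, c.chl_b_646]])
    Minv = np.linalg.inv(M)

    rows, truth_rows = [], []
    for _, r in design.table.iterrows():
        bleach = 0.4 if r["treatment"] == "treated" else 1.0
        chl_a = bleach * rng.uniform(8.0, 14.0)
        chl_b = bleach * rng.uniform(3.0, 6.0)
        car = bleach * rng.uniform(2.0, 5.0)
        a663, a646 = Minv @ np.array([chl_a, chl_b])
        a470 = (c.car_denom * car - c.car_chl_a * chl_a - c.car_chl_b * chl_b) / c.car_470
        # baseline kept well above the read-noise scale so noisy readings
        # stay non-negative (absorbance invariant)
        a720 = rng.uniform(0.05, 0.1)
        noise = rng.normal(0.0, noise_sd, 4) if noise_sd > 0 else np.zeros(4)
        rows.append({
            "sample_id": r["sample_id"],
            "a470": a470 + a720 + noise[0],
            "a646": a646 + a720 + noise[1],
            "a663": a663 + a720 + noise[2],
            "a720": a720 + noise[3],
        })
        truth_rows.append({
            "sample_id": r["sample_id"],
            "chl_a": chl_a, "chl_b": chl_b, "carotenoids": car,
        })
    readings = pd.DataFrame(rows).set_index("sample_id")
    truth = pd.DataFrame(truth_rows).set_index("sample_id")
    return readings, truth
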