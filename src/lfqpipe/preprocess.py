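"""Normalization and imputation chain for LFQ intensity matrices.

The chain mirrors standard label-free practice: intensities are log
converted (base 2 by default, so downstream fold changes are log2
ratios), each sample is centred on its own mean abundance, each sample
is scaled to unit distribution width to equalize acquisition dynamic
range, proteins with too few valid measurements are filtered, and
remaining missing values are imputed by drawing from a down-shifted
Gaussian in the low tail of the observed per-sample distribution
(probabilistic minimum imputation, the standard missing-not-at-random
model for LFQ dropout).

Every transform appends to a provenance list; replaying the provenance
on the raw matrix reproduces the normalized matrix exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .tables_io import IntensityMatrix, SampleDesign, TableValidationError

__all__ = [
    "NormalizedMatrix",
    "log_transform",
    "center_by_sample_mean",
    "scale_by_sample_width",
    "filter_by_validity",
    "impute_min_probabilistic",
    "replay",
    "scale_widths",
]

DEFAULT_DOWN_SHIFT = 2.0
DEFAULT_IMPUTE_WIDTH = 0.3


@dataclass(frozen=True)
class NormalizedMatrix:
    """Log-space protein × sample matrix with imputation flags.

    ``values`` keeps NaN for missing cells until imputation fills them;
    ``imputed`` marks the cells that were filled. ``provenance`` is the
    append-only list of applied transforms with their parameters.
    """

    values: pd.DataFrame
    design: SampleDesign
    imputed: pd.DataFrame  # boolean, same shape as values
    provenance: tuple[dict, ...] = ()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    @property
    def n_imputed(self) -> int:
        return int(self.imputed.to_numpy().sum())

    def valid_mask(self) -> pd.DataFrame:
        """Cells carrying an originally measured (non-imputed) value."""
        return self.values.notna() & ~self.imputed

    def _with(self, values: pd.DataFrame, step: dict, imputed=None) -> "NormalizedMatrix":
        return NormalizedMatrix(
            values=values,
            design=self.design,
            imputed=self.imputed if imputed is None else imputed,
            provenance=self.provenance + (step,),
        )


def log_transform(matrix: IntensityMatrix, base: float = 2.0) -> NormalizedMatrix:
    """Convert raw intensities to log space; missing cells stay missing."""
    if base <= 0 or base == 1:
        raise ValueError("log base must be positive and != 1")
    arr = matrix.values.to_numpy(dtype=float)
    if np.any(arr[~np.isnan(arr)] <= 0):
        raise ValueError("non-positive present intensity; cannot log-transform")
    values = np.log(matrix.values) / np.log(base)
    flags = pd.DataFrame(
        False, index=matrix.values.index, columns=matrix.values.columns
    )
    return NormalizedMatrix(
        values=values,
        design=matrix.design,
        imputed=flags,
        provenance=({"op": "log_transform", "base": base},),
    )


def _center_stat(col: pd.Series, stat: str) -> float:
    if stat == "mean":
        return float(col.mean())
    if stat == "median":
        return float(col.median())
    raise ValueError(f"unknown centering statistic {stat!r}")


def center_by_sample_mean(
    m: NormalizedMatrix, stat: Literal["mean", "median"] = "mean"
) -> NormalizedMatrix:
    """Subtract each sample's valid-value mean (or median) from its valid cells."""
    valid_counts = m.values.notna().sum(axis=0)
    low = valid_counts[valid_counts < 2]
    if len(low):
        raise TableValidationError(
            f"sample {low.index[0]!r} has {low.iloc[0]} valid value(s); need >= 2"
        )
    centers = m.values.apply(lambda col: _center_stat(col.dropna(), stat), axis=0)
    values = m.values.sub(centers, axis=1)
    return m._with(values, {"op": "center_by_sample_mean", "stat": stat})


def _width_stat(col: pd.Series, stat: str) -> float:
    if stat == "sd":
        return float(col.std(ddof=1))
    if stat == "iqr":
        return float(col.quantile(0.75) - col.quantile(0.25))
    raise ValueError(f"unknown width statistic {stat!r}")


def scale_by_sample_width(
    m: NormalizedMatrix, stat: Literal["sd", "iqr"] = "sd"
) -> NormalizedMatrix:
    """Divide each sample's valid cells by its distribution width (SD by default)."""
    widths = m.values.apply(lambda col: _width_stat(col.dropna(), stat), axis=0)
    zero = widths[(widths == 0) | widths.isna()]
    if len(zero):
        raise TableValidationError(
            f"sample {zero.index[0]!r} has zero distribution width; cannot scale"
        )
    values = m.values.div(widths, axis=1)
    # widths are recorded so fold-change thresholds stated on the raw log2
    # scale can be translated onto the width-scaled axis downstream
    return m._with(values, {"op": "scale_by_sample_width", "stat": stat,
                            "widths": {s: float(w) for s, w in widths.items()}})


def filter_by_validity(
    m: NormalizedMatrix,
    min_valid_per_group: int = 2,
    groups: Sequence[tuple[str, str]] | None = None,
) -> tuple[NormalizedMatrix, list[str]]:
    """Retain proteins with >= ``min_valid_per_group`` valid values in at
    least one design group.

    ``groups`` restricts the check to specific (isolate, treatment)
    groups; by default every design group counts. Returns the filtered
    matrix and the list of removed accessions.
    """
    design_groups = m.design.groups()
    if groups is None:
        use = list(design_groups)
    else:
        unknown = [g for g in groups if tuple(g) not in design_groups]
        if unknown:
            raise KeyError(f"unknown group(s): {unknown}")
        use = [tuple(g) for g in groups]
    keep = pd.Series(False, index=m.values.index)
    for g in use:
        cols = design_groups[g]
        keep |= m.values[cols].notna().sum(axis=1) >= min_valid_per_group
    removed = list(m.values.index[~keep])
    step = {
        "op": "filter_by_validity",
        "min_valid_per_group": min_valid_per_group,
        "groups": [list(g) for g in use],
    }
    out = NormalizedMatrix(
        values=m.values.loc[keep],
        design=m.design,
        imputed=m.imputed.loc[keep],
        provenance=m.provenance + (step,),
    )
    return out, removed


def impute_min_probabilistic(
    m: NormalizedMatrix,
    down_shift: float = DEFAULT_DOWN_SHIFT,
    width: float = DEFAULT_IMPUTE_WIDTH,
    seed: int | None = None,
) -> NormalizedMatrix:
    """Fill missing cells with draws from a down-shifted Gaussian.

    For sample *s* with valid-value mean μ_s and SD σ_s, each missing
    cell is drawn independently from N(μ_s − down_shift·σ_s,
    (width·σ_s)²) — low abundance is modelled as sitting ``down_shift``
    standard deviations below the observed distribution, resampled with
    variability ``width``. A seed is mandatory whenever missing cells
    exist: imputation must be reproducible.
    """
    if m.n_missing == 0:
        return m._with(
            m.values.copy(),
            {"op": "impute_min_probabilistic", "down_shift": down_shift,
             "width": width, "seed": seed, "n_imputed": 0},
        )
    if seed is None:
        raise ValueError("a seed is required when missing cells are imputed")
    rng = np.random.default_rng(seed)
    values = m.values.copy()
    imputed = m.imputed.copy()
    for s in values.columns:  # column order is design order → deterministic
        col = values[s]
        miss = col.isna()
        if not miss.any():
            continue
        valid = col.dropna()
        mu, sigma = float(valid.mean()), float(valid.std(ddof=1))
        draws = rng.normal(mu - down_shift * sigma, width * sigma, int(miss.sum()))
        values.loc[miss, s] = draws
        imputed.loc[miss, s] = True
    step = {
        "op": "impute_min_probabilistic",
        "down_shift": down_shift,
        "width": width,
        "seed": seed,
        "n_imputed": int(imputed.to_numpy().sum()),
    }
    return NormalizedMatrix(values=values, design=m.design, imputed=imputed,
                            provenance=m.provenance + (step,))


def scale_widths(m: NormalizedMatrix) -> pd.Series | None:
    """Per-sample distribution widths recorded by the scaling step.

    A fold-change threshold stated on the raw log2 scale (e.g. the
    two-fold cut |log2FC| = 1) corresponds to ``threshold /
    median(widths)`` on the width-scaled axis. Returns None when the
    matrix was never width-scaled.
    """
    for step in reversed(m.provenance):
        if step["op"] == "scale_by_sample_width":
            return pd.Series(step["widths"])
    return None


_REPLAY = {
    "log_transform": lambda m, p: log_transform(m, base=p["base"]),
    "center_by_sample_mean": lambda m, p: center_by_sample_mean(m, stat=p["stat"]),
    "scale_by_sample_width": lambda m, p: scale_by_sample_width(m, stat=p["stat"]),
    "filter_by_validity": lambda m, p: filter_by_validity(
        m, p["min_valid_per_group"], [tuple(g) for g in p["groups"]]
    )[0],
    "impute_min_probabilistic": lambda m, p: impute_min_probabilistic(
        m, p["down_shift"], p["width"], p["seed"]
    ),
}


def replay(raw: IntensityMatrix, provenance: Sequence[dict]) -> NormalizedMatrix:
    """Re-apply a recorded provenance to a raw matrix.

    The provenance fully determines the output: replaying it reproduces
    the normalized matrix exactly (same seeds, same draws).
    """
    state: NormalizedMatrix | IntensityMatrix = raw
    for step in provenance:
        op = step["op"]
        if op not in _REPLAY:
            raise KeyError(f"unknown provenance op {op!r}")
        state = _REPLAY[op](state, step)
    if isinstance(state, IntensityMatrix):
        raise ValueError("provenance contained no transform steps")
    return state
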