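"""Per-protein differential expression between treated and control groups.

Each protein is tested with a two-sample t-test whose flavour is gated
by an F-test for variance homogeneity: proteins whose replicate
variances are compatible (F-test p >= alpha_f) get the pooled-variance
homoscedastic test, the rest get Welch's unequal-variance test. Fold
changes are differences of group means in log2 space (= log2 of the
intensity ratio), and proteins are classified on the volcano plane by
joint fold-change and p-value thresholds.

The p-value axis is reported as -log2(p): with the conventional p <
0.05 cut this corresponds to a transformed threshold of 4.32.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import NormalizedMatrix

__all__ = [
    "DEResult",
    "variance_gate",
    "gated_t_test",
    "fold_change",
    "classify_volcano",
    "p_axis_transform",
    "run_de_table",
    "DE_TABLE_COLUMNS",
    "write_de_table",
]

HOMOSCEDASTIC = "homoscedastic"
HETEROSCEDASTIC = "heteroscedastic"

DE_TABLE_COLUMNS = [
    "accession", "mean_control", "mean_treated", "log2_fc", "f_pvalue",
    "variance_mode", "t_stat", "df", "p_value", "neg_log2_p", "volcano_class",
]


@dataclass(frozen=True)
class DEResult:
    """One protein's differential-expression record for a contrast."""

    accession: str
    group_a: str  # treated
    group_b: str  # control
    mean_a: float
    mean_b: float
    log2_fc: float
    f_stat: float
    f_pvalue: float
    variance_mode: str
    t_stat: float
    df: float
    p_value: float
    neg_log2_p: float
    volcano_class: str


def variance_gate(
    a: Sequence[float], b: Sequence[float], alpha_f: float = 0.05
) -> tuple[str, float, float]:
    """F-test for variance homogeneity between two replicate groups.

    F is the larger sample variance over the smaller, with matching
    degrees of freedom; the p-value is two-sided. Returns
    ``(variance_mode, f_stat, f_pvalue)`` with mode heteroscedastic iff
    p < alpha_f. A single zero-variance group is routed to the
    heteroscedastic branch (Welch handles unequal variances; a pooled
    df would be misleading); two zero-variance groups are degenerate
    and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both groups have zero variance; protein is degenerate")
    if va == 0 or vb == 0:
        return HETEROSCEDASTIC, math.inf, 0.0
    if va >= vb:
        f, dfn, dfd = va / vb, len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    p = min(1.0, 2.0 * float(stats.f.sf(f, dfn, dfd)))
    mode = HETEROSCEDASTIC if p < alpha_f else HOMOSCEDASTIC
    return mode, float(f), p


def gated_t_test(
    a: Sequence[float], b: Sequence[float], variance_mode: str
) -> tuple[float, float, float]:
    """Two-sample t-test using the branch chosen by the variance gate.

    Homoscedastic → pooled-variance test with df = n_a + n_b − 2;
    heteroscedastic → Welch's test with Welch–Satterthwaite df.
    Returns ``(t_stat, df, p_value)`` with a two-sided p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate but well-defined when the means coincide
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    equal_var = variance_mode == HOMOSCEDASTIC
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def fold_change(a: Sequence[float], b: Sequence[float]) -> float:
    """log2 fold change: difference of group means in log2 space."""
    return float(np.mean(a) - np.mean(b))


def classify_volcano(
    log2_fc: float,
    p_value: float,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    strict: bool = True,
) -> str:
    """Classify a protein as ``up``, ``down`` or ``not_significant``.

    ``strict`` keeps the boundary |log2FC| = fc_threshold out of the
    significant classes (fold change must exceed the threshold); with
    ``strict=False`` the boundary is included.
    """
    if not (math.isfinite(log2_fc) and math.isfinite(p_value)):
        raise ValueError("log2_fc and p_value must be finite")
    if p_value >= p_threshold:
        return "not_significant"
    if strict:
        if log2_fc > fc_threshold:
            return "up"
        if log2_fc < -fc_threshold:
            return "down"
    else:
        if log2_fc >= fc_threshold:
            return "up"
        if log2_fc <= -fc_threshold:
            return "down"
    return "not_significant"


def p_axis_transform(p_value: float, base: float = 2.0) -> float:
    """Volcano y-axis transform: −log_base(p). Base 2 maps p = 0.05 to 4.32."""
    if not 0 < p_value <= 1:
        raise ValueError(f"p-value must be in (0, 1], got {p_value}")
    return float(-math.log(p_value, base))


def run_de_table(
    m: NormalizedMatrix,
    isolate: str,
    alpha_f: float = 0.05,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    strict: bool = True,
    adjust: bool = False,
    min_valid_per_group: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Differential-expression table for one isolate's treated-vs-control
    contrast.

    The matrix must be filtered and imputed (no missing cells). Fold
    changes are oriented treated minus control, so ``up`` means higher
    abundance under treatment. Proteins with zero variance in both
    groups and unequal means cannot be tested and are excluded with a
    logged reason. ``adjust`` adds a Benjamini–Hochberg ``q_value``
    column as an annotation; it never alters ``volcano_class``.

    ``min_valid_per_group`` applies the validity rule *per contrast*:
    proteins with fewer than that many originally measured (non-imputed)
    values in both of this contrast's groups are excluded — their test
    would compare mostly imputed cells. With triplicates the common
    setting is 3 (one fully observed group required). None disables the
    per-contrast check (the global filter still applies upstream).

    Returns the table and a summary dict with ``n_up``, ``n_down``,
    ``n_tested``, ``excluded`` and the thresholds in force.
    """
    if m.n_missing:
        raise ValueError("matrix has missing cells; impute before testing")
    treated_cols = m.design.samples_for(isolate, "treated")
    control_cols = m.design.samples_for(isolate, "control")
    if len(treated_cols) < 2 or len(control_cols) < 2:
        raise ValueError("each contrast group needs >= 2 replicates")

    ta = m.values[treated_cols].to_numpy(dtype=float)
    ca = m.values[control_cols].to_numpy(dtype=float)
    if min_valid_per_group is not None:
        valid = m.valid_mask()
        enough = (
            (valid[treated_cols].sum(axis=1) >= min_valid_per_group)
            | (valid[control_cols].sum(axis=1) >= min_valid_per_group)
        ).to_numpy()
    else:
        enough = np.ones(len(m.values), dtype=bool)
    rows, excluded = [], []
    for i, acc in enumerate(m.values.index):
        a, b = ta[i], ca[i]
        if not enough[i]:
            excluded.append((acc, "insufficient valid values in contrast groups"))
            continue
        try:
            mode, f_stat, f_p = variance_gate(a, b, alpha_f)
        except ValueError as e:
            excluded.append((acc, str(e)))
            continue
        t_stat, df, p = gated_t_test(a, b, mode)
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        fc = fold_change(a, b)
        rows.append(DEResult(
            accession=acc, group_a="treated", group_b="control",
            mean_a=float(a.mean()), mean_b=float(b.mean()), log2_fc=fc,
            f_stat=f_stat, f_pvalue=f_p, variance_mode=mode,
            t_stat=t_stat, df=df, p_value=p,
            neg_log2_p=p_axis_transform(p),
            volcano_class=classify_volcano(fc, p, fc_threshold, p_threshold, strict),
        ))
    table = pd.DataFrame(
        [{
            "accession": r.accession, "mean_control": r.mean_b,
            "mean_treated": r.mean_a, "log2_fc": r.log2_fc,
            "f_stat": r.f_stat, "f_pvalue": r.f_pvalue,
            "variance_mode": r.variance_mode, "t_stat": r.t_stat, "df": r.df,
            "p_value": r.p_value, "neg_log2_p": r.neg_log2_p,
            "volcano_class": r.volcano_class,
        } for r in rows],
        columns=["accession", "mean_control", "mean_treated", "log2_fc",
                 "f_stat", "f_pvalue", "variance_mode", "t_stat", "df",
                 "p_value", "neg_log2_p", "volcano_class"],
    )
    if adjust and len(table):
        from statsmodels.stats.multitest import multipletests

        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    thresholds = {
        "alpha_f": alpha_f, "fc_threshold": fc_threshold,
        "p_threshold": p_threshold, "strict": strict,
        "min_valid_per_group": min_valid_per_group,
    }
    table.attrs["thresholds"] = thresholds
    table.attrs["isolate"] = isolate
    summary = {
        "isolate": isolate,
        "n_tested": len(table),
        "n_up": int((table["volcano_class"] == "up").sum()) if len(table) else 0,
        "n_down": int((table["volcano_class"] == "down").sum()) if len(table) else 0,
        "excluded": excluded,
        "thresholds": thresholds,
    }
    return table, summary


def write_de_table(table: pd.DataFrame, path) -> None:
    """Write the DE table TSV with the documented column set."""
    table[DE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)
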