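"""Cohort statistics: BSA, ANOVA, Holm-Bonferroni, chi-square, coverage.

Group displacement tables follow the reporting layout of the motion
study: per (plane, border, segment, component) a mean +/- SD per group,
a one-way ANOVA p-value, Holm-adjusted pairwise p-values for the six
group pairs, and letter marks (a: vs control, b: vs HFpEF, c: vs HFmrEF)
for the heart-failure groups at alpha = 0.05.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GROUPS

COMPONENTS = ("overall", "tangential", "normal")

#: Pairwise comparisons among the four groups, in a fixed order.
GROUP_PAIRS = tuple(itertools.combinations(GROUPS, 2))


def bsa_mosteller(height: float, weight: float) -> float:
    """Mosteller body surface area: sqrt(height_cm * weight_kg / 3600)."""
    if height <= 0 or weight <= 0:
        raise ValueError("height and weight must be > 0")
    return math.sqrt(height * weight / 3600.0)


def normalize_by_bsa(displacement: float, bsa: float) -> float:
    """Displacement (mm) per unit body surface area (mm/m^2)."""
    if bsa <= 0:
        raise ValueError("BSA must be > 0")
    return displacement / bsa


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA (F statistic, upper-tail p).

    Computed from the explicit between/within sum-of-squares
    decomposition; the p-value is the upper tail of the F distribution.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("every group needs at least 2 values")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrays)
    df_between = len(arrays) - 1
    df_within = all_vals.size - len(arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return float(f), p


def holm_adjust(pvalues) -> np.ndarray:
    """Step-down Holm-Bonferroni adjustment, order preserved, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)  # step-down monotonicity
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def chi_square_counts(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("table has a zero marginal row or column")
    stat, p, _, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat), float(p)


def normal_fraction_below(mean: float, sd: float, threshold: float) -> float:
    """P(X < threshold) for X ~ Normal(mean, sd)."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    return float(sps.norm.cdf((threshold - mean) / sd))


def one_sigma_interval(mean: float, sd: float) -> tuple[float, float]:
    """(mean - sd, mean + sd): the central ~68% normal coverage interval."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return (mean - sd, mean + sd)


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    return float(sps.ttest_ind(a, b, equal_var=True).pvalue)


def build_group_tables(per_patient: pd.DataFrame, subjects: pd.DataFrame,
                       alpha: float = 0.05,
                       pairwise: str = "welch") -> pd.DataFrame:
    """Aggregate per-patient segment displacements into group tables.

    ``per_patient`` needs columns subject_id, plane, border, segment and
    the three displacement components; ``subjects`` maps subject_id to
    group.  Returns one row per (plane, border, segment, component) with
    per-group mean/SD/n, ANOVA p, Holm-adjusted pairwise p-values and
    significance marks.  Cells where some group has < 2 patients are
    flagged (``insufficient`` = True) rather than fatal.
    """
    if pairwise not in ("welch", "pooled"):
        raise ValueError("pairwise must be 'welch' or 'pooled'")
    ttest = _welch_t if pairwise == "welch" else _pooled_t
    merged = per_patient.drop(columns=["group"], errors="ignore").merge(
        subjects[["subject_id", "group"]], on="subject_id", how="left")
    if merged["group"].isna().any():
        missing = merged.loc[merged["group"].isna(), "subject_id"].unique()
        raise ValueError(f"subjects without group label: {list(missing)}")

    rows = []
    for (plane, border, segment), cell in merged.groupby(
            ["plane", "border", "segment"]):
        for comp in COMPONENTS:
            by_group = {g: cell.loc[cell["group"] == g, comp]
                          .dropna().to_numpy(dtype=float)
                        for g in GROUPS}
            row: dict = {"plane": plane, "border": border,
                         "segment": segment, "component": comp}
            for g in GROUPS:
                v = by_group[g]
                row[f"{g}_mean"] = v.mean() if v.size else np.nan
                row[f"{g}_sd"] = v.std(ddof=1) if v.size > 1 else np.nan
                row[f"{g}_n"] = v.size
            insufficient = any(by_group[g].size < 2 for g in GROUPS)
            row["insufficient"] = insufficient
            if insufficient:
                row["anova_p"] = np.nan
                rows.append(row)
                continue
            _, row["anova_p"] = anova_oneway([by_group[g] for g in GROUPS])
            raw = [ttest(by_group[a], by_group[b]) for a, b in GROUP_PAIRS]
            adj = holm_adjust(raw)
            sig = {}
            for (a, b), padj in zip(GROUP_PAIRS, adj):
                row[f"p_{a}_vs_{b}"] = padj
                sig[(a, b)] = padj < alpha
            # letter marks on the HF groups, as in the study tables
            mark_vs = {"a": "control", "b": "HFpEF", "c": "HFmrEF"}
            for g in ("HFpEF", "HFmrEF", "HFrEF"):
                marks = ""
                for letter, ref in mark_vs.items():
                    if ref == g:
                        continue
                    pair = (ref, g) if GROUPS.index(ref) < GROUPS.index(g) \
                        else (g, ref)
                    if sig.get(pair, False):
                        marks += letter
                row[f"{g}_marks"] = marks
            rows.append(row)
    return pd.DataFrame(rows)


def format_group_table(table: pd.DataFrame, plane: str, border: str,
                       component: str) -> pd.DataFrame:
    """Render one study-style table: 'mean ± SD' strings plus p-value."""
    sel = table[(table["plane"] == plane) & (table["border"] == border)
                & (table["component"] == component)].sort_values("segment")
    out = pd.DataFrame({"segment": sel["segment"].to_numpy()})
    for g in GROUPS:
        marks = sel.get(f"{g}_marks")
        cells = []
        for i, (_, r) in enumerate(sel.iterrows()):
            m, s = r[f"{g}_mean"], r[f"{g}_sd"]
            txt = "" if np.isnan(m) else f"{m:.1f} ± {s:.1f}"
            if marks is not None and isinstance(r.get(f"{g}_marks"), str):
                txt += r[f"{g}_marks"]
            cells.append(txt)
        out[g] = cells
    out["p"] = [("<0.001" if p < 0.001 else f"{p:.3f}") if np.isfinite(p)
                else "n/a" for p in sel["anova_p"]]
    return out
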