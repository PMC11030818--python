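"""Differential metabolite calling, lipid classes and rescue analysis.

Fold changes are computed on raw peak-area group means (peak area is
the quantitative unit of MRM metabolomics).  Two calling criteria are
supported and the choice is always explicit:

* ``vip`` mode — differential when VIP >= vip_min and
  |log2FC| >= abs_log2fc_min (both non-strict);
* ``ratio`` mode — differential when the raw ratio is >= fc_up or
  <= fc_down (non-strict).

Lipid classes are resolved from a curated annotation when present,
otherwise by longest-prefix match of the display name against the
class vocabulary (so "LPC 18:0" is LPC, not PC).  Class summaries
report counts and percentages of the differential subset, with
half-up rounding at the reported precision.

The three-group rescue analysis flags metabolites that are
differential in stress vs control and reversed in the rescue group:
a down metabolite is recovered when rescue/stress >= rescue_up, an up
metabolite when rescue/stress <= rescue_down.
"""

from __future__ import annotations

import logging
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .config import ThresholdConfig
from .io import MetaboliteTable, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "LIPID_CLASSES",
    "PHOSPHOLIPID_CLASSES",
    "LYSOPHOSPHOLIPID_CLASSES",
    "percentage",
    "metabolite_fold_change",
    "classify_lipid",
    "call_differential_metabolites",
    "class_summary",
    "recovery_analysis",
    "enrichment_test",
]

#: class vocabulary; lyso-forms listed first so longest-prefix matching
#: resolves LPC/LPE/LPA before PC/PE/PA.
LIPID_CLASSES = ("LPC", "LPE", "LPA", "PC", "PE", "PI", "PA", "TG", "SM")
PHOSPHOLIPID_CLASSES = frozenset({"PE", "PC", "PI"})
LYSOPHOSPHOLIPID_CLASSES = frozenset({"LPE", "LPC", "LPA"})


def percentage(numerator: float, denominator: float, decimals: int = 2) -> float:
    """``100 * numerator / denominator`` rounded half-up to ``decimals``.

    Half-up (not banker's) rounding matches how percentages are
    conventionally reported; 0/0 is returned as 0.
    """
    if denominator == 0:
        return 0.0
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def _impute_half_min(areas: pd.DataFrame) -> pd.DataFrame:
    """Replace missing areas by half the row's minimum observed area."""
    row_min = areas.min(axis=1, skipna=True)
    out = areas.copy()
    for mid in out.index[out.isna().any(axis=1)]:
        if pd.notna(row_min[mid]):
            out.loc[mid] = out.loc[mid].fillna(row_min[mid] / 2.0)
    return out


def metabolite_fold_change(
    table: MetaboliteTable,
    contrast: tuple[str, str],
    sheet: SampleSheet,
) -> pd.DataFrame:
    """Per-metabolite raw-area ratio and log2 fold change.

    ``ratio = mean(area in numerator group) / mean(area in denominator
    group)`` after half-minimum imputation of missing cells.  Rows with
    an undefined ratio (zero or fully missing denominator) get NaN and
    are logged.
    """
    group_a, group_b = contrast
    cols_a = sheet.samples(group_a)
    cols_b = sheet.samples(group_b)
    areas = _impute_half_min(table.values[cols_a + cols_b])
    mean_a = areas[cols_a].mean(axis=1, skipna=True)
    mean_b = areas[cols_b].mean(axis=1, skipna=True)
    ratio = mean_a / mean_b
    bad = mean_b.isna() | (mean_b == 0) | mean_a.isna()
    if bad.any():
        logger.warning("metabolite_fold_change: %d metabolites with undefined ratio", int(bad.sum()))
        ratio[bad] = np.nan
    with np.errstate(divide="ignore"):
        log2fc = np.log2(ratio)
    return pd.DataFrame({"ratio": ratio, "log2fc": log2fc}, index=table.values.index)


def classify_lipid(name: str, annotation: str | None = None) -> str:
    """Resolve a lipid class from annotation or display-name prefix."""
    if annotation is not None and not pd.isna(annotation) and str(annotation) != "":
        return str(annotation)
    cleaned = str(name).strip().upper()
    best = ""
    for cls in LIPID_CLASSES:
        if cleaned.startswith(cls) and len(cls) > len(best):
            best = cls
    return best or "other"


def _classes_for(table: MetaboliteTable) -> pd.Series:
    ann = table.classes if table.classes is not None else pd.Series(index=table.values.index, dtype=object)
    return pd.Series(
        [classify_lipid(table.names[mid], ann.get(mid)) for mid in table.values.index],
        index=table.values.index,
        name="lipid_class",
    )


def call_differential_metabolites(
    table: MetaboliteTable,
    contrast: tuple[str, str],
    sheet: SampleSheet,
    thresholds: ThresholdConfig,
    vip: pd.Series | np.ndarray | None = None,
    criterion: str = "vip",
) -> pd.DataFrame:
    """Call metabolites up / down / ns under an explicit criterion.

    ``criterion='vip'`` needs per-metabolite VIP scores aligned to the
    table and applies VIP >= vip_min & |log2FC| >= abs_log2fc_min;
    ``criterion='ratio'`` applies ratio >= fc_up / <= fc_down.  All
    comparisons are non-strict.  Returns a DataFrame with ``ratio``,
    ``log2fc``, ``vip`` (NaN in ratio mode), ``direction`` and
    ``lipid_class``.
    """
    if criterion not in ("vip", "ratio"):
        raise ValueError(f"criterion must be 'vip' or 'ratio', got {criterion!r}")
    fc = metabolite_fold_change(table, contrast, sheet)
    direction = pd.Series("ns", index=fc.index, name="direction")
    if criterion == "vip":
        if vip is None:
            raise ValueError("criterion='vip' requires vip scores")
        vip_series = pd.Series(np.asarray(vip, dtype=float), index=fc.index, name="vip") \
            if not isinstance(vip, pd.Series) else vip.rename("vip").reindex(fc.index)
        passed = vip_series >= thresholds.vip_min
        direction[passed & (fc["log2fc"] >= thresholds.abs_log2fc_min)] = "up"
        direction[passed & (fc["log2fc"] <= -thresholds.abs_log2fc_min)] = "down"
    else:
        vip_series = pd.Series(np.nan, index=fc.index, name="vip")
        direction[fc["ratio"] >= thresholds.fc_up] = "up"
        direction[fc["ratio"] <= thresholds.fc_down] = "down"
    direction[fc["ratio"].isna()] = "ns"
    calls = pd.concat([fc, vip_series, direction, _classes_for(table)], axis=1)
    logger.info(
        "call_differential_metabolites %s vs %s (%s): %s",
        contrast[0], contrast[1], criterion, direction.value_counts().to_dict(),
    )
    return calls


def class_summary(calls: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Class-level composition of the differential subset.

    For each lipid class among the up/down calls: total differential
    count, up/down split, share of all differential metabolites, and
    up/down shares within the class.  Percentages use half-up rounding
    at ``decimals``.  An empty differential set yields an empty frame.
    """
    diff = calls[calls["direction"].isin(["up", "down"])]
    n_all = len(diff)
    rows = []
    if n_all:
        for cls, sub in diff.groupby("lipid_class", sort=True):
            n_up = int((sub["direction"] == "up").sum())
            n_down = int((sub["direction"] == "down").sum())
            n_total = len(sub)
            rows.append({
                "lipid_class": cls,
                "n_total": n_total,
                "n_up": n_up,
                "n_down": n_down,
                "pct_of_all_differential": percentage(n_total, n_all, decimals),
                "pct_up_within_class": percentage(n_up, n_total, decimals),
                "pct_down_within_class": percentage(n_down, n_total, decimals),
            })
    return pd.DataFrame(
        rows,
        columns=[
            "lipid_class", "n_total", "n_up", "n_down",
            "pct_of_all_differential", "pct_up_within_class", "pct_down_within_class",
        ],
    )


def recovery_analysis(
    table: MetaboliteTable,
    sheet: SampleSheet,
    groups: tuple[str, str, str],
    thresholds: ThresholdConfig,
) -> pd.DataFrame:
    """Three-group reversal calling (control, stress, rescue).

    Step 1 calls stress-vs-control differential metabolites with the
    ratio criterion; step 2 tests the rescue-vs-stress ratio for a
    reversal in the opposite direction (>= rescue_up for down
    metabolites, <= rescue_down for up ones).  ``recovered`` is True
    only when both hold.  Returns a DataFrame with
    ``dir_stress_vs_control``, ``ratio_stress_vs_control``,
    ``ratio_rescue_vs_stress``, ``recovered`` and ``lipid_class``.
    """
    control, stress, rescue = groups
    step1 = call_differential_metabolites(
        table, (stress, control), sheet, thresholds, criterion="ratio"
    )
    step2 = metabolite_fold_change(table, (rescue, stress), sheet)
    reversal = pd.Series(False, index=step1.index)
    down = step1["direction"] == "down"
    up = step1["direction"] == "up"
    reversal[down & (step2["ratio"] >= thresholds.rescue_up)] = True
    reversal[up & (step2["ratio"] <= thresholds.rescue_down)] = True
    out = pd.DataFrame({
        "dir_stress_vs_control": step1["direction"],
        "ratio_stress_vs_control": step1["ratio"],
        "ratio_rescue_vs_stress": step2["ratio"],
        "recovered": reversal,
        "lipid_class": step1["lipid_class"],
    })
    logger.info("recovery_analysis: %d recovered of %d differential",
                int(reversal.sum()), int((down | up).sum()))
    return out


def enrichment_test(
    selected: set[str],
    universe: set[str],
    annotation: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per category.

    ``annotation`` maps ids to their category sets; categories with no
    member in the universe are skipped (logged).  Returns a DataFrame
    with per-category counts, the hypergeometric tail p-value and its
    Benjamini-Hochberg adjustment.
    """
    if not selected <= universe:
        raise ValueError("selected must be a subset of universe")
    categories: dict[str, set[str]] = {}
    for mid in universe:
        for cat in annotation.get(mid, ()):
            categories.setdefault(cat, set()).add(mid)
    skipped = set()
    for cat in set(annotation_categories(annotation)) - set(categories):
        skipped.add(cat)
    if skipped:
        logger.info("enrichment_test: categories absent from universe skipped: %s", sorted(skipped))

    n_universe = len(universe)
    n_selected = len(selected)
    rows = []
    for cat, members in sorted(categories.items()):
        k = len(selected & members)
        big_k = len(members)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_selected)) if n_selected else 1.0
        rows.append({"category": cat, "n_selected_in_cat": k,
                     "n_cat": big_k, "n_selected": n_selected,
                     "n_universe": n_universe, "p_value": min(p, 1.0)})
    result = pd.DataFrame(rows, columns=["category", "n_selected_in_cat", "n_cat",
                                         "n_selected", "n_universe", "p_value"])
    if len(result):
        result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
    else:
        result["q_value"] = pd.Series(dtype=float)
    return result


def annotation_categories(annotation: dict[str, set[str]]):
    for cats in annotation.values():
        yield from cats
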