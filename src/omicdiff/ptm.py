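"""Differential quantification chain for PTM-site intensity data.

The chain mirrors standard label-free/TMT site-level practice:

1. *Centralization*: each site's per-sample intensity is divided by the
   site's across-sample mean, giving relative quantitative values
   ``R_ij = I_ij / mean_j(I_j)`` whose row mean is 1.
2. *Protein normalization* (optional): each site's relative value is
   divided by the host protein's relative value in the same sample, to
   remove protein-expression changes from the modification signal.
3. *Fold change*: ``FC(A/B) = mean_{i in A}(R_i) / mean_{i in B}(R_i)``
   — the ratio of group means of relative values.
4. *CV statistic*: the coefficient of variation of the replicate-paired
   between-group ratios ``A_1/B_1, A_2/B_2, ...`` (sample SD, n-1
   denominator, divided by the mean).  It is the significance index:
   a site is callable only when CV < ``cv_max``.
5. *Threshold calling*: up when ``FC > fc_up`` and ``CV < cv_max``;
   down when ``FC < fc_down`` and ``CV < cv_max`` (strict
   inequalities); sites with fewer than two usable ratio pairs or an
   undefined fold change are ``undetermined``.
6. *Aggregation*: a protein counts as up (down) when at least one of
   its sites is up (down); a protein may be both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ThresholdConfig
from .io import SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "RelativeQuantTable",
    "centralize",
    "centralize_proteins",
    "protein_normalize",
    "fold_change",
    "cv_statistic",
    "call_differential_sites",
    "aggregate_sites_to_proteins",
]

DIRECTIONS = ("up", "down", "ns", "undetermined")


@dataclass
class RelativeQuantTable:
    """Centralized relative quantitative values.

    ``values`` keeps the site MultiIndex of the source intensity table;
    ``protein_normalized`` flags, per row, whether every cell of the row
    was divided by the host protein's relative value (False both before
    normalization and when any cell had to fall back to its
    unnormalized value).
    """

    values: pd.DataFrame
    protein_normalized: pd.Series

    def __post_init__(self) -> None:
        self.protein_normalized = self.protein_normalized.reindex(self.values.index)


def centralize(table: pd.DataFrame) -> RelativeQuantTable:
    """Divide each row by its across-sample mean of non-missing cells.

    Rows where every cell is missing cannot be centralized and are
    dropped with a logged count.
    """
    n_all_missing = int(table.isna().all(axis=1).sum())
    if n_all_missing:
        logger.info("centralize: dropping %d all-missing rows", n_all_missing)
        table = table.dropna(how="all")
    row_means = table.mean(axis=1, skipna=True)
    values = table.div(row_means, axis=0)
    flags = pd.Series(False, index=values.index, name="protein_normalized")
    return RelativeQuantTable(values=values, protein_normalized=flags)


def centralize_proteins(proteins: pd.DataFrame) -> pd.DataFrame:
    """Row-wise centralization of a protein intensity table."""
    proteins = proteins.dropna(how="all")
    return proteins.div(proteins.mean(axis=1, skipna=True), axis=0)


def protein_normalize(sites: RelativeQuantTable, proteins: pd.DataFrame) -> RelativeQuantTable:
    """Divide site relative values by the host protein's relative value.

    The protein table is centralized first.  A site cell keeps its
    unnormalized value when its protein is absent from the protein
    table or the protein value is missing in that sample; any fallback
    marks the row ``protein_normalized=False``.  A protein relative
    value of exactly 0 would produce an infinite ratio, so that cell is
    set missing instead (logged).
    """
    prot_rel = centralize_proteins(proteins)
    values = sites.values.copy()
    flags = pd.Series(False, index=values.index, name="protein_normalized")
    protein_ids = values.index.get_level_values("protein_id")
    shared_cols = [c for c in values.columns if c in prot_rel.columns]
    n_zero = 0
    for i, pid in enumerate(protein_ids):
        if pid not in prot_rel.index:
            continue
        prow = prot_rel.loc[pid, shared_cols]
        srow = values.iloc[i]
        fallback = False
        for col in values.columns:
            if pd.isna(srow[col]):
                continue
            pval = prow.get(col, np.nan)
            if pd.isna(pval):
                fallback = True
            elif pval == 0:
                values.iloc[i, values.columns.get_loc(col)] = np.nan
                n_zero += 1
            else:
                values.iloc[i, values.columns.get_loc(col)] = srow[col] / pval
        flags.iloc[i] = not fallback
    if n_zero:
        logger.warning("protein_normalize: %d cells dropped (protein relative value 0)", n_zero)
    return RelativeQuantTable(values=values, protein_normalized=flags)


def _group_values(relq: RelativeQuantTable, sheet: SampleSheet, group: str) -> pd.DataFrame:
    cols = [s for s in sheet.samples(group) if s in relq.values.columns]
    if not cols:
        raise KeyError(f"no columns for group {group!r} in table")
    return relq.values[cols]


def fold_change(
    relq: RelativeQuantTable,
    contrast: tuple[str, str],
    sheet: SampleSheet,
) -> pd.Series:
    """Per-site fold change ``mean_A(R) / mean_B(R)``.

    NaN where either group has no non-missing value for the site.
    """
    group_a, group_b = contrast
    mean_a = _group_values(relq, sheet, group_a).mean(axis=1, skipna=True)
    mean_b = _group_values(relq, sheet, group_b).mean(axis=1, skipna=True)
    fc = mean_a / mean_b
    fc[(mean_b == 0) | mean_a.isna() | mean_b.isna()] = np.nan
    fc.name = "fc"
    return fc


def _paired_ratios(
    relq: RelativeQuantTable,
    contrast: tuple[str, str],
    sheet: SampleSheet,
) -> pd.DataFrame:
    """Matrix of replicate-paired ratios A_i/B_i (one column per pair).

    Pairs with a missing numerator/denominator, or a zero denominator
    (which would give an infinite ratio), yield NaN in that column.
    """
    group_a, group_b = contrast
    pairs = sheet.paired_samples(group_a, group_b)
    out = {}
    n_zero_denom = 0
    for k, (sa, sb) in enumerate(pairs, start=1):
        num = relq.values[sa]
        den = relq.values[sb]
        ratio = num / den
        zero = den == 0
        n_zero_denom += int((zero & num.notna()).sum())
        ratio[zero] = np.nan
        out[f"pair{k}"] = ratio
    if n_zero_denom:
        logger.warning("cv_statistic: excluded %d pairs with zero denominator", n_zero_denom)
    return pd.DataFrame(out, index=relq.values.index)


def cv_statistic(
    relq: RelativeQuantTable,
    contrast: tuple[str, str],
    sheet: SampleSheet,
) -> pd.Series:
    """Coefficient of variation of the replicate-paired ratios.

    ``CV = SD(A_1/B_1, ..., A_n/B_n) / mean(...)`` with the sample SD
    (n-1 denominator).  NaN where fewer than 2 usable pairs exist.
    """
    ratios = _paired_ratios(relq, contrast, sheet)
    n_pairs = ratios.notna().sum(axis=1)
    cv = ratios.std(axis=1, ddof=1, skipna=True) / ratios.mean(axis=1, skipna=True)
    cv[n_pairs < 2] = np.nan
    cv.name = "cv"
    return cv


def call_differential_sites(
    relq: RelativeQuantTable,
    contrast: tuple[str, str],
    sheet: SampleSheet,
    thresholds: ThresholdConfig,
) -> pd.DataFrame:
    """Classify every site as up / down / ns / undetermined.

    Returns a DataFrame on the site MultiIndex with columns ``fc``,
    ``cv``, ``n_ratio_pairs`` and ``direction``.  Thresholds are strict:
    up requires ``fc > fc_up`` and ``cv < cv_max``; down requires
    ``fc < fc_down`` and ``cv < cv_max``.  A site is undetermined when
    its fold change is undefined or fewer than two replicate-paired
    ratios are usable.
    """
    if thresholds.mode not in ("label_free", "tmt"):
        raise ValueError(f"site calling needs mode label_free or tmt, got {thresholds.mode!r}")
    fc = fold_change(relq, contrast, sheet)
    ratios = _paired_ratios(relq, contrast, sheet)
    n_pairs = ratios.notna().sum(axis=1).rename("n_ratio_pairs")
    cv = ratios.std(axis=1, ddof=1, skipna=True) / ratios.mean(axis=1, skipna=True)
    cv[n_pairs < 2] = np.nan
    cv.name = "cv"

    direction = pd.Series("ns", index=relq.values.index, name="direction")
    usable = fc.notna() & cv.notna()
    direction[~usable] = "undetermined"
    direction[usable & (fc > thresholds.fc_up) & (cv < thresholds.cv_max)] = "up"
    direction[usable & (fc < thresholds.fc_down) & (cv < thresholds.cv_max)] = "down"
    calls = pd.concat([fc, cv, n_pairs, direction], axis=1)
    logger.info(
        "call_differential_sites %s vs %s: %s",
        contrast[0], contrast[1], direction.value_counts().to_dict(),
    )
    return calls


def aggregate_sites_to_proteins(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse site calls to per-protein summaries.

    A protein is flagged up (down) when at least one of its sites is up
    (down); both flags may be set.  Returns a DataFrame indexed by
    ``protein_id`` with columns ``n_sites_up``, ``n_sites_down``,
    ``protein_direction_up``, ``protein_direction_down``.
    """
    protein_ids = calls.index.get_level_values("protein_id")
    up = (calls["direction"] == "up").groupby(protein_ids).sum().astype(int)
    down = (calls["direction"] == "down").groupby(protein_ids).sum().astype(int)
    out = pd.DataFrame({
        "n_sites_up": up,
        "n_sites_down": down,
    })
    out["protein_direction_up"] = out["n_sites_up"] >= 1
    out["protein_direction_down"] = out["n_sites_down"] >= 1
    out.index.name = "protein_id"
    return out
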