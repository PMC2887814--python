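"""Stage 2 — lineage-specificity scoring against a reference compendium.

This is the core of the pipeline. For every candidate transcript:

1. *Present/absent calls.* In each non-target reference cell the
   transcript is called **present** if its level exceeds 50% of the
   target-lineage reference level, otherwise **absent**.
2. *Enrichment score.* ECS = (number of absent calls) / n over the n
   non-target reference cells; ECS = 1 means the transcript is absent
   everywhere outside the target lineage.
3. *Outlier analysis.* Over all reference cells jointly, a cell is an
   outlier when its expression deviates more than two sample standard
   deviations from the all-cell mean. A transcript is a good candidate
   only when the outlier cluster is non-empty, consists purely of
   target-lineage cells, and lies above the mean (``target_only``).
4. *Rank score.* rank = FC x REF_FOLD, the product of the primary-panel
   and reference-compendium target/background mean-expression ratios.
   Higher rank = higher confidence in lineage restriction.

Selection keeps candidates with ECS = 1, a target-only outlier cluster
and REF_FOLD >= 3, then trims to the top fraction (default 60%) by rank
score. Allow/deny lists apply last — they stand in for any manual
curation applied to a published list, which is not an algorithmic step.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import TARGET, ExpressionMatrix, SampleSheet
from .differential import DEFAULT_EPS, fold_change
from .errors import UsageError

OUTLIER_TARGET_ONLY = "target_only"
OUTLIER_MIXED = "mixed"
OUTLIER_NONE = "none"


def present_absent_calls(reference_matrix: ExpressionMatrix,
                         reference_sheet: SampleSheet,
                         ec_level_stat: str = "mean",
                         fraction: float = 0.5) -> pd.DataFrame:
    """Boolean present-call table (genes x non-target reference cells).

    The target-lineage reference level L is the mean (or, optionally,
    max) over target reference cells; cell i is *present* iff its value
    is strictly greater than ``fraction * L``.
    """
    reference_sheet.check_matches(reference_matrix)
    target = reference_sheet.target_samples
    others = reference_sheet.background_samples
    if not target:
        raise UsageError("reference sheet marks no target cells")
    t_vals = reference_matrix.column_values(target)
    if ec_level_stat == "mean":
        level = t_vals.mean(axis=1)
    elif ec_level_stat == "max":
        level = t_vals.max(axis=1)
    else:
        raise UsageError(f"unknown ec_level_stat {ec_level_stat!r}")
    o_vals = reference_matrix.column_values(others)
    present = o_vals > fraction * level[:, None]
    return pd.DataFrame(present, index=list(reference_matrix.gene_ids),
                        columns=others)


def enrichment_score(calls) -> "pd.Series | float":
    """Fraction of non-target reference cells in which a gene is absent.

    ``calls`` is a boolean present-call vector (one gene) or table
    (genes x cells) as returned by :func:`present_absent_calls`.
    """
    if isinstance(calls, pd.DataFrame):
        if calls.shape[1] == 0:
            raise UsageError("empty call vector")
        return 1.0 - calls.mean(axis=1)
    arr = np.asarray(calls, dtype=bool)
    if arr.ndim != 1 or arr.size == 0:
        raise UsageError("calls must be a non-empty 1-D vector or a DataFrame")
    return float(1.0 - arr.mean())


def outlier_analysis(expression_row: pd.Series,
                     sheet: SampleSheet) -> tuple[set[str], str]:
    """Two-sigma outlier cluster of one gene across all samples.

    Returns the outlier sample set and its class: ``target_only`` when
    the cluster is non-empty, purely target-lineage and above the mean;
    ``none`` when empty (including the zero-variance case); ``mixed``
    otherwise.
    """
    row = expression_row.reindex(list(sheet.sample_ids))
    if row.isna().any():
        raise UsageError("expression row does not cover all sheet samples")
    x = row.to_numpy(dtype=float)
    if x.size < 3:
        raise UsageError("outlier analysis needs >= 3 samples")
    mu = x.mean()
    s = x.std(ddof=1)
    if s == 0:
        return set(), OUTLIER_NONE
    mask = np.abs(x - mu) > 2.0 * s
    outliers = {sid for sid, m in zip(sheet.sample_ids, mask) if m}
    if not outliers:
        return set(), OUTLIER_NONE
    lineage = dict(zip(sheet.frame["sample_id"], sheet.frame["lineage"]))
    all_target = all(lineage[sid] == TARGET for sid in outliers)
    above = all(row[sid] > mu for sid in outliers)
    if all_target and above:
        return outliers, OUTLIER_TARGET_ONLY
    return outliers, OUTLIER_MIXED


def ref_fold(reference_matrix: ExpressionMatrix, reference_sheet: SampleSheet,
             eps: float = DEFAULT_EPS) -> pd.Series:
    """Target/non-target mean-expression ratio in the reference compendium."""
    reference_sheet.check_matches(reference_matrix)
    series = fold_change(reference_matrix, reference_sheet.target_samples,
                         reference_sheet.background_samples, eps)
    return series.rename("ref_fold")


def rank_score(fc, ref_fold_value):
    """Composite rank = FC x REF_FOLD (works on scalars or arrays)."""
    fc_arr = np.asarray(fc, dtype=float)
    rf_arr = np.asarray(ref_fold_value, dtype=float)
    if np.any(fc_arr <= 0) or np.any(rf_arr <= 0):
        raise UsageError("rank_score requires strictly positive fc and ref_fold")
    out = fc_arr * rf_arr
    return float(out) if out.ndim == 0 else out


def specificity_table(primary_matrix: ExpressionMatrix,
                      primary_sheet: SampleSheet,
                      reference_matrix: ExpressionMatrix,
                      reference_sheet: SampleSheet,
                      genes: Sequence[str] | None = None,
                      ec_level_stat: str = "mean",
                      eps: float = DEFAULT_EPS) -> pd.DataFrame:
    """Full per-gene specificity record table.

    ``genes`` restricts the computation (typically to the DE-passing
    union from stage 1); the genes must be present in both matrices.
    Columns: gene_id, fc, ecs, outlier_class, ref_fold, rank_score.
    """
    primary_sheet.check_matches(primary_matrix)
    reference_sheet.check_matches(reference_matrix)
    if genes is not None:
        primary_matrix = primary_matrix.subset_genes(genes)
        reference_matrix = reference_matrix.subset_genes(genes)
    if primary_matrix.gene_ids != reference_matrix.gene_ids:
        raise UsageError("primary and reference matrices must cover the same genes")

    fc = fold_change(primary_matrix, primary_sheet.target_samples,
                     primary_sheet.background_samples, eps)
    calls = present_absent_calls(reference_matrix, reference_sheet, ec_level_stat)
    ecs = enrichment_score(calls)
    rf = ref_fold(reference_matrix, reference_sheet, eps)

    ref_frame = reference_matrix.to_frame()
    classes = []
    for gene in primary_matrix.gene_ids:
        _, klass = outlier_analysis(ref_frame.loc[gene], reference_sheet)
        classes.append(klass)

    table = pd.DataFrame({
        "gene_id": list(primary_matrix.gene_ids),
        "fc": fc.to_numpy(),
        "ecs": ecs.to_numpy(),
        "outlier_class": classes,
        "ref_fold": rf.to_numpy(),
    })
    table["rank_score"] = table["fc"].to_numpy() * table["ref_fold"].to_numpy()
    return table


def select_restricted(records: pd.DataFrame, top_fraction: float = 0.60,
                      min_ref_fold: float = 3.0,
                      allowlist: Sequence[str] = (),
                      denylist: Sequence[str] = ()) -> pd.DataFrame:
    """Final selection: candidacy gate, top-fraction trim, curation lists.

    Candidates need ECS = 1, a target-only outlier cluster and
    REF_FOLD >= ``min_ref_fold``. The ceil(top_fraction * pool) highest
    rank scores are kept (ties broken by gene_id, ascending). Denylist
    removals and allowlist retentions (of pool candidates trimmed by the
    fraction cut) apply last. Returns the full record table with a
    ``selected`` flag, sorted by rank score descending.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise UsageError("top_fraction must be in (0, 1]")
    required = {"gene_id", "ecs", "outlier_class", "ref_fold", "rank_score"}
    missing = required - set(records.columns)
    if missing:
        raise UsageError(f"records missing columns {sorted(missing)}")

    table = records.sort_values(["rank_score", "gene_id"],
                                ascending=[False, True],
                                kind="mergesort").reset_index(drop=True)
    pool = (table["ecs"] == 1.0) \
        & (table["outlier_class"] == OUTLIER_TARGET_ONLY) \
        & (table["ref_fold"] >= min_ref_fold)
    n_pool = int(pool.sum())
    if n_pool == 0:
        warnings.warn("empty candidate pool; nothing selected")
    n_keep = math.ceil(top_fraction * n_pool)
    pool_rank = pool.cumsum()  # position within the pool, in rank order
    selected = pool & (pool_rank <= n_keep)
    if allowlist:
        selected |= pool & table["gene_id"].isin(set(allowlist))
    if denylist:
        selected &= ~table["gene_id"].isin(set(denylist))
    table["selected"] = selected.to_numpy()
    return table
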