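"""Stage 1 — differential expression by lower-confidence-bound fold change.

A gene is called differentially expressed for a target subgroup when the
90% lower confidence bound (LCB) of its fold change against the pooled
background samples exceeds a threshold (default 3) and the set-level
permutation estimate of the median false discovery rate is below a
threshold (default 2%).

The LCB is a deliberately stringent estimate of the fold change: it
divides a one-sided 95% lower bound on the target mean by a one-sided
95% upper bound on the background mean (two one-sided t bounds forming
a conservative 90% bound on the ratio):

    lcb = max(0, (m_t - t_{0.95,df_t} se_t) / (m_b + t_{0.95,df_b} se_b))

where m, se are the group mean and standard error and df = n - 1. By
construction lcb <= fc for every gene.

The FDR is a set-level quantity, attached to every record of a
comparison: the median, over random target/background relabelings that
preserve group sizes, of the number of genes passing the LCB cut,
divided by the observed passing count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import TARGET, ExpressionMatrix, SampleSheet
from .errors import UsageError

DEFAULT_EPS = 1.0  # signal-unit floor for denominators; ratios of
                   # near-zero normalized signals are meaningless


def _group_arrays(matrix: ExpressionMatrix, target_samples: Sequence[str],
                  background_samples: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    t_ids, b_ids = list(target_samples), list(background_samples)
    if not t_ids or not b_ids:
        raise UsageError("target and background sample groups must be non-empty")
    if set(t_ids) & set(b_ids):
        raise UsageError("target and background sample groups must be disjoint")
    return matrix.column_values(t_ids), matrix.column_values(b_ids)


def fold_change(matrix: ExpressionMatrix, target_samples: Sequence[str],
                background_samples: Sequence[str], eps: float = DEFAULT_EPS,
                ) -> pd.Series:
    """Per-gene ratio of group means, with an ``eps`` floor on the denominator."""
    t, b = _group_arrays(matrix, target_samples, background_samples)
    fc = t.mean(axis=1) / np.maximum(b.mean(axis=1), eps)
    return pd.Series(fc, index=list(matrix.gene_ids), name="fc")


def _lcb_from_arrays(t: np.ndarray, b: np.ndarray, level: float,
                     eps: float) -> np.ndarray:
    n_t, n_b = t.shape[1], b.shape[1]
    if n_t < 2 or n_b < 2:
        raise UsageError("LCB needs >= 2 samples per group")
    alpha = (1.0 - level) / 2.0  # one-sided 95% bounds for the default 90% level
    q_t = stats.t.ppf(1.0 - alpha, n_t - 1)
    q_b = stats.t.ppf(1.0 - alpha, n_b - 1)
    m_t, m_b = t.mean(axis=1), b.mean(axis=1)
    se_t = t.std(axis=1, ddof=1) / np.sqrt(n_t)
    se_b = b.std(axis=1, ddof=1) / np.sqrt(n_b)
    numer = np.maximum(m_t - q_t * se_t, 0.0)
    denom = np.maximum(m_b + q_b * se_b, eps)
    return numer / denom


def lcb_fold_change(matrix: ExpressionMatrix, target_samples: Sequence[str],
                    background_samples: Sequence[str], level: float = 0.90,
                    eps: float = DEFAULT_EPS) -> pd.Series:
    """Per-gene lower confidence bound of the fold change (default 90%)."""
    t, b = _group_arrays(matrix, target_samples, background_samples)
    lcb = _lcb_from_arrays(t, b, level, eps)
    return pd.Series(lcb, index=list(matrix.gene_ids), name="lcb")


def _comparison_samples(sheet: SampleSheet, subgroup: str) -> tuple[list[str], list[str]]:
    target = sheet.samples_where(lineage=TARGET, subgroup=subgroup)
    if not target:
        raise UsageError(f"no target samples in subgroup {subgroup!r}")
    background = sheet.background_samples
    return target, background


def permutation_fdr(matrix: ExpressionMatrix, sheet: SampleSheet, subgroup: str,
                    lcb_threshold: float = 3.0, n_perm: int = 100,
                    seed: int = 0, level: float = 0.90,
                    eps: float = DEFAULT_EPS) -> float:
    """Set-level median FDR of the LCB cut, by label permutation.

    Group sizes are preserved under relabeling. When the observed pass
    count is zero the FDR is 0 by convention. The estimate is clipped
    to [0, 1].
    """
    if n_perm < 10:
        raise UsageError("n_perm must be >= 10")
    target, background = _comparison_samples(sheet, subgroup)
    pooled = matrix.column_values(target + background)
    n_t, n = len(target), len(target) + len(background)

    observed = int((_lcb_from_arrays(pooled[:, :n_t], pooled[:, n_t:],
                                     level, eps) > lcb_threshold).sum())
    n_distinct = comb(n, n_t)
    if n_distinct <= n_perm:
        warnings.warn(
            f"only {n_distinct} distinct relabelings for this design; using all")
        assignments: Iterable[Sequence[int]] = combinations(range(n), n_t)
    else:
        rng = np.random.default_rng(seed)
        assignments = (rng.permutation(n)[:n_t] for _ in range(n_perm))

    counts = []
    idx_all = np.arange(n)
    for t_idx in assignments:
        t_mask = np.zeros(n, dtype=bool)
        t_mask[list(t_idx)] = True
        lcb = _lcb_from_arrays(pooled[:, idx_all[t_mask]],
                               pooled[:, idx_all[~t_mask]], level, eps)
        counts.append(int((lcb > lcb_threshold).sum()))
    if observed == 0:
        return 0.0
    return float(np.clip(np.median(counts) / observed, 0.0, 1.0))


@dataclass(frozen=True)
class OverlapSummary:
    """Exact Venn-region counts over subgroup DE lists."""

    regions: Mapping[tuple[str, ...], int]  # sorted-subgroup-tuple -> count
    union_transcripts: int
    union_genes: int

    def __post_init__(self) -> None:
        if sum(self.regions.values()) != self.union_transcripts:
            raise UsageError("Venn region counts must sum to the union size")


def call_de(matrix: ExpressionMatrix, sheet: SampleSheet, subgroup: str,
            lcb_threshold: float = 3.0, fdr_threshold: float = 0.02,
            n_perm: int = 100, seed: int = 0, level: float = 0.90,
            eps: float = DEFAULT_EPS) -> pd.DataFrame:
    """Call DE for one subgroup-vs-background comparison.

    Returns one record per gene with columns ``gene_id, comparison, fc,
    lcb, fdr, passes``; ``passes`` requires a strictly-above-threshold
    LCB and a set-level FDR strictly below threshold.
    """
    sheet.check_matches(matrix)
    target, background = _comparison_samples(sheet, subgroup)
    fc = fold_change(matrix, target, background, eps)
    lcb = lcb_fold_change(matrix, target, background, level, eps)
    fdr = permutation_fdr(matrix, sheet, subgroup, lcb_threshold, n_perm,
                          seed, level, eps)
    passes = (lcb > lcb_threshold) & (fdr < fdr_threshold)
    return pd.DataFrame({
        "gene_id": list(matrix.gene_ids),
        "comparison": f"{subgroup}_vs_background",
        "fc": fc.to_numpy(),
        "lcb": lcb.to_numpy(),
        "fdr": fdr,
        "passes": passes.to_numpy(),
    })


def overlap_summary(de_lists: Mapping[str, Iterable[str]],
                    gene_map: Mapping[str, str] | None = None) -> OverlapSummary:
    """Venn-region counts and union sizes over per-subgroup DE lists.

    ``gene_map`` maps transcript ids to gene ids for the gene-level
    union; transcripts missing from the map count as their own gene
    (with a warning).
    """
    names = sorted(de_lists)
    if len(names) < 2:
        raise UsageError("overlap_summary needs >= 2 subgroup lists")
    sets = {name: set(de_lists[name]) for name in names}
    union = set().union(*sets.values())
    regions: dict[tuple[str, ...], int] = {}
    for transcript in union:
        member_of = tuple(sorted(n for n in names if transcript in sets[n]))
        regions[member_of] = regions.get(member_of, 0) + 1
    if gene_map is None:
        gene_map = {}
    missing = [t for t in union if t not in gene_map]
    if gene_map and missing:
        warnings.warn(f"{len(missing)} transcripts missing from gene_map; "
                      "counted as their own gene")
    genes = {gene_map.get(t, t) for t in union}
    return OverlapSummary(regions, len(union), len(genes))
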