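"""Stage 4 — over-representation statistics for gene sets, promoter
sites and miRNA seed matches.

Three related analyses share the one-tailed Fisher exact
(hypergeometric) test:

* **Gene-set over-representation** — a study list against named sets
  (GMT) within a background universe, reported both as the plain Fisher
  tail p and as the conservative EASE variant (one overlapping gene
  removed), with Benjamini–Hochberg adjustment across sets.
* **Promoter-site enrichment gate** — yes-set vs no-set promoter hit
  counts; a site family passes when the Fisher p is below 0.01 *and*
  the hit-density ratio yes/no exceeds 1.2.
* **miRNA seed-match enrichment** — exact reverse-complement matches of
  the miRNA seed (positions 2–8 by default) in 3'UTRs, compared between
  a study set and a background set of UTRs.

Sequence comparisons happen in the DNA alphabet (U is normalized to T
on input) and are case-insensitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import GeneSetCollection, SequenceRecord
from .errors import UsageError


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    overlap: int
    study_size: int
    set_size: int
    background_size: int
    p_value: float
    ease_p: float = float("nan")
    adjusted_p: float = float("nan")
    passes_gate: bool = False
    ratio: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise UsageError("p_value outside [0, 1]")
        if self.overlap > min(self.study_size, self.set_size):
            raise UsageError("overlap exceeds study or set size")


def _hypergeom_tail(overlap: int, background: int, set_size: int,
                    study: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(background, set_size, study)."""
    return float(stats.hypergeom.sf(overlap - 1, background, set_size, study))


def fisher_overrepresentation(study_genes: Sequence[str],
                              gene_set: Sequence[str],
                              background_genes: Sequence[str],
                              set_id: str = "") -> EnrichmentResult:
    """One-tailed Fisher exact over-representation of ``gene_set`` in
    ``study_genes`` within the ``background_genes`` universe."""
    background = set(background_genes)
    if not background:
        raise UsageError("background universe is empty")
    study = set(study_genes)
    if not study <= background:
        raise UsageError("study genes must be a subset of the background")
    members = set(gene_set) & background
    overlap = len(study & members)
    p = _hypergeom_tail(overlap, len(background), len(members), len(study))
    return EnrichmentResult(set_id, overlap, len(study), len(members),
                            len(background), min(p, 1.0),
                            ease_p=ease_score(study_genes, gene_set,
                                              background_genes))


def ease_score(study_genes: Sequence[str], gene_set: Sequence[str],
               background_genes: Sequence[str]) -> float:
    """Conservative EASE variant of the Fisher tail: recomputed with one
    study gene removed from the overlap (overlap-1, study-1). Overlaps
    of one collapse to p = 1."""
    background = set(background_genes)
    if not background:
        raise UsageError("background universe is empty")
    study = set(study_genes)
    members = set(gene_set) & background
    overlap = len(study & members)
    if overlap == 0:
        return 1.0
    p = _hypergeom_tail(overlap - 1, len(background), len(members),
                        len(study) - 1)
    return float(min(p, 1.0))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise UsageError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def gmt_overrepresentation(study_genes: Sequence[str],
                           collection: GeneSetCollection,
                           background_genes: Sequence[str]) -> pd.DataFrame:
    """Fisher + EASE over every set of a collection, BH-adjusted."""
    rows = [fisher_overrepresentation(study_genes, gs.members,
                                      background_genes, gs.set_id)
            for gs in collection]
    table = pd.DataFrame([vars(r) for r in rows])
    if not table.empty:
        table["adjusted_p"] = bh_fdr(table["p_value"])
        table["neg_log10_ease"] = -np.log10(np.maximum(table["ease_p"], 1e-300))
        table = table.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return table


def site_enrichment_gate(yes_hits: int, yes_promoters: int, no_hits: int,
                         no_promoters: int, p_threshold: float = 0.01,
                         ratio_threshold: float = 1.2,
                         set_id: str = "") -> EnrichmentResult:
    """Yes/no promoter-site enrichment with the two-condition gate.

    Hits are counted as promoters carrying the site (at most one per
    promoter); the one-tailed Fisher test treats promoters as trials.
    The gate passes when p < ``p_threshold`` AND the hit-density ratio
    yes/no exceeds ``ratio_threshold``.
    """
    if min(yes_hits, no_hits) < 0 or min(yes_promoters, no_promoters) <= 0:
        raise UsageError("hit counts must be >= 0 and promoter counts > 0")
    if yes_hits > yes_promoters or no_hits > no_promoters:
        raise UsageError("hits cannot exceed the number of promoters")
    density_yes = yes_hits / yes_promoters
    density_no = no_hits / no_promoters
    total = yes_promoters + no_promoters
    p = _hypergeom_tail(yes_hits, total, yes_hits + no_hits, yes_promoters)
    if density_no == 0:
        warnings.warn("no-set hit density is zero; ratio undefined, "
                      "gate decided by p only")
        ratio = float("inf")
        passes = p < p_threshold
    else:
        ratio = density_yes / density_no
        passes = (p < p_threshold) and (ratio > ratio_threshold)
    return EnrichmentResult(set_id, yes_hits, yes_promoters,
                            yes_hits + no_hits, total, min(p, 1.0),
                            passes_gate=passes, ratio=ratio)


@dataclass(frozen=True)
class SeedMatchResult:
    mirna_id: str
    gene_id: str
    n_sites: int
    site_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_sites != len(self.site_positions):
            raise UsageError("n_sites must equal the number of positions")


def seed_site(mirna: SequenceRecord,
              seed_span: tuple[int, int] = (2, 8)) -> str:
    """Reverse complement of the miRNA seed (1-based inclusive span)."""
    lo, hi = seed_span
    if not 1 <= lo <= hi:
        raise UsageError("seed_span must be 1-based with lo <= hi")
    if hi > len(mirna.sequence):
        raise UsageError(
            f"miRNA {mirna.id!r} shorter than seed span {seed_span}")
    seed = mirna.sequence[lo - 1:hi]
    return str(Seq(seed).reverse_complement())


def count_sites(sequence: str, site: str,
                allow_overlap: bool = False) -> list[int]:
    """0-based start offsets of ``site`` in ``sequence``.

    Non-overlapping occurrences are counted greedily left-to-right
    unless ``allow_overlap`` is set.
    """
    seq = sequence.upper().replace("U", "T")
    positions: list[int] = []
    start = 0
    while True:
        hit = seq.find(site, start)
        if hit < 0:
            break
        positions.append(hit)
        start = hit + (1 if allow_overlap else len(site))
    return positions


def mirna_seed_match(utr_records: Sequence[SequenceRecord],
                     mirna_records: Sequence[SequenceRecord],
                     seed_span: tuple[int, int] = (2, 8),
                     allow_overlap: bool = False) -> list[SeedMatchResult]:
    """Exact seed-complement site counts for every miRNA x UTR pair."""
    results = []
    for mirna in mirna_records:
        site = seed_site(mirna, seed_span)
        for utr in utr_records:
            positions = count_sites(utr.sequence, site, allow_overlap)
            results.append(SeedMatchResult(mirna.id, utr.id, len(positions),
                                           tuple(positions)))
    return results


def genes_with_sites(matches: Sequence[SeedMatchResult]) -> dict[str, int]:
    """Per-miRNA count of genes carrying at least one site."""
    counts: dict[str, int] = {}
    for m in matches:
        if m.n_sites > 0:
            counts[m.mirna_id] = counts.get(m.mirna_id, 0) + 1
    return counts


def total_sites(matches: Sequence[SeedMatchResult]) -> dict[str, int]:
    """Per-miRNA total site count (all genes summed)."""
    counts: dict[str, int] = {}
    for m in matches:
        counts[m.mirna_id] = counts.get(m.mirna_id, 0) + m.n_sites
    return counts


def mirna_enrichment(match_counts_study: Mapping[str, int],
                     match_counts_background: Mapping[str, int],
                     study_size: int, background_size: int) -> pd.DataFrame:
    """Per-miRNA enrichment of seed-carrying genes in the study set.

    ``match_counts_*`` give, per miRNA, the number of genes with at
    least one seed site; the background is the full universe including
    the study genes. One-tailed Fisher per miRNA, BH across miRNAs.
    """
    if background_size < study_size:
        raise UsageError("background must be at least as large as the study set")
    rows = []
    for mirna in sorted(set(match_counts_study) | set(match_counts_background)):
        a = int(match_counts_study.get(mirna, 0))
        k = int(match_counts_background.get(mirna, 0))
        if a > min(k, study_size):
            raise UsageError(
                f"{mirna}: study hits ({a}) exceed background hits ({k}) "
                f"or study size ({study_size})")
        p = 1.0 if k == 0 else _hypergeom_tail(a, background_size, k, study_size)
        rows.append((mirna, a, k, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["mirna_id", "study_hits",
                                        "background_hits", "p_value"])
    if not table.empty:
        table["adjusted_p"] = bh_fdr(table["p_value"])
        table = table.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return table
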