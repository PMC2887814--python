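"""End-to-end orchestration: DE calling -> specificity -> selection ->
patterns, with a run manifest and a fixed-layout report.

The stage order matches the filter cascade of the underlying study
design: per-subgroup DE lists are unioned, the union is scored against
the reference compendium, candidates are gated (ECS = 1, target-only
outlier cluster, REF_FOLD >= 3) and trimmed to the top fraction by rank
score, and the surviving genes are pattern-clustered. Record counts can
only shrink along the cascade, and the manifest records each count.

Outputs are deterministic for a fixed config and seed (the manifest's
wall-clock timestamp aside).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .data_model import ExpressionMatrix, SampleSheet
from .differential import call_de, overlap_summary, OverlapSummary
from .errors import UsageError
from .patterns import kmeans_patterns
from .specificity import select_restricted, specificity_table

REPORT_COLUMNS = ("gene_id", "fc", "ref_fold", "rank_score", "ecs",
                  "outlier_class", "selected")


@dataclass(frozen=True)
class PipelineParams:
    lcb_threshold: float = 3.0
    fdr_threshold: float = 0.02
    n_perm: int = 100
    top_fraction: float = 0.60
    min_ref_fold: float = 3.0
    k: int = 4
    seed: int = 0
    eps: float = 1.0
    ec_level_stat: str = "mean"
    allowlist: tuple[str, ...] = ()
    denylist: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.lcb_threshold <= 0 or self.min_ref_fold <= 0:
            raise UsageError("thresholds must be positive")
        if not 0.0 < self.top_fraction <= 1.0:
            raise UsageError("top_fraction must be in (0, 1]")
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise UsageError("fdr_threshold must be in (0, 1]")


@dataclass
class PipelineResult:
    de_tables: dict[str, pd.DataFrame]
    overlap: OverlapSummary
    records: pd.DataFrame       # full specificity table with `selected`
    selected: pd.DataFrame      # selected rows, rank-sorted
    pattern_assignments: pd.DataFrame | None
    manifest: dict


def _config_hash(params: PipelineParams) -> str:
    blob = json.dumps(asdict(params), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(primary_matrix: ExpressionMatrix, primary_sheet: SampleSheet,
                 reference_matrix: ExpressionMatrix,
                 reference_sheet: SampleSheet,
                 params: PipelineParams = PipelineParams(),
                 gene_map: dict[str, str] | None = None) -> PipelineResult:
    """Run DE -> specificity -> selection -> patterns on in-memory inputs."""
    primary_sheet.check_matches(primary_matrix)
    reference_sheet.check_matches(reference_matrix)

    de_tables: dict[str, pd.DataFrame] = {}
    de_lists: dict[str, list[str]] = {}
    for subgroup in primary_sheet.target_subgroups:
        table = call_de(primary_matrix, primary_sheet, subgroup,
                        lcb_threshold=params.lcb_threshold,
                        fdr_threshold=params.fdr_threshold,
                        n_perm=params.n_perm, seed=params.seed,
                        eps=params.eps)
        de_tables[subgroup] = table
        de_lists[subgroup] = list(table.loc[table["passes"], "gene_id"])

    if len(de_lists) >= 2:
        overlap = overlap_summary(de_lists, gene_map)
    else:
        only = next(iter(de_lists.values()), [])
        overlap = OverlapSummary({tuple(de_lists): len(only)} if only else {},
                                 len(only), len(only))

    union = sorted(set().union(*de_lists.values())) if de_lists else []
    ref_genes = set(reference_matrix.gene_ids)
    union = [g for g in union if g in ref_genes]

    if union:
        records = specificity_table(primary_matrix, primary_sheet,
                                    reference_matrix, reference_sheet,
                                    genes=union,
                                    ec_level_stat=params.ec_level_stat,
                                    eps=params.eps)
        records = select_restricted(records, params.top_fraction,
                                    params.min_ref_fold,
                                    params.allowlist, params.denylist)
    else:
        warnings.warn("no transcript passed the DE stage")
        records = pd.DataFrame(columns=list(REPORT_COLUMNS))
    selected = records.loc[records.get("selected", pd.Series(dtype=bool)) == True]  # noqa: E712
    selected = selected.reset_index(drop=True)

    if records.empty:
        n_candidates, n_pool = 0, 0
    else:
        gate = (records["ecs"] == 1.0) & (records["outlier_class"] == "target_only")
        n_candidates = int(gate.sum())
        n_pool = int((gate & (records["ref_fold"] >= params.min_ref_fold)).sum())

    patterns_table = None
    if len(selected) >= params.k:
        patterns_table = kmeans_patterns(
            primary_matrix.subset_genes(list(selected["gene_id"])),
            primary_sheet, k=params.k, seed=params.seed)

    manifest = {
        "config_hash": _config_hash(params),
        "seed": params.seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "counts": {
            "n_genes": primary_matrix.n_genes,
            "de_pass_per_subgroup": {s: len(g) for s, g in de_lists.items()},
            "de_union_transcripts": len(union),
            "ecs1_outlier_pool": int(n_candidates),
            "candidate_pool": n_pool,
            "selected": len(selected),
        },
    }
    return PipelineResult(de_tables, overlap, records, selected,
                          patterns_table, manifest)


def write_report(result: PipelineResult, outdir,
                 top_n: int = 10) -> list[Path]:
    """Write the fixed-layout report files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    restricted_path = outdir / "restricted_genes.tsv"
    table = result.records
    if table.empty:
        table = pd.DataFrame(columns=list(REPORT_COLUMNS))
    table[list(REPORT_COLUMNS)].to_csv(restricted_path, sep="\t", index=False,
                                       float_format="%.10g")
    written.append(restricted_path)

    for subgroup, de in result.de_tables.items():
        p = outdir / f"de_{subgroup}.tsv"
        de.to_csv(p, sep="\t", index=False, float_format="%.10g")
        written.append(p)

    overlap_path = outdir / "overlap_summary.tsv"
    with open(overlap_path, "w", encoding="utf-8") as handle:
        handle.write("region\tcount\n")
        for region in sorted(result.overlap.regions):
            handle.write("+".join(region) + f"\t{result.overlap.regions[region]}\n")
        handle.write(f"union_transcripts\t{result.overlap.union_transcripts}\n")
        handle.write(f"union_genes\t{result.overlap.union_genes}\n")
    written.append(overlap_path)

    if result.pattern_assignments is not None:
        p = outdir / "patterns.tsv"
        result.pattern_assignments.to_csv(p, sep="\t", index=False)
        written.append(p)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(result.manifest, indent=2) + "\n")
    written.append(manifest_path)

    summary_path = outdir / "summary.txt"
    with open(summary_path, "w", encoding="utf-8") as handle:
        counts = result.manifest["counts"]
        handle.write("Lineage-restricted gene selection summary\n")
        for key, value in counts.items():
            handle.write(f"  {key}: {value}\n")
        sel = result.selected
        if sel.empty:
            handle.write("zero genes selected\n")
        else:
            handle.write(f"top {min(top_n, len(sel))} by rank score:\n")
            for row in sel.head(top_n).itertuples(index=False):
                handle.write(f"  {row.gene_id}\trank={row.rank_score:.4g}\t"
                             f"fc={row.fc:.4g}\tref_fold={row.ref_fold:.4g}\n")
    written.append(summary_path)
    return written
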