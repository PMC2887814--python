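"""Synthetic primary-panel and reference-compendium generator with known truth.

The generator emulates the statistical structure the downstream analysis
assumes: positive, right-skewed normalized microarray signals that are
log-normal per gene, with multiplicative lineage effects and
multiplicative replicate noise.

Two matrices are produced from one planted truth:

* a *primary* panel — five target cell types in three subgroups
  (microvascular / venous / arterial) plus three background cell types,
  each in duplicate, mirroring a cultured primary-cell experiment;
* a *reference compendium* — a wide panel of primary cells (30 by
  default) of which a configurable small number (1 by default) belongs
  to the target lineage, mirroring public compendia in which a single
  endothelial entry sits among many other primary cell types.

Planted restricted genes are multiplied by a per-gene programmed fold in
target samples only; a configurable fraction is restricted to one target
subgroup (microvascular by default). All randomness descends from one
master seed, split into fixed per-generator streams so stages can be
re-run independently and still reproduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import BACKGROUND, TARGET, ExpressionMatrix, SampleSheet
from .errors import ConfigError, DataFormatError

PATTERN_PAN = "pan"
PATTERN_SUBGROUP = "subgroup_only"

_DEFAULT_TARGETS: Mapping[str, str] = {
    "HMVEC": "microvascular",
    "HUVEC": "venous",
    "HPVEC": "venous",
    "HAEC": "arterial",
    "HCAEC": "arterial",
}
_DEFAULT_BACKGROUND: Sequence[str] = ("HASMC", "B_CELL", "T_CELL")

# fixed stream indices split from the master seed
_STREAM_PRIMARY, _STREAM_REFERENCE, _STREAM_NULL = 0, 1, 2


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    ``baseline_log_mean``/``baseline_log_sd`` place the per-gene
    baseline on the natural-log scale (default ln(100), sd 1.0 — signals
    spanning roughly 1 to 10^4 units). ``noise_log_sd`` is the replicate
    noise on the natural-log scale (default 0.15, about 0.2 on the log2
    scale — typical duplicate-culture spread). Programmed folds are
    drawn log-uniformly from ``fold_range``.
    """

    n_genes: int = 1000
    n_restricted: int = 50
    target_cell_types: Mapping[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_TARGETS))
    background_cell_types: tuple[str, ...] = tuple(_DEFAULT_BACKGROUND)
    n_replicates: int = 2
    n_reference_cells: int = 30
    n_reference_target: int = 1
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 1.0
    fold_range: tuple[float, float] = (3.0, 200.0)
    noise_log_sd: float = 0.15
    pattern_mix: float = 0.2
    restricted_subgroup: str = "microvascular"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not 0 <= self.n_restricted <= self.n_genes:
            raise ConfigError("need 0 <= n_restricted <= n_genes")
        if self.baseline_log_sd < 0 or self.noise_log_sd < 0:
            raise ConfigError("log-scale standard deviations must be >= 0")
        lo, hi = self.fold_range
        if not (1.0 < lo <= hi):
            raise ConfigError("fold_range must satisfy 1 < lo <= hi")
        if not 0.0 <= self.pattern_mix <= 1.0:
            raise ConfigError("pattern_mix must be in [0, 1]")
        if not self.target_cell_types or not self.background_cell_types:
            raise ConfigError("need at least one target and one background cell type")
        if self.restricted_subgroup not in set(self.target_cell_types.values()):
            raise ConfigError(
                f"restricted_subgroup {self.restricted_subgroup!r} is not a "
                "subgroup of any target cell type")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not 1 <= self.n_reference_target < self.n_reference_cells:
            raise ConfigError("need 1 <= n_reference_target < n_reference_cells")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted-gene oracle: which genes are restricted, how and how much."""

    frame: pd.DataFrame  # gene_id, is_restricted, programmed_fold, pattern, subgroup

    def __post_init__(self) -> None:
        required = {"gene_id", "is_restricted", "programmed_fold", "pattern", "subgroup"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DataFormatError(f"truth table missing columns {sorted(missing)}")

    @property
    def restricted_genes(self) -> list[str]:
        f = self.frame
        return list(f.loc[f["is_restricted"], "gene_id"])

    @property
    def pan_genes(self) -> list[str]:
        f = self.frame
        return list(f.loc[f["is_restricted"] & (f["pattern"] == PATTERN_PAN), "gene_id"])

    @property
    def subgroup_genes(self) -> list[str]:
        f = self.frame
        return list(f.loc[f["is_restricted"] & (f["pattern"] == PATTERN_SUBGROUP),
                          "gene_id"])


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _primary_sheet(config: SimulationConfig) -> SampleSheet:
    rows = []
    for ct, sub in config.target_cell_types.items():
        for r in range(1, config.n_replicates + 1):
            rows.append((f"{ct}_r{r}", ct, TARGET, sub, r))
    for ct in config.background_cell_types:
        for r in range(1, config.n_replicates + 1):
            rows.append((f"{ct}_r{r}", ct, BACKGROUND, "", r))
    return SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "cell_type", "lineage", "subgroup", "replicate"]))


def _draw_truth(config: SimulationConfig, rng: np.random.Generator) -> SyntheticTruth:
    genes = _gene_ids(config.n_genes)
    restricted = np.sort(rng.choice(config.n_genes, size=config.n_restricted,
                                    replace=False))
    n_sub = int(round(config.n_restricted * config.pattern_mix))
    order = rng.permutation(config.n_restricted)
    sub_only = set(restricted[order[:n_sub]])
    folds = np.exp(rng.uniform(math.log(config.fold_range[0]),
                               math.log(config.fold_range[1]),
                               size=config.n_restricted))
    fold_of = dict(zip(restricted.tolist(), folds.tolist()))
    rows = []
    for i, g in enumerate(genes):
        if i in fold_of:
            pattern = PATTERN_SUBGROUP if i in sub_only else PATTERN_PAN
            sub = config.restricted_subgroup if pattern == PATTERN_SUBGROUP else ""
            rows.append((g, True, fold_of[i], pattern, sub))
        else:
            rows.append((g, False, 1.0, "", ""))
    return SyntheticTruth(pd.DataFrame(
        rows, columns=["gene_id", "is_restricted", "programmed_fold",
                       "pattern", "subgroup"]))


def _effect_matrix(config: SimulationConfig, truth: SyntheticTruth,
                   sheet: SampleSheet) -> np.ndarray:
    """Per-gene, per-sample multiplicative effect (1 everywhere except
    planted genes in their target samples)."""
    frame = sheet.frame
    n = len(truth.frame)
    effects = np.ones((n, len(frame)))
    is_target = (frame["lineage"] == TARGET).to_numpy()
    subgroups = frame["subgroup"].to_numpy()
    for i, row in enumerate(truth.frame.itertuples(index=False)):
        if not row.is_restricted:
            continue
        if row.pattern == PATTERN_SUBGROUP:
            cols = is_target & (subgroups == row.subgroup)
        else:
            cols = is_target
        effects[i, cols] = row.programmed_fold
    return effects


def _signal(base: np.ndarray, effects: np.ndarray, noise_log_sd: float,
            rng: np.random.Generator) -> np.ndarray:
    noise = np.exp(noise_log_sd * rng.standard_normal(effects.shape)) \
        if noise_log_sd > 0 else 1.0
    return base[:, None] * effects * noise


def generate_primary_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleSheet, SyntheticTruth]:
    """Simulate the primary cultured-cell panel with planted truth."""
    rng = _rng(config, _STREAM_PRIMARY)
    sheet = _primary_sheet(config)
    base = np.exp(config.baseline_log_mean
                  + config.baseline_log_sd * rng.standard_normal(config.n_genes))
    truth = _draw_truth(config, rng)
    values = _signal(base, _effect_matrix(config, truth, sheet),
                     config.noise_log_sd, rng)
    matrix = ExpressionMatrix(tuple(truth.frame["gene_id"]), sheet.sample_ids, values)
    return matrix, sheet, truth


def generate_reference_compendium(
    config: SimulationConfig, truth: SyntheticTruth,
) -> tuple[ExpressionMatrix, SampleSheet]:
    """Simulate the wide reference panel consistent with a planted truth.

    Restricted genes are elevated (by their programmed fold) only in the
    target reference cells; background genes have comparable levels
    everywhere. Baselines are re-drawn — the compendium emulates an
    independent platform, so absolute levels need not match the primary
    panel; the statistics downstream only use within-compendium ratios.
    """
    if len(truth.frame) != config.n_genes:
        raise ConfigError(
            f"truth has {len(truth.frame)} genes, config says {config.n_genes}")
    if len(truth.restricted_genes) != config.n_restricted:
        raise ConfigError("truth/config disagree on the number of restricted genes")
    rng = _rng(config, _STREAM_REFERENCE)
    n_t = config.n_reference_target
    rows = []
    for i in range(1, n_t + 1):
        rows.append((f"REF_EC_{i:02d}", "reference_EC", TARGET, "", i))
    for i in range(1, config.n_reference_cells - n_t + 1):
        rows.append((f"REF_C{i:02d}", f"reference_cell_{i:02d}", BACKGROUND, "", 1))
    sheet = SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "cell_type", "lineage", "subgroup", "replicate"]))

    base = np.exp(config.baseline_log_mean
                  + config.baseline_log_sd * rng.standard_normal(config.n_genes))
    frame = sheet.frame
    effects = np.ones((config.n_genes, len(frame)))
    is_target = (frame["lineage"] == TARGET).to_numpy()
    restricted_mask = truth.frame["is_restricted"].to_numpy()
    folds = truth.frame["programmed_fold"].to_numpy()
    effects[np.ix_(restricted_mask, is_target)] = \
        folds[restricted_mask][:, None]
    values = _signal(base, effects, config.noise_log_sd, rng)
    matrix = ExpressionMatrix(tuple(truth.frame["gene_id"]), sheet.sample_ids, values)
    return matrix, sheet


def generate_null_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleSheet]:
    """Simulate a primary panel with no lineage effect (label-exchangeable)."""
    if config.n_restricted != 0:
        raise ConfigError("null dataset requires n_restricted = 0")
    rng = _rng(config, _STREAM_NULL)
    sheet = _primary_sheet(config)
    base = np.exp(config.baseline_log_mean
                  + config.baseline_log_sd * rng.standard_normal(config.n_genes))
    effects = np.ones((config.n_genes, len(sheet.frame)))
    values = _signal(base, effects, config.noise_log_sd, rng)
    matrix = ExpressionMatrix(tuple(_gene_ids(config.n_genes)), sheet.sample_ids,
                              values)
    return matrix, sheet


def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    truth.frame.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> SyntheticTruth:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    frame["is_restricted"] = frame["is_restricted"].astype(bool)
    frame["pattern"] = frame["pattern"].fillna("")
    frame["subgroup"] = frame["subgroup"].fillna("")
    return SyntheticTruth(frame)


def score_recovery(truth: SyntheticTruth, selected_genes: Sequence[str]) -> dict:
    """Compare a final selected-gene list against the planted truth.

    Returns sensitivity for pan-restricted genes, sensitivity over all
    planted genes, and the false-inclusion fraction among non-planted
    genes.
    """
    selected = set(selected_genes)
    pan = set(truth.pan_genes)
    planted = set(truth.restricted_genes)
    non_planted = set(truth.frame["gene_id"]) - planted
    return {
        "sensitivity_pan": len(pan & selected) / len(pan) if pan else float("nan"),
        "sensitivity_all": (len(planted & selected) / len(planted)
                            if planted else float("nan")),
        "false_inclusion": (len(selected - planted) / len(non_planted)
                            if non_planted else float("nan")),
        "n_selected": len(selected),
    }
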