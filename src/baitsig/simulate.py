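"""Synthetic expression data with planted co-expression and genotype effects.

The generator emulates the statistical structure the downstream analyses
assume: a shared per-sample latent "hypoxia" factor carried by bait and
module genes, HIF1a-target genes shifted up only in the VHL group, and
HIF2a-target genes shifted up in VHL, SDH and EPAS1 groups, on top of
log-normal (Gaussian-on-log2) residual noise. Ground truth is returned for
recovery tests.

Model, all on log2 scale::

    x[g, s] = baseline[g] + loading[g] * factor[s] + effect[g, group(s)]
              + Normal(0, noise_sd)

The latent factor is ``N(0, 1)`` noise plus a mean shift
(``pseudohypoxia_factor_shift``) in pseudohypoxic samples — constitutive
hypoxia-pathway activation is what distinguishes VHL/SDH/EPAS1 tumors —
then standardized by its theoretical moments so it has cohort mean 0 and
variance 1. For bait/module genes
``loading = sqrt(module_r / (1 - module_r)) * noise_sd``, so the induced
pairwise Pearson correlation between any two factor-carrying genes equals
``module_r`` exactly (loading^2 / (loading^2 + noise_sd^2) = module_r)
regardless of the factor shift.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleAnnotation, ValidationError

logger = logging.getLogger("baitsig")

GROUPS = ("VHL", "SDH", "EPAS1", "other", "normal")
PSEUDOHYPOXIC_GROUPS = ("VHL", "SDH", "EPAS1")
HIF2_GROUPS = ("VHL", "SDH", "EPAS1")  # HIF2a targets rise in all three
HIF1_GROUPS = ("VHL",)  # HIF1a targets rise in VHL only


def _default_group_sizes() -> dict[str, int]:
    # 30 samples in each of the five groups: a PPGL-scale cohort of 150.
    return {g: 30 for g in GROUPS}


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated world of the simulator; defaults match the planted-module
    recovery scenario (500 genes, 50-gene module at r=0.7, 150 samples,
    +2 log2 genotype effects, unit residual noise)."""

    n_genes: int = 500
    n_samples_per_group: dict[str, int] = field(default_factory=_default_group_sizes)
    n_baits: int = 10
    module_size: int = 50
    module_r: float = 0.7
    hif1_panel_size: int = 20
    hif2_panel_size: int = 20
    hif1_effect: float = 2.0
    hif2_effect: float = 2.0
    pseudohypoxia_factor_shift: float = 1.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        reserved = self.module_size + self.hif1_panel_size + self.hif2_panel_size + self.n_baits
        if reserved > self.n_genes:
            raise ValidationError(
                f"module_size + panel sizes + n_baits = {reserved} exceeds n_genes = {self.n_genes}"
            )
        if not 0 <= self.module_r < 1:
            raise ValidationError("module_r must be in [0, 1)")
        for name in ("n_genes", "n_baits", "module_size", "hif1_panel_size", "hif2_panel_size"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        unknown = set(self.n_samples_per_group) - set(GROUPS)
        if unknown:
            raise ValidationError(f"unknown groups {sorted(unknown)}; allowed: {GROUPS}")
        if any(n < 0 for n in self.n_samples_per_group.values()):
            raise ValidationError("sample counts must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted gene roles and sample group assignments."""

    bait_ids: tuple[str, ...]
    module_ids: tuple[str, ...]
    hif1_panel_ids: tuple[str, ...]
    hif2_panel_ids: tuple[str, ...]
    background_ids: tuple[str, ...]
    group_assignments: dict[str, str]

    def __post_init__(self) -> None:
        sets = [set(self.bait_ids), set(self.module_ids), set(self.hif1_panel_ids),
                set(self.hif2_panel_ids), set(self.background_ids)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValidationError("truth gene-id sets must be pairwise disjoint")

    def to_dict(self) -> dict:
        return {
            "bait_ids": list(self.bait_ids),
            "module_ids": list(self.module_ids),
            "hif1_panel_ids": list(self.hif1_panel_ids),
            "hif2_panel_ids": list(self.hif2_panel_ids),
            "background_ids": list(self.background_ids),
            "group_assignments": dict(self.group_assignments),
        }


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, SyntheticTruth]:
    """Draw one dataset from the generative model; deterministic given seed."""
    rng = np.random.default_rng(cfg.seed)

    # Gene ids by role; names reveal the role by design (synthetic data).
    bait_ids = [f"BAIT{i:03d}" for i in range(cfg.n_baits)]
    module_ids = [f"MOD{i:04d}" for i in range(cfg.module_size)]
    hif1_ids = [f"H1T{i:03d}" for i in range(cfg.hif1_panel_size)]
    hif2_ids = [f"H2T{i:03d}" for i in range(cfg.hif2_panel_size)]
    n_bg = cfg.n_genes - cfg.n_baits - cfg.module_size - cfg.hif1_panel_size - cfg.hif2_panel_size
    bg_ids = [f"BG{i:05d}" for i in range(n_bg)]
    gene_ids = bait_ids + module_ids + hif1_ids + hif2_ids + bg_ids

    # Samples in fixed group order for reproducibility.
    sample_ids: list[str] = []
    groups: list[str] = []
    for g in GROUPS:
        n = cfg.n_samples_per_group.get(g, 0)
        sample_ids += [f"{g}_{i:03d}" for i in range(n)]
        groups += [g] * n
    if len(sample_ids) == 0:
        raise ValidationError("at least one sample is required")
    n_samples = len(sample_ids)

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    # Latent hypoxia factor: unit noise plus a pseudohypoxic mean shift,
    # standardized by its theoretical moments so cohort variance is 1 and
    # pairwise module correlations equal module_r exactly.
    grp_arr = np.asarray(groups)
    is_pseudo = np.isin(grp_arr, PSEUDOHYPOXIC_GROUPS)
    p_pseudo = float(is_pseudo.mean())
    shift = cfg.pseudohypoxia_factor_shift
    factor_raw = rng.normal(0.0, 1.0, size=n_samples) + shift * is_pseudo
    factor_sd = np.sqrt(1.0 + shift**2 * p_pseudo * (1.0 - p_pseudo))
    factor = (factor_raw - shift * p_pseudo) / factor_sd
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_samples))

    loading = np.zeros(cfg.n_genes)
    n_factor = cfg.n_baits + cfg.module_size
    if cfg.module_r > 0:
        loading[:n_factor] = np.sqrt(cfg.module_r / (1.0 - cfg.module_r)) * cfg.noise_sd

    effect = np.zeros((cfg.n_genes, n_samples))
    grp = grp_arr
    h1_rows = slice(n_factor, n_factor + cfg.hif1_panel_size)
    h2_rows = slice(n_factor + cfg.hif1_panel_size, n_factor + cfg.hif1_panel_size + cfg.hif2_panel_size)
    effect[h1_rows, np.isin(grp, HIF1_GROUPS)] = cfg.hif1_effect
    effect[h2_rows, np.isin(grp, HIF2_GROUPS)] = cfg.hif2_effect

    values = baseline[:, None] + loading[:, None] * factor[None, :] + effect + noise
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids), scale="log2"
    )

    ann = SampleAnnotation(
        table=pd.DataFrame(
            {"group": groups, "is_tumor": [g != "normal" for g in groups]},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = SyntheticTruth(
        bait_ids=tuple(bait_ids),
        module_ids=tuple(module_ids),
        hif1_panel_ids=tuple(hif1_ids),
        hif2_panel_ids=tuple(hif2_ids),
        background_ids=tuple(bg_ids),
        group_assignments=dict(zip(sample_ids, groups)),
    )
    return matrix, ann, truth


def truth_recall_precision(sig, truth: SyntheticTruth) -> tuple[float, float]:
    """Recall and precision of a derived signature against the planted module.

    Bait genes are excluded from both numerator and denominator: they are
    inputs to the derivation, not discoveries. An empty signature has
    undefined precision, reported as 0.0 with a warning.
    """
    members = set(getattr(sig, "members", sig)) - set(truth.bait_ids)
    module = set(truth.module_ids)
    hits = members & module
    recall = len(hits) / len(module) if module else 0.0
    if not members:
        warnings.warn("empty signature: precision undefined, reporting 0.0")
        return recall, 0.0
    return recall, len(hits) / len(members)
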