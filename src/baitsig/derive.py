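"""Bait-gene co-expression signature derivation.

The core procedure: each bait gene is correlated (Pearson, on log2 values)
against every other gene across all samples; genes with r above a threshold
(default 0.4) and a two-sided p below a threshold (default 0.001) form that
bait's co-expression set; genes present in at least ``min_overlap_k`` of the
bait sets (default 5 of 10) constitute the signature, and at least
``top_overlap_k`` (default 9) its top-ranking subset. "Upregulated" is read
as positive correlation with the bait, which the r-threshold already
enforces when positive.

p-values come from the exact t-transform of r, ``t = r * sqrt((n-2)/(1-r^2))``
with n-2 degrees of freedom — deterministic and standard for co-expression
screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import AnalysisConfig, ExpressionMatrix, GeneSet, ValidationError

logger = logging.getLogger("baitsig")


@dataclass(frozen=True)
class BaitCorrelationSets:
    """Per-bait correlation tables: for each bait, a DataFrame indexed by
    gene with columns ``r``, ``p`` and boolean ``passes``."""

    bait_ids: tuple[str, ...]
    tables: dict[str, pd.DataFrame]

    def passing_set(self, bait_id: str) -> set[str]:
        t = self.tables[bait_id]
        return set(t.index[t["passes"]])

    @property
    def n_baits(self) -> int:
        return len(self.bait_ids)


@dataclass(frozen=True)
class Signature:
    """Named gene list with full derivation provenance.

    Members are ordered by descending overlap count, ties broken
    lexicographically, so that a signature is a reproducible artifact.
    """

    name: str
    members: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)

    def to_geneset(self) -> GeneSet:
        desc = f"baitsig signature (k>={self.provenance.get('overlap_k', '?')})"
        return GeneSet(name=self.name, description=desc, members=frozenset(self.members))


def _pearson_to_gene(values: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson r of ``target`` (1d, n samples) against every row
    of ``values`` (g x n), plus the variance mask of the rows."""
    n = target.shape[0]
    xc = target - target.mean()
    yc = values - values.mean(axis=1, keepdims=True)
    x_ss = float(xc @ xc)
    y_ss = np.einsum("ij,ij->i", yc, yc)
    ok = y_ss > 0
    denom = np.sqrt(x_ss * y_ss, where=ok, out=np.full_like(y_ss, np.nan))
    r = np.where(ok, (yc @ xc) / denom, np.nan)
    return np.clip(r, -1.0, 1.0), ok


def _r_to_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t-transform of r with n-2 df; |r|=1 maps to 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def correlate_bait(
    m: ExpressionMatrix, bait_id: str, cfg: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Correlate one bait against every other gene in the matrix.

    Returns a DataFrame indexed by gene with ``r``, ``p`` and ``passes``
    columns. The bait itself is excluded; constant (zero-variance) genes are
    excluded with a logged warning because r is undefined for them.
    """
    cfg = cfg or AnalysisConfig()
    if m.scale != "log2":
        raise ValidationError("correlation expects a log2-scale matrix; apply to_log_scale first")
    if bait_id not in m.values.index:
        raise ValidationError(f"bait gene {bait_id!r} absent from the matrix")
    n = m.shape[1]
    if n < 4:
        raise ValidationError(f"need >= 4 samples for correlation p-values, got {n}")

    others = m.values.drop(index=bait_id)
    target = m.values.loc[bait_id].to_numpy(dtype=float)
    if np.ptp(target) == 0:
        raise ValidationError(f"bait gene {bait_id!r} has zero variance; r undefined")
    r, ok = _pearson_to_gene(others.to_numpy(dtype=float), target)
    if not ok.all():
        dropped = list(others.index[~ok])
        logger.warning(
            "%d constant gene(s) excluded from correlation with %s: %s%s",
            len(dropped), bait_id, dropped[:5], "..." if len(dropped) > 5 else "",
        )
    r = r[ok]
    genes = others.index[ok]
    p = _r_to_p(r, n)
    if cfg.direction == "positive_only":
        passes = (r > cfg.r_threshold) & (p < cfg.p_threshold)
    else:
        passes = (np.abs(r) > cfg.r_threshold) & (p < cfg.p_threshold)
    return pd.DataFrame({"r": r, "p": p, "passes": passes}, index=genes)


def build_bait_sets(
    m: ExpressionMatrix, baits: GeneSet | list[str], cfg: AnalysisConfig | None = None
) -> BaitCorrelationSets:
    """Apply :func:`correlate_bait` for every bait gene.

    A bait may appear in another bait's passing set; bait genes are removed
    from signature membership downstream, not here.
    """
    cfg = cfg or AnalysisConfig()
    bait_ids = sorted(baits.members) if isinstance(baits, GeneSet) else list(baits)
    if not bait_ids:
        raise ValidationError("bait set is empty")
    missing = [b for b in bait_ids if b not in m.values.index]
    if missing:
        raise ValidationError(f"bait gene(s) absent from matrix: {missing}")
    tables = {b: correlate_bait(m, b, cfg) for b in bait_ids}
    return BaitCorrelationSets(bait_ids=tuple(bait_ids), tables=tables)


def count_overlaps(sets: BaitCorrelationSets) -> pd.Series:
    """Number of bait passing-sets containing each evaluated gene."""
    all_genes: pd.Index | None = None
    for t in sets.tables.values():
        all_genes = t.index if all_genes is None else all_genes.union(t.index)
    counts = pd.Series(0, index=all_genes.sort_values(), dtype=int, name="overlap_count")
    for b in sets.bait_ids:
        passing = sets.tables[b].index[sets.tables[b]["passes"]]
        counts.loc[passing] += 1
    return counts


def assemble_signature(
    overlap_counts: pd.Series,
    cfg: AnalysisConfig | None = None,
    name: str = "signature",
    bait_ids: list[str] | tuple[str, ...] = (),
    overlap_k: int | None = None,
    provenance_extra: dict | None = None,
) -> Signature:
    """Select genes with overlap count >= k (default ``cfg.min_overlap_k``),
    drop baits, and order members by (descending count, gene id)."""
    cfg = cfg or AnalysisConfig()
    k = cfg.min_overlap_k if overlap_k is None else overlap_k
    n_baits = len(bait_ids)
    if n_baits and k > n_baits:
        raise ValidationError(f"overlap threshold k={k} exceeds number of baits ({n_baits})")
    selected = overlap_counts[overlap_counts >= k]
    selected = selected.drop(index=[b for b in bait_ids if b in selected.index])
    order = sorted(selected.index, key=lambda g: (-int(selected.loc[g]), str(g)))
    provenance = {
        "config": cfg.to_dict(),
        "overlap_k": int(k),
        "baits": sorted(map(str, bait_ids)),
        "baits_removed_from_members": True,
        **(provenance_extra or {}),
    }
    return Signature(name=name, members=tuple(order), provenance=provenance)


def correlate_single_gene_scan(
    m: ExpressionMatrix, gene_id: str, cfg: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Transcriptome-wide correlate scan of one gene (same machinery as a
    single bait); the scanned gene is excluded from its own result."""
    return correlate_bait(m, gene_id, cfg)


def signature_correlated_fraction(scan: pd.DataFrame, sig: Signature) -> float:
    """Fraction of signature genes passing a single-gene correlate scan —
    e.g. the share of a pseudohypoxia signature co-expressed with EPAS1."""
    members = [g for g in sig.members if g in scan.index]
    if not members:
        return 0.0
    return float(scan.loc[members, "passes"].mean())


def bait_consistency_rank(
    datasets: list[tuple[ExpressionMatrix, pd.Series]],
    candidates: GeneSet | list[str],
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Rank candidate genes by how consistently they are overexpressed in
    hypoxic samples across datasets.

    Per dataset, a candidate counts as overexpressed when the one-sided
    rank-sum test (hypoxic > non-hypoxic) is significant after BH adjustment
    across the candidates and the median difference is positive. Output is
    sorted by descending consistency count, ties lexicographic.
    """
    cfg = cfg or AnalysisConfig()
    cand = sorted(candidates.members) if isinstance(candidates, GeneSet) else list(candidates)
    if not datasets:
        raise ValidationError("at least one dataset is required")
    counts = pd.Series(0, index=pd.Index(cand, name="gene"), dtype=int)
    for i, (m, hypoxia) in enumerate(datasets):
        if hypoxia is None:
            raise ValidationError(f"dataset {i} lacks hypoxia labels")
        labels = pd.Series(hypoxia).reindex(m.sample_ids)
        if labels.isna().any():
            raise ValidationError(f"dataset {i}: hypoxia labels missing for some samples")
        labels = labels.astype(bool)
        hyp = m.values.loc[:, labels.values]
        non = m.values.loc[:, ~labels.values]
        if hyp.shape[1] == 0 or non.shape[1] == 0:
            raise ValidationError(f"dataset {i}: both hypoxic and non-hypoxic samples required")
        present = [g for g in cand if g in m.values.index]
        pvals, meddiff = [], []
        for g in present:
            res = stats.mannwhitneyu(
                hyp.loc[g], non.loc[g], alternative="greater", method="asymptotic"
            )
            pvals.append(res.pvalue)
            meddiff.append(float(hyp.loc[g].median() - non.loc[g].median()))
        if not present:
            continue
        p_adj = multipletests(pvals, method="fdr_bh")[1]
        for g, pa, md in zip(present, p_adj, meddiff):
            if pa < cfg.p_threshold and md > 0:
                counts.loc[g] += 1
    out = counts.rename("consistency_count").reset_index()
    out = out.sort_values(["consistency_count", "gene"], ascending=[False, True], kind="stable")
    return out.reset_index(drop=True)


class BaitSignatureDeriver(BaseEstimator):
    """Derive a bait co-expression signature from an expression matrix.

    scikit-learn-style estimator: construct with hyperparameters, call
    :meth:`fit` with a log2-scale :class:`~baitsig.io.ExpressionMatrix` (or a
    genes x samples DataFrame assumed to be log2), then read the fitted
    attributes.

    Parameters
    ----------
    baits : list of str or GeneSet
        Bait gene identifiers; all must be present in the fitted matrix.
    r_threshold, p_threshold : float
        Per-bait Pearson filters (defaults 0.4 and 0.001).
    min_overlap_k, top_overlap_k : int
        Bait-set overlap thresholds for the signature (default 5) and its
        top-ranking subset (default 9).
    direction : {"positive_only", "both"}
        Whether only positively correlated genes pass.

    Attributes
    ----------
    bait_sets_ : BaitCorrelationSets
    overlap_counts_ : pandas.Series
    signature_ : Signature
        Members with overlap count >= ``min_overlap_k``.
    top_signature_ : Signature
        Members with overlap count >= ``top_overlap_k``.
    """

    def __init__(
        self,
        baits=None,
        r_threshold: float = 0.4,
        p_threshold: float = 0.001,
        min_overlap_k: int = 5,
        top_overlap_k: int = 9,
        direction: str = "positive_only",
        name: str = "bait-signature",
    ):
        self.baits = baits
        self.r_threshold = r_threshold
        self.p_threshold = p_threshold
        self.min_overlap_k = min_overlap_k
        self.top_overlap_k = top_overlap_k
        self.direction = direction
        self.name = name

    def _config(self) -> AnalysisConfig:
        return AnalysisConfig(
            r_threshold=self.r_threshold,
            p_threshold=self.p_threshold,
            min_overlap_k=self.min_overlap_k,
            top_overlap_k=self.top_overlap_k,
            direction=self.direction,
        )

    def fit(self, X: ExpressionMatrix | pd.DataFrame, y=None) -> "BaitSignatureDeriver":
        if self.baits is None:
            raise ValidationError("baits must be provided")
        m = X if isinstance(X, ExpressionMatrix) else ExpressionMatrix(values=X, scale="log2")
        cfg = self._config()
        self.n_samples_ = m.shape[1]
        self.bait_sets_ = build_bait_sets(m, self.baits, cfg)
        self.overlap_counts_ = count_overlaps(self.bait_sets_)
        extra = {"dataset_fingerprint": m.fingerprint(), "n_samples": m.shape[1]}
        self.signature_ = assemble_signature(
            self.overlap_counts_, cfg, self.name, self.bait_sets_.bait_ids,
            overlap_k=cfg.min_overlap_k, provenance_extra=extra,
        )
        self.top_signature_ = assemble_signature(
            self.overlap_counts_, cfg, f"{self.name}-top", self.bait_sets_.bait_ids,
            overlap_k=cfg.top_overlap_k, provenance_extra=extra,
        )
        return self

    def get_signature(self, overlap_k: int | None = None) -> Signature:
        """Signature at an arbitrary overlap threshold from the fitted counts."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "overlap_counts_")
        if overlap_k is None:
            return self.signature_
        return assemble_signature(
            self.overlap_counts_, self._config(), f"{self.name}-k{overlap_k}",
            self.bait_sets_.bait_ids, overlap_k=overlap_k,
        )


def derive_signature(
    m: ExpressionMatrix, baits: GeneSet | list[str], cfg: AnalysisConfig | None = None,
    name: str = "bait-signature",
) -> Signature:
    """Functional wrapper over :class:`BaitSignatureDeriver`."""
    cfg = cfg or AnalysisConfig()
    bait_ids = sorted(baits.members) if isinstance(baits, GeneSet) else list(baits)
    est = BaitSignatureDeriver(
        baits=bait_ids, r_threshold=cfg.r_threshold, p_threshold=cfg.p_threshold,
        min_overlap_k=cfg.min_overlap_k, top_overlap_k=cfg.top_overlap_k,
        direction=cfg.direction, name=name,
    ).fit(m)
    return est.signature_
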