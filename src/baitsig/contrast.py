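"""Log-z-score transformation and genotype-group contrasts.

Expression values are standardized per gene across *all* samples (tumor and
normal together), so a group's z-distribution is read against the whole
cohort. Each genotype group is then compared to a reference group gene by
gene with a two-sided rank-sum test, BH-corrected across genes within that
comparison; the direction is the sign of the median z difference. A 2x2
Fisher exact test (point-probability two-sided convention) covers
marker-by-genotype tables; larger tables fall back to a chi-squared test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSet, SampleAnnotation, ValidationError
from .derive import Signature

logger = logging.getLogger("baitsig")


@dataclass(frozen=True)
class ZMatrix:
    """Per-gene z-scores of log2 expression across all samples.

    ``constant_genes`` flags genes with zero variance, carried as all-zero
    rows rather than dropped, so gene panels keep their shape.
    """

    values: pd.DataFrame
    constant_genes: tuple[str, ...] = ()
    ddof: int = 1

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def zscore(m: ExpressionMatrix, ddof: int = 1) -> ZMatrix:
    """Standardize each gene row: (x - mean) / sd over all samples."""
    if m.scale != "log2":
        raise ValidationError("z-scores are defined on log2 expression; transform first")
    if m.shape[1] < 2:
        raise ValidationError("z-scores need at least 2 samples")
    vals = m.values.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    const = (sd == 0).ravel() | ~np.isfinite(sd).ravel()
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (vals - mu) / sd_safe
    z[const, :] = 0.0
    if const.any():
        logger.warning("%d constant gene(s) z-scored as zero rows", int(const.sum()))
    return ZMatrix(
        values=pd.DataFrame(z, index=m.values.index, columns=m.values.columns),
        constant_genes=tuple(m.values.index[const]),
        ddof=ddof,
    )


class LogZScaler(BaseEstimator, TransformerMixin):
    """Transformer wrapper over :func:`zscore` for an ExpressionMatrix.

    ``transform`` standardizes each gene against the distribution seen at
    ``fit`` time, so held-out samples are scored on the cohort's scale.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X: ExpressionMatrix, y=None) -> "LogZScaler":
        if X.scale != "log2":
            raise ValidationError("LogZScaler expects a log2-scale matrix")
        if X.shape[1] < 2:
            raise ValidationError("z-scores need at least 2 samples")
        vals = X.values.to_numpy(dtype=float)
        self.mean_ = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=self.ddof)
        self.constant_mask_ = sd == 0
        self.scale_ = np.where(self.constant_mask_, 1.0, sd)
        self.gene_ids_ = list(X.values.index)
        return self

    def transform(self, X: ExpressionMatrix) -> ZMatrix:
        if list(X.values.index) != self.gene_ids_:
            raise ValidationError("gene ids differ from the fitted matrix")
        z = (X.values.to_numpy(dtype=float) - self.mean_[:, None]) / self.scale_[:, None]
        z[self.constant_mask_, :] = 0.0
        return ZMatrix(
            values=pd.DataFrame(z, index=X.values.index, columns=X.values.columns),
            constant_genes=tuple(np.asarray(self.gene_ids_)[self.constant_mask_]),
            ddof=self.ddof,
        )


def contrast_groups(
    z: ZMatrix,
    ann: SampleAnnotation,
    genes: GeneSet | Signature | list[str],
    reference_group: str,
    groups: list[str] | None = None,
    test: str = "mannwhitney",
    multiple_testing: str = "BH",
) -> pd.DataFrame:
    """Per-gene two-sided test of each group vs the reference group on z
    values, BH-corrected across genes within each group comparison.

    Returns a tidy DataFrame with one row per (gene, group): ``n``,
    ``median_z``, ``statistic``, ``p``, ``p_adj``, ``direction``.
    """
    if isinstance(genes, (GeneSet, Signature)):
        gene_ids = sorted(genes.members)
    else:
        gene_ids = list(genes)
    gene_ids = [g for g in gene_ids if g in z.values.index]
    if not gene_ids:
        raise ValidationError("none of the requested genes are in the z-matrix")
    labels = ann.groups.reindex(z.sample_ids)
    known = set(labels.dropna().unique())
    if reference_group not in known:
        raise ValidationError(f"reference group {reference_group!r} not among labels {sorted(known)}")
    if groups is None:
        groups = sorted(g for g in known if g != reference_group)
    unknown = [g for g in groups if g not in known]
    if unknown:
        raise ValidationError(f"unknown group label(s): {unknown}")
    ref_samples = labels.index[labels == reference_group]
    if len(ref_samples) < 2:
        raise ValidationError(f"reference group {reference_group!r} needs n >= 2")

    rows = []
    for grp in groups:
        grp_samples = labels.index[labels == grp]
        if len(grp_samples) < 2:
            raise ValidationError(f"group {grp!r} needs n >= 2")
        pvals = []
        for g in gene_ids:
            a = z.values.loc[g, grp_samples].to_numpy()
            b = z.values.loc[g, ref_samples].to_numpy()
            if test == "mannwhitney":
                res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
                stat, p = float(res.statistic), float(res.pvalue)
            elif test == "welch":
                res = stats.ttest_ind(a, b, equal_var=False)
                stat, p = float(res.statistic), float(res.pvalue)
            else:
                raise ValidationError("test must be 'mannwhitney' or 'welch'")
            med_diff = float(np.median(a) - np.median(b))
            rows.append({
                "gene": g, "group": grp, "n": int(len(grp_samples)),
                "median_z": float(np.median(a)), "statistic": stat, "p": p,
                "direction": int(np.sign(med_diff)),
            })
            pvals.append(p)
        if multiple_testing == "BH":
            adj = multipletests(pvals, method="fdr_bh")[1]
        else:
            adj = pvals
        for r, pa in zip(rows[-len(gene_ids):], adj):
            r["p_adj"] = float(pa)
    return pd.DataFrame(rows, columns=["gene", "group", "n", "median_z", "statistic",
                                       "p", "p_adj", "direction"])


def cluster_signature_genes(
    z: ZMatrix, sig: Signature | GeneSet | list[str], k: int = 2
) -> dict[str, int]:
    """Cut an average-linkage hierarchical clustering of signature gene
    z-rows (correlation distance 1 - r) into k clusters.

    Deterministic given the input; gene input order does not change the
    partition because genes are sorted before clustering.
    """
    members = sorted(sig.members) if isinstance(sig, (Signature, GeneSet)) else sorted(sig)
    members = [g for g in members if g in z.values.index]
    if len(members) < k:
        raise ValidationError(f"need at least k={k} signature genes in the matrix, have {len(members)}")
    if k == 1:
        return {g: 1 for g in members}
    X = z.values.loc[members].to_numpy(dtype=float)
    Z = linkage(X, method="average", metric="correlation")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return dict(zip(members, (int(l) for l in labels)))


def association_test(table) -> tuple[float, float]:
    """Association between two categorical variables from a contingency table.

    2x2 tables get Fisher's exact test (two-sided, sum of point
    probabilities <= observed — the common convention) with the conditional
    odds ratio, reported as NaN when a margin contains a zero. Larger R x C
    tables fall back to the chi-squared test without an odds ratio.
    """
    t = np.asarray(table)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValidationError("contingency table counts must be non-negative")
    if not np.allclose(t, np.round(t)):
        raise ValidationError("contingency table counts must be integers")
    t = t.astype(int)
    if t.sum() == 0:
        raise ValidationError("contingency table is empty")
    if t.shape == (2, 2):
        oddsratio, p = stats.fisher_exact(t, alternative="two-sided")
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            oddsratio = float("nan")
        return float(oddsratio), float(p)
    chi2 = stats.chi2_contingency(t)
    return float("nan"), float(chi2.pvalue)
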