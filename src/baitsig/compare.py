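"""Set-overlap statistics between a derived signature and reference gene sets.

Reports pairwise intersection counts, Jaccard indices, one-sided
hypergeometric over-representation p-values, and the union-coverage
fraction: the share of the query signature found in the union of all
references (the statistic behind "only 6% of the signature appears in any
published hypoxia signature" style claims). The gene universe is a
mandatory, logged parameter — overlap p-values are meaningless without it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSet, ValidationError
from .derive import Signature

logger = logging.getLogger("baitsig")


@dataclass(frozen=True)
class OverlapReport:
    per_reference: pd.DataFrame  # index: reference name; intersection_size, jaccard, hypergeometric_p
    union_coverage: float
    universe_size: int
    query_size: int


def _as_set(obj) -> set[str]:
    if isinstance(obj, Signature):
        return set(obj.members)
    if isinstance(obj, GeneSet):
        return set(obj.members)
    return set(obj)


def _check_universe(universe: set[str], name: str, genes: set[str]) -> None:
    out = genes - universe
    if out:
        raise ValidationError(f"{name}: gene(s) outside the universe: {sorted(out)[:10]}")


def hypergeom_overlap_p(universe_size: int, ref_size: int, query_size: int, overlap: int) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeometric(M=universe,
    K=ref_size, n=query_size)."""
    return float(stats.hypergeom.sf(overlap - 1, universe_size, ref_size, query_size))


def compare_signatures(
    query: Signature | GeneSet | set[str],
    refs: list[GeneSet],
    universe: set[str],
) -> OverlapReport:
    """Exact set arithmetic plus hypergeometric overlap tests vs each
    reference, and union coverage over all references."""
    if not refs:
        raise ValidationError("at least one reference set is required")
    universe = set(universe)
    q = _as_set(query)
    _check_universe(universe, "query", q)
    rows = {}
    union: set[str] = set()
    for ref in refs:
        rmem = set(ref.members)
        _check_universe(universe, f"reference {ref.name!r}", rmem)
        inter = q & rmem
        uni = q | rmem
        rows[ref.name] = {
            "intersection_size": len(inter),
            "jaccard": (len(inter) / len(uni)) if uni else 0.0,
            "hypergeometric_p": hypergeom_overlap_p(len(universe), len(rmem), len(q), len(inter)),
        }
        union |= rmem
    coverage = (len(q & union) / len(q)) if q else 0.0
    logger.info("signature comparison: |universe|=%d, |query|=%d, union coverage=%.3f",
                len(universe), len(q), coverage)
    return OverlapReport(
        per_reference=pd.DataFrame.from_dict(rows, orient="index"),
        union_coverage=coverage,
        universe_size=len(universe),
        query_size=len(q),
    )


def enrich_against_collection(
    query: Signature | GeneSet | set[str],
    collection: list[GeneSet],
    universe: set[str],
    multiple_testing: str = "BH",
) -> pd.DataFrame:
    """One hypergeometric over-representation test per collection set, with
    optional BH adjustment across the collection. Generic stand-in for
    web-service enrichment tools, driven by user GMT files."""
    if not collection:
        raise ValidationError("empty gene-set collection")
    universe = set(universe)
    q = _as_set(query)
    _check_universe(universe, "query", q)
    rows = []
    for gs in collection:
        mem = set(gs.members)
        _check_universe(universe, f"set {gs.name!r}", mem)
        inter = len(q & mem)
        rows.append({
            "set": gs.name,
            "set_size": len(mem),
            "intersection": inter,
            "p": hypergeom_overlap_p(len(universe), len(mem), len(q), inter),
        })
    out = pd.DataFrame(rows)
    if multiple_testing == "BH":
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    elif multiple_testing == "none":
        out["p_adj"] = out["p"]
    else:
        raise ValidationError("multiple_testing must be 'none' or 'BH'")
    return out.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
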