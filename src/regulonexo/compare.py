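"""Comparative analyses downstream of the regulon: cross-TF overlap, COG and
localization tabulation, ortholog conservation, known-site benchmarking, and
growth-rate estimation.

All printed percentages use round-half-up to integers (7/8 -> 88, 34/37 -> 92),
the convention every reported figure follows.
"""
from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .model import GenomeAnnotation, GrowthCurve, Peak

__all__ = [
    "round_half_up_percent", "tf_count_distribution", "overlap_with_tfs",
    "tabulate_annotation", "conservation_matrix", "benchmark_known_sites",
    "max_growth_rate", "relative_rate",
]

log = logging.getLogger("regulonexo.compare")


def round_half_up_percent(count: int, total: int) -> int:
    """Integer percent with exact half-up rounding (87.5 -> 88)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(math.floor(100 * count / total + 0.5))


def tf_count_distribution(membership: pd.DataFrame) -> pd.DataFrame:
    """Histogram of genes by the number of TFs regulating them.

    Rows regulated by zero TFs in the given columns are dropped first (a gene
    belongs to the union only through some regulon). Returns counts and
    round-half-up integer percents per k = 1..#TFs.
    """
    _check_binary(membership)
    per_gene = membership.sum(axis=1)
    per_gene = per_gene[per_gene > 0]
    total = int(per_gene.size)
    ks = range(1, membership.shape[1] + 1)
    counts = [int((per_gene == k).sum()) for k in ks]
    return pd.DataFrame({
        "n_tfs": list(ks),
        "count": counts,
        "percent": [round_half_up_percent(c, total) for c in counts],
    }).set_index("n_tfs")


def overlap_with_tfs(focal_genes, membership: pd.DataFrame, tf_subset
                     ) -> dict[str, int | None]:
    """How many focal genes are regulated by none of ``tf_subset``.

    Genes absent from the membership table count as regulated by zero TFs.
    Returns count, total and round-half-up percent (None on an empty focal set).
    """
    _check_binary(membership)
    focal = list(focal_genes)
    if not focal:
        return {"count": 0, "total": 0, "percent": None}
    cols = [c for c in tf_subset if c in membership.columns]
    zero = 0
    for g in focal:
        if g not in membership.index or membership.loc[g, cols].sum() == 0:
            zero += 1
    return {"count": zero, "total": len(focal),
            "percent": round_half_up_percent(zero, len(focal))}


def tabulate_annotation(genes, annotation: GenomeAnnotation) -> dict:
    """COG-category and localization counts of a gene set, with the membrane
    percent (inner + outer membrane over total, round-half-up)."""
    genes = list(genes)
    cog: dict[str, int] = {}
    loc = {"IM": 0, "OM": 0, "C": 0, "ND": 0}
    for g in genes:
        rec = annotation.genes[g]
        cog[rec.cog] = cog.get(rec.cog, 0) + 1
        loc[rec.localization] = loc.get(rec.localization, 0) + 1
    membrane = loc["IM"] + loc["OM"]
    return {
        "cog": dict(sorted(cog.items())),
        "localization": loc,
        "membrane_percent": round_half_up_percent(membrane, len(genes)) if genes else None,
    }


def conservation_matrix(presence: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-gene fraction of genomes carrying an ortholog, within each taxon group."""
    _check_binary(presence)
    missing = set(presence.columns) - set(groups.index)
    if missing:
        raise ValueError(f"genomes without a group assignment: {sorted(missing)[:5]}")
    out = {}
    for group, genomes in groups.groupby(groups):
        cols = genomes.index
        if len(cols) == 0:
            raise ValueError(f"empty taxon group {group!r}")
        out[group] = presence[cols].mean(axis=1)
    # preserve the first-appearance group order of the mapping
    order = list(dict.fromkeys(groups))
    return pd.DataFrame(out)[order]


def benchmark_known_sites(peaks: list[Peak], known_sites: list[tuple[int, int]]
                          ) -> dict[str, int | None]:
    """Fraction of previously reported binding-site intervals overlapped (>= 1 bp)
    by any called peak."""
    if not known_sites:
        return {"detected": 0, "total": 0, "percent": None}
    detected = 0
    for s, e in known_sites:
        if any(p.start < e and s < p.end for p in peaks):
            detected += 1
    return {"detected": detected, "total": len(known_sites),
            "percent": round_half_up_percent(detected, len(known_sites))}


def max_growth_rate(curve: GrowthCurve, window: int = 4) -> float:
    """Maximum specific growth rate (1/h): the largest least-squares slope of
    ln(OD600) versus time over a sliding window of consecutive points."""
    if window < 3:
        raise ValueError("window must span >= 3 points")
    t, y = curve.time, np.log(curve.od)
    if t.size < window:
        raise ValueError("growth curve shorter than the fitting window")
    best = -np.inf
    for i in range(t.size - window + 1):
        slope = np.polyfit(t[i:i + window], y[i:i + window], 1)[0]
        best = max(best, float(slope))
    return best


def relative_rate(mutant: GrowthCurve, wildtype: GrowthCurve, window: int = 4) -> float:
    """Mutant maximum specific growth rate normalized by wild-type under the
    same condition."""
    if mutant.condition != wildtype.condition:
        raise ValueError("curves must share a condition for normalization")
    return max_growth_rate(mutant, window) / max_growth_rate(wildtype, window)


def _check_binary(df: pd.DataFrame) -> None:
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("table entries must be binary 0/1")
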