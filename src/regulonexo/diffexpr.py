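"""Knockout-versus-wild-type differential expression from integer counts.

Bacterial operon data has no isoforms, so the stage works at the gene level:
library-size-normalized log2 fold changes (KO/WT orientation — deleting an
activator drives its targets to log2FC <= -1, deleting a repressor to >= +1),
an exact conditional binomial test on pooled per-condition counts, and
Benjamini-Hochberg FDR control. A gene is called differentially expressed when
|log2FC| >= 1 and q <= 0.01 under the defaults.

The conditional binomial test assumes Poisson-level noise around the pooled
proportion; with biological overdispersion its p-values are anti-conservative
at high coverage, which is why the significance call combines the FDR with the
fold-change threshold (see docs/methods.md).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import CountTable

__all__ = ["fpkm", "estimate_log2fc", "exact_count_test", "bh_fdr", "call_deg",
           "run_diffexpr"]

log = logging.getLogger("regulonexo.diffexpr")


def fpkm(table: CountTable) -> pd.DataFrame:
    """Fragments per kilobase of gene per million mapped fragments."""
    if (table.lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (table.library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    kb = table.lengths / 1e3
    millions = table.library_sizes / 1e6
    return table.counts.div(kb, axis=0).div(millions, axis=1)


def _size_factors(table: CountTable) -> pd.Series:
    libs = table.library_sizes.astype(float)
    return libs / np.exp(np.log(libs).mean())


def estimate_log2fc(table: CountTable, pseudocount: float = 1.0) -> pd.Series:
    """log2((mean normalized KO + pc) / (mean normalized WT + pc)).

    Normalization divides each sample by its library-size factor (library size
    over the geometric mean of library sizes).
    """
    norm = table.counts.div(_size_factors(table), axis=1)
    ko = norm[table.samples("KO")].mean(axis=1)
    wt = norm[table.samples("WT")].mean(axis=1)
    return np.log2((ko + pseudocount) / (wt + pseudocount)).rename("log2fc")


def exact_count_test(table: CountTable) -> pd.Series:
    """Two-sided exact conditional binomial test per gene.

    Counts are pooled within condition; given total t = a + b (a pooled KO,
    b pooled WT) the p-value is the two-sided minimum-likelihood tail of
    Binomial(t, pi0) with pi0 the KO share of the total library mass.
    """
    ko_s, wt_s = table.samples("KO"), table.samples("WT")
    ko_mass = float(table.library_sizes[ko_s].sum())
    total_mass = float(table.library_sizes.sum())
    pi0 = ko_mass / total_mass
    a = table.counts[ko_s].sum(axis=1).to_numpy()
    b = table.counts[wt_s].sum(axis=1).to_numpy()
    pvals = np.ones(a.size)
    for i, (ai, ti) in enumerate(zip(a, a + b)):
        if ti == 0:
            continue
        pvals[i] = stats.binomtest(int(ai), int(ti), pi0).pvalue
    return pd.Series(pvals, index=table.counts.index, name="pvalue")


def bh_fdr(pvalues: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up q-values, reported in input order."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return pvalues
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(arr, method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(q, index=pvalues.index, name="qvalue")
    return q


def call_deg(results: pd.DataFrame, lfc_min: float = 1.0,
             fdr_max: float = 0.01) -> pd.DataFrame:
    """Flag genes with |log2FC| >= ``lfc_min`` and q <= ``fdr_max``."""
    out = results.copy()
    out["significant"] = (out["log2fc"].abs() >= lfc_min) & (out["qvalue"] <= fdr_max)
    return out


def run_diffexpr(table: CountTable, lfc_min: float = 1.0, fdr_max: float = 0.01,
                 pseudocount: float = 1.0) -> pd.DataFrame:
    """Full stage: log2FC, exact test, BH, significance call. Deterministic."""
    res = pd.DataFrame({
        "log2fc": estimate_log2fc(table, pseudocount),
        "pvalue": exact_count_test(table),
    })
    res["qvalue"] = bh_fdr(res["pvalue"])
    res = call_deg(res, lfc_min=lfc_min, fdr_max=fdr_max)
    log.info("diffexpr: %d genes, %d significant (|lfc|>=%.1f, q<=%.2g)",
             len(res), int(res["significant"].sum()), lfc_min, fdr_max)
    return res
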