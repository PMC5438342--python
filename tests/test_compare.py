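"""Comparative-analysis tests: overlap distributions, annotation tabulation,
conservation fractions, known-site benchmark, growth rates."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import regulonexo as rx
from regulonexo.compare import (
    benchmark_known_sites, conservation_matrix, max_growth_rate,
    overlap_with_tfs, relative_rate, round_half_up_percent,
    tabulate_annotation, tf_count_distribution,
)
from regulonexo.model import GrowthCurve, Peak


# ------------------------------------------------------------ rounding

@pytest.mark.parametrize("count,total,expected", [
    (7, 8, 88),        # 87.5 rounds up
    (34, 37, 92),
    (25, 37, 68),
    (206, 243, 85),
    (33, 243, 14),     # 13.58: half-up gives 14
    (18, 37, 49),
    (1, 8, 13),        # 12.5 rounds up
])
def test_round_half_up_percent(count, total, expected):
    assert round_half_up_percent(count, total) == expected


# ------------------------------------------------------------ TF counts

def build_membership(n_singles=206, n_doubles=33, n_triples=4, n_tfs=8):
    tfs = [f"T{i}" for i in range(n_tfs)]
    rows = {}
    rng = np.random.default_rng(0)
    i = 0
    for n, k in ((n_singles, 1), (n_doubles, 2), (n_triples, 3)):
        for _ in range(n):
            row = np.zeros(n_tfs, dtype=int)
            row[rng.choice(n_tfs, size=k, replace=False)] = 1
            rows[f"g{i}"] = row
            i += 1
    return pd.DataFrame(rows, index=tfs).T


def test_union_distribution_fractions():
    """A 206/33/4 composition of 243 genes gives 85% singly regulated; the
    doubly regulated 33/243 = 13.58% renders as 14 under half-up rounding."""
    dist = tf_count_distribution(build_membership())
    assert dist["count"].sum() == 243
    assert dist.loc[1, "count"] == 206 and dist.loc[1, "percent"] == 85
    assert dist.loc[2, "count"] == 33 and dist.loc[2, "percent"] == 14
    assert abs(dist["percent"].sum() - 100) <= 1


def test_distribution_all_genes_all_tfs():
    mem = pd.DataFrame(1, index=[f"g{i}" for i in range(10)],
                       columns=[f"T{i}" for i in range(8)])
    dist = tf_count_distribution(mem)
    assert dist.loc[8, "count"] == 10 and dist.loc[8, "percent"] == 100
    assert dist.loc[1:7, "count"].sum() == 0


def test_generated_membership_distribution(paper_ds):
    dist = tf_count_distribution(paper_ds.membership[paper_ds.stress_tfs])
    assert dist["count"].sum() == 243
    assert dist.loc[1, "count"] == 206 and dist.loc[1, "percent"] == 85
    assert dist.loc[2, "count"] == 33


# ------------------------------------------------------------ overlaps

def regulon_gene_list(ds):
    tids = {s.tu_id for s in ds.truth.signal_sites}
    return [g for t in sorted(tids) for g in ds.annotation.tus[t].gene_ids]


def test_focal_overlap_with_stress_tfs(paper_ds):
    genes = regulon_gene_list(paper_ds)
    subset = [t for t in paper_ds.stress_tfs if t != paper_ds.focal_tf]
    res = overlap_with_tfs(genes, paper_ds.membership, subset)
    assert (res["count"], res["total"], res["percent"]) == (34, 37, 92)


def test_focal_overlap_with_all_tfs(paper_ds):
    genes = regulon_gene_list(paper_ds)
    subset = [c for c in paper_ds.membership.columns if c != paper_ds.focal_tf]
    res = overlap_with_tfs(genes, paper_ds.membership, subset)
    assert (res["count"], res["total"], res["percent"]) == (18, 37, 49)


def test_overlap_counts_absent_genes_as_unregulated():
    mem = pd.DataFrame({"A": [1], "B": [0]}, index=["g0"])
    res = overlap_with_tfs(["g0", "ghost"], mem, ["B"])
    assert res["count"] == 2 and res["percent"] == 100


def test_overlap_empty_focal_set():
    mem = pd.DataFrame({"A": [1]}, index=["g0"])
    assert overlap_with_tfs([], mem, ["A"])["percent"] is None


# ------------------------------------------------------------ annotation

def test_membrane_percent_from_planted_localizations(paper_ds):
    genes = regulon_gene_list(paper_ds)
    tab = tabulate_annotation(genes, paper_ds.annotation)
    loc = tab["localization"]
    assert loc["IM"] == 18 and loc["OM"] == 7
    assert tab["membrane_percent"] == 68
    assert sum(loc.values()) == len(genes)
    assert len(tab["cog"]) == 13


def test_membrane_percent_zero_when_cytosolic(small_ds):
    genes = list(small_ds.annotation.genes)[:4]
    for g in genes:
        small_ds.annotation.genes[g].localization = "C"
    tab = tabulate_annotation(genes, small_ds.annotation)
    assert tab["membrane_percent"] == 0


# ------------------------------------------------------------ conservation

def test_conservation_fraction_definition():
    genomes = [f"e{i}" for i in range(13)]
    groups = pd.Series(["Escherichia"] * 13, index=genomes)
    row = np.zeros(13, dtype=int)
    row[:10] = 1
    presence = pd.DataFrame([row, np.zeros(13, dtype=int)],
                            index=["gA", "gB"], columns=genomes)
    mat = conservation_matrix(presence, groups)
    assert mat.loc["gA", "Escherichia"] == pytest.approx(10 / 13)
    assert mat.loc["gB", "Escherichia"] == 0.0


def test_tf_more_conserved_than_regulon(paper_ds):
    mat = conservation_matrix(paper_ds.orthologs, paper_ds.genome_groups)
    tf_mean = mat.loc[paper_ds.truth.tf_gene].mean()
    gene_means = mat.drop(index=paper_ds.truth.tf_gene).mean(axis=1)
    assert tf_mean > gene_means.mean()


def test_conservation_invariant_under_column_permutation(paper_ds):
    rng = np.random.default_rng(12)
    presence = paper_ds.orthologs
    groups = paper_ds.genome_groups
    permuted_cols = []
    for _, genomes in groups.groupby(groups, sort=False):
        cols = list(genomes.index)
        rng.shuffle(cols)
        permuted_cols.extend(cols)
    shuffled = presence[permuted_cols]
    pd.testing.assert_frame_equal(
        conservation_matrix(shuffled, groups), conservation_matrix(presence, groups)
    )


def test_empty_group_rejected():
    presence = pd.DataFrame({"g1": [1]}, index=["gA"])
    presence.columns = ["g1"]
    groups = pd.Series(["X"], index=["g1"])
    with pytest.raises(ValueError):
        conservation_matrix(presence, pd.Series([], dtype=object, name="group"))


# ------------------------------------------------------------ benchmark

def test_known_site_benchmark_printed_case():
    peaks = [Peak(i * 100, i * 100 + 21, i * 100, i * 100 + 20) for i in range(7)]
    known = [(i * 100 + 5, i * 100 + 15) for i in range(7)] + [(5000, 5020)]
    res = benchmark_known_sites(peaks, known)
    assert (res["detected"], res["total"], res["percent"]) == (7, 8, 88)


def test_benchmark_no_known_sites():
    assert benchmark_known_sites([], [])["percent"] is None


def test_benchmark_all_detected():
    peaks = [Peak(0, 50, 0, 49)]
    assert benchmark_known_sites(peaks, [(10, 20), (30, 40)])["percent"] == 100


def test_benchmark_monotone_in_sn_threshold(paper_ds):
    known = [(s.start, s.end) for s in paper_ds.truth.known_sites]
    detected = []
    for sn_min in (6.0, 1.0, 0.5):
        cfg = rx.RunConfig(seed=42, peak_sn_min=sn_min)
        peaks = rx.call_peaks(paper_ds.chip, cfg)
        detected.append(benchmark_known_sites(peaks, known)["detected"])
    assert detected == sorted(detected)


# ------------------------------------------------------------ growth

def test_growth_rate_exact_on_exponential():
    t = np.arange(0, 5, 0.5)
    curve = GrowthCurve(t, 0.02 * np.exp(0.6 * t), "WT", "normal")
    assert max_growth_rate(curve) == pytest.approx(0.6, abs=1e-9)


def test_relative_rate_identity():
    t = np.arange(0, 5, 0.5)
    a = GrowthCurve(t, 0.02 * np.exp(0.6 * t), "WT", "osmotic")
    b = GrowthCurve(t, 0.02 * np.exp(0.6 * t), "mut", "osmotic")
    assert relative_rate(b, a) == pytest.approx(1.0)


def test_growth_rate_on_logistic_curve():
    r, K, od0 = 0.8, 1.5, 0.005
    t = np.arange(0, 12, 0.25)
    od = K / (1 + (K / od0 - 1) * np.exp(-r * t))
    est = max_growth_rate(GrowthCurve(t, od, "WT", "normal"))
    assert est == pytest.approx(r, rel=0.05)


def test_nonincreasing_time_rejected():
    with pytest.raises(ValueError):
        GrowthCurve(np.array([0, 1, 1, 2, 3.0]), np.ones(5), "WT", "normal")


def test_condition_mismatch_rejected():
    t = np.arange(0, 5, 0.5)
    a = GrowthCurve(t, 0.02 * np.exp(0.6 * t), "WT", "normal")
    b = GrowthCurve(t, 0.02 * np.exp(0.6 * t), "mut", "osmotic")
    with pytest.raises(ValueError):
        relative_rate(b, a)


def test_generated_growth_rates(paper_ds):
    curves = {(c.strain, c.condition): c for c in paper_ds.growth}
    rel = relative_rate(curves[("repressedOE", "osmotic")],
                        curves[("WT", "osmotic")])
    assert rel == pytest.approx(0.6, abs=0.1)
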