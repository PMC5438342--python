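"""Peak-caller unit and property tests: normalization, border pairing,
signal-to-noise, replicate reproducibility and filtering."""
from __future__ import annotations

import numpy as np
import pytest

import regulonexo as rx
from regulonexo.model import BorderProfile, Peak
from regulonexo.peak_calling import (
    call_candidate_peaks, filter_peaks, normalize_depth, reproducible_peaks,
    signal_to_noise,
)


def make_profile(length, spikes, strand="+", label="rep1", background=0.0):
    counts = np.full(length, background, dtype=float)
    for pos, value in spikes:
        counts[pos] = value
    return BorderProfile(strand, counts, int(counts.sum()), label)


# ------------------------------------------------------------ normalization

def test_normalize_identity_at_one_million():
    prof = BorderProfile("+", np.ones(1_000_000), 1_000_000, "rep1")
    out = normalize_depth(prof)
    assert np.allclose(out.counts, prof.counts)


def test_normalize_scales_by_library_size():
    counts = np.zeros(100)
    counts[10] = 4
    prof = BorderProfile("+", counts, 2_000_000, "rep1")
    assert normalize_depth(prof).counts[10] == pytest.approx(2.0)


def test_normalize_zero_library_rejected():
    prof = BorderProfile("+", np.zeros(10), 0, "rep1")
    with pytest.raises(ValueError):
        normalize_depth(prof)


def test_normalized_total_mass(paper_ds):
    for fwd, rev in paper_ds.chip.values():
        assert normalize_depth(fwd).counts.sum() == pytest.approx(1e6)
        assert normalize_depth(rev).counts.sum() == pytest.approx(1e6)


# ------------------------------------------------------------ candidates

def test_uniform_profile_yields_no_candidates():
    fwd = normalize_depth(BorderProfile("+", np.full(5000, 3.0), 15000, "rep1"))
    rev = normalize_depth(BorderProfile("-", np.full(5000, 3.0), 15000, "rep1"))
    assert call_candidate_peaks(fwd, rev) == []


def test_two_sites_pair_without_crosstalk():
    """Two planted border pairs 5 kb apart pair up site-locally: the pairing
    equals the brute-force nearest-downstream assignment."""
    L = 20_000
    fwd = make_profile(L, [(1000, 500), (6000, 500)], "+")
    rev = make_profile(L, [(1020, 500), (6020, 500)], "-")
    nf, nr = normalize_depth(fwd), normalize_depth(rev)
    peaks = call_candidate_peaks(nf, nr)
    assert [(p.fwd_border, p.rev_border) for p in peaks] == [(1000, 1020), (6000, 6020)]
    # brute-force oracle: each fwd border with its nearest in-range rev border
    expected = []
    for f in (1000, 6000):
        downstream = [r for r in (1020, 6020) if f <= r <= f + 100]
        if downstream:
            expected.append((f, min(downstream)))
    assert [(p.fwd_border, p.rev_border) for p in peaks] == expected


def test_unpaired_borders_discarded():
    L = 10_000
    fwd = make_profile(L, [(1000, 500)], "+")
    rev = make_profile(L, [(1500, 500)], "-")   # 500 bp away: beyond max span
    peaks = call_candidate_peaks(normalize_depth(fwd), normalize_depth(rev))
    assert peaks == []


def test_zero_noise_single_site_borders(small_ds):
    """A single zero-noise site yields exactly one candidate with borders at
    the footprint edges (+-2 bp jitter)."""
    site = small_ds.truth.signal_sites[0]
    chip = rx.simulate_chipexo([site], small_ds.annotation.genome_length,
                               depth=10_000, noise=0.0, seed=2, labels=("rep1",))
    fwd, rev = (normalize_depth(p) for p in chip["rep1"])
    peaks = call_candidate_peaks(fwd, rev)
    assert len(peaks) == 1
    assert abs(peaks[0].fwd_border - site.start) <= 2
    assert abs(peaks[0].rev_border - (site.end - 1)) <= 2


# ------------------------------------------------------------ S/N

def test_sn_equals_one_on_flat_region():
    fwd = BorderProfile("+", np.full(1000, 5.0), 5000, "rep1", normalized=True)
    rev = BorderProfile("-", np.full(1000, 5.0), 5000, "rep1", normalized=True)
    peak = Peak(100, 120, 100, 119)
    assert signal_to_noise(peak, fwd, rev) == pytest.approx(1.0)


def test_sn_ratio_definition():
    counts = np.full(1000, 10.0)
    counts[100:120] = 50.0
    fwd = BorderProfile("+", counts / 2, 1, "rep1", normalized=True)
    rev = BorderProfile("-", counts / 2, 1, "rep1", normalized=True)
    peak = Peak(100, 120, 100, 119)
    genome_mean = counts.mean()
    assert signal_to_noise(peak, fwd, rev) == pytest.approx(50.0 / genome_mean)


def test_sn_zero_density_rejected():
    fwd = BorderProfile("+", np.zeros(100), 0, "rep1", normalized=True)
    rev = BorderProfile("-", np.zeros(100), 0, "rep1", normalized=True)
    with pytest.raises(ValueError):
        signal_to_noise(Peak(10, 20, 10, 19), fwd, rev)


def test_all_final_peaks_meet_sn_threshold(paper_peaks):
    assert all(p.sn >= 1.0 for p in paper_peaks)


# ------------------------------------------------------------ reproducibility

def test_identical_peaks_merge_idempotently():
    p = [Peak(100, 121, 100, 120, sn=5.0)]
    q = [Peak(100, 121, 100, 120, sn=3.0)]
    merged = reproducible_peaks(p, q)
    assert len(merged) == 1
    assert (merged[0].start, merged[0].end) == (100, 121)
    assert merged[0].sn == pytest.approx(4.0)
    assert merged[0].support == "both"


def test_replicate_only_peak_dropped():
    assert reproducible_peaks([Peak(100, 121, 100, 120)], []) == []


def _random_peaks(rng, n, span=1000):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, span))
        e = s + int(rng.integers(5, 40))
        out.append(Peak(s, e, s, e - 1, sn=float(rng.uniform(1, 10))))
    return out


def test_reproducible_matches_quadratic_oracle():
    """On random instances the merge equals the brute-force all-pairs overlap
    computation, and is symmetric in its arguments."""
    rng = np.random.default_rng(11)
    for _ in range(100):
        a = _random_peaks(rng, int(rng.integers(0, 8)))
        b = _random_peaks(rng, int(rng.integers(0, 8)))
        got = {(p.start, p.end) for p in reproducible_peaks(a, b)}
        swapped = {(p.start, p.end) for p in reproducible_peaks(b, a)}
        oracle = {
            (min(p.start, q.start), max(p.end, q.end))
            for p in a for q in b
            if p.start < q.end and q.start < p.end
        }
        assert got == oracle == swapped


# ------------------------------------------------------------ filtering

def test_low_sn_peak_removed():
    peaks = [Peak(10, 30, 10, 29, sn=0.9), Peak(50, 70, 50, 69, sn=5.0)]
    kept = filter_peaks(peaks, mock_peaks=[], sn_min=1.0)
    assert [(p.start, p.end) for p in kept] == [(50, 70)]


def test_mock_overlap_removed():
    peaks = [Peak(10, 30, 10, 29, sn=5.0), Peak(100, 130, 100, 129, sn=5.0)]
    mock = [Peak(25, 40, 25, 39, sn=2.0)]
    kept = filter_peaks(peaks, mock, sn_min=1.0)
    assert [(p.start, p.end) for p in kept] == [(100, 130)]


def test_planted_artifact_removed_end_to_end(paper_ds, paper_peaks):
    artifacts = [s for s in paper_ds.truth.sites if s.is_artifact]
    assert artifacts
    for a in artifacts:
        assert not any(p.start < a.end and a.start < p.end for p in paper_peaks)


def test_peak_count_monotone_in_sn_min(paper_ds):
    cfg = rx.RunConfig(seed=42)
    counts = []
    for sn_min in (0.5, 1.0, 3.0, 6.0):
        cfg.peak_sn_min = sn_min
        counts.append(len(rx.call_peaks(paper_ds.chip, cfg)))
    assert counts == sorted(counts, reverse=True)


def test_peak_count_monotone_in_k(small_ds):
    counts = []
    for k in (2.0, 3.0, 5.0, 50.0):
        cfg = rx.RunConfig(seed=1, peak_k=k)
        counts.append(len(rx.call_peaks(small_ds.chip, cfg)))
    assert counts == sorted(counts, reverse=True)
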