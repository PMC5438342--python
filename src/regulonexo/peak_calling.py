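"""Reproducible binding-peak calling from strand-specific ChIP-exo border profiles.

Lambda-exonuclease digestion leaves sharp 5' read borders flanking the bound
footprint: forward-strand borders pile up at its left edge, reverse-strand
borders at its right edge. The caller finds candidate borders as thresholded
local maxima on each strand, pairs each forward border with the nearest
downstream reverse border, keeps peaks reproduced in both biological
duplicates, and removes low signal-to-noise peaks and peaks shared with the
mock immunoprecipitation. The whole stage is deterministic given the profiles.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import uniform_filter1d

from .config import RunConfig
from .model import BorderProfile, Peak

__all__ = [
    "normalize_depth", "call_candidate_peaks", "signal_to_noise",
    "reproducible_peaks", "filter_peaks", "call_peaks",
]

log = logging.getLogger("regulonexo.peaks")


def normalize_depth(profile: BorderProfile) -> BorderProfile:
    """Rescale a raw border profile to reads-per-million (RPM)."""
    if profile.library_size <= 0:
        raise ValueError("library size must be positive for depth normalization")
    if profile.normalized:
        return profile
    scaled = profile.counts * (1e6 / profile.library_size)
    return BorderProfile(profile.strand, scaled, profile.library_size,
                         profile.label, normalized=True)


def _candidate_borders(values: np.ndarray, k: float, bg_window: int) -> np.ndarray:
    """Positions that are local maxima exceeding ``k`` x local background.

    Local background is the mean over a centered ``bg_window``, floored at the
    genome-wide uniform density 1e6 / genome length (RPM units). Plateau ties
    keep the leftmost position so each border is reported once.
    """
    n = values.size
    floor = 1e6 / n
    local_bg = uniform_filter1d(values, size=bg_window, mode="wrap")
    threshold = k * np.maximum(local_bg, floor)
    left = np.empty(n)
    right = np.empty(n)
    left[0], left[1:] = -np.inf, values[:-1]
    right[-1], right[:-1] = -np.inf, values[1:]
    is_max = (values > 0) & (values > left) & (values >= right)
    return np.flatnonzero(is_max & (values >= threshold))


def call_candidate_peaks(fwd: BorderProfile, rev: BorderProfile,
                         config: RunConfig | None = None) -> list[Peak]:
    """Call candidate peaks from one library's normalized strand pair.

    Each forward border pairs with the nearest downstream reverse border within
    ``peak_max_span`` bp; the peak interval is ``[fwd_border, rev_border + 1)``.
    Unpaired borders are discarded.
    """
    config = config or RunConfig()
    if not (fwd.normalized and rev.normalized):
        raise ValueError("profiles must be depth-normalized before peak calling")
    if fwd.genome_length != rev.genome_length:
        raise ValueError("strand profiles cover different genome lengths")
    fwd_borders = _candidate_borders(fwd.counts, config.peak_k, config.peak_bg_window)
    rev_borders = _candidate_borders(rev.counts, config.peak_k, config.peak_bg_window)
    peaks: list[Peak] = []
    if fwd_borders.size and rev_borders.size:
        idx = np.searchsorted(rev_borders, fwd_borders, side="left")
        for f, i in zip(fwd_borders, idx):
            if i == rev_borders.size:
                continue
            r = rev_borders[i]
            if r - f <= config.peak_max_span:
                peaks.append(Peak(int(f), int(r) + 1, int(f), int(r),
                                  support=fwd.label))
    for p in peaks:
        p.sn = signal_to_noise(p, fwd, rev)
    log.info("%s: %d fwd / %d rev candidate borders -> %d candidate peaks",
             fwd.label, fwd_borders.size, rev_borders.size, len(peaks))
    return peaks


def signal_to_noise(peak: Peak, fwd: BorderProfile, rev: BorderProfile) -> float:
    """Mean combined-strand border density in the peak over the genome-wide mean."""
    combined = fwd.counts + rev.counts
    genome_mean = combined.mean()
    if genome_mean <= 0:
        raise ValueError("zero genome-wide border density")
    return float(combined[peak.start:peak.end].mean() / genome_mean)


def reproducible_peaks(peaks_rep1: list[Peak], peaks_rep2: list[Peak]) -> list[Peak]:
    """Merge peak pairs that overlap by >= 1 bp across the two duplicates.

    The merged peak takes the union interval, the outermost borders, and the
    mean of the two replicate S/N values. Duplicate merged intervals (one peak
    overlapping several in the other replicate yielding the same union) are
    reported once. Symmetric in its two arguments.
    """
    merged: dict[tuple[int, int], Peak] = {}
    a = sorted(peaks_rep1, key=lambda p: p.start)
    b = sorted(peaks_rep2, key=lambda p: p.start)
    for p in a:
        for q in b:
            if q.start >= p.end:
                break
            if p.overlaps(q):
                start, end = min(p.start, q.start), max(p.end, q.end)
                key = (start, end)
                if key not in merged:
                    sn = None
                    if p.sn is not None and q.sn is not None:
                        sn = 0.5 * (p.sn + q.sn)
                    merged[key] = Peak(start, end,
                                       min(p.fwd_border, q.fwd_border),
                                       max(p.rev_border, q.rev_border),
                                       sn=sn, support="both")
    out = [merged[k] for k in sorted(merged)]
    for i, p in enumerate(out):
        p.name = f"peak{i + 1}"
    return out


def filter_peaks(peaks: list[Peak], mock_peaks: list[Peak],
                 sn_min: float = 1.0) -> list[Peak]:
    """Drop peaks with S/N below ``sn_min`` or overlapping any mock-IP peak."""
    kept = []
    for p in peaks:
        if p.sn is not None and p.sn < sn_min:
            continue
        if any(p.overlaps(m) for m in mock_peaks):
            continue
        kept.append(p)
    log.info("filter: %d -> %d peaks (sn_min=%.2f, %d mock peaks)",
             len(peaks), len(kept), sn_min, len(mock_peaks))
    return kept


def call_peaks(chip: dict[str, tuple[BorderProfile, BorderProfile]],
               config: RunConfig | None = None) -> list[Peak]:
    """Full chain: normalize -> candidates per duplicate -> reproducibility ->
    S/N and mock-IP filters. ``chip`` maps rep1/rep2/mock to (fwd, rev) profiles."""
    config = config or RunConfig()
    per_label: dict[str, list[Peak]] = {}
    for label in ("rep1", "rep2", "mock"):
        fwd, rev = chip[label]
        per_label[label] = call_candidate_peaks(
            normalize_depth(fwd), normalize_depth(rev), config
        )
    reproduced = reproducible_peaks(per_label["rep1"], per_label["rep2"])
    final = filter_peaks(reproduced, per_label["mock"], config.peak_sn_min)
    for i, p in enumerate(final):
        p.name = f"peak{i + 1}"
    log.info("called %d reproducible peaks after filters", len(final))
    return final
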