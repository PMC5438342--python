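"""Binding-motif discovery from peak sequences.

The finder runs expectation-maximization over a ZOOPS model (zero or one motif
occurrence per sequence, either strand, fixed occurrence prior) with a 0-order
background, multiple deterministic restarts, and a Dirichlet pseudocount in the
M-step. The tracked objective is the MAP objective (data log-likelihood plus
the Dirichlet log-prior term), which EM makes non-decreasing; restarts are
ranked by their final objective. A motif found on double-stranded input is only
identified up to reverse complement.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .model import PWM, Peak

__all__ = [
    "extract_peak_sequences", "discover_motif", "iupac_consensus", "scan_pwm",
    "reverse_complement", "MotifResult",
]

log = logging.getLogger("regulonexo.motif")

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# base sets for IUPAC codes, and the reverse lookup used when rendering
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_CODE_OF_SET = {v: k for k, v in IUPAC_SETS.items()}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_peak_sequences(peaks: list[Peak], genome: str, flank: int = 10) -> list[str]:
    """One uppercase sequence per peak: the peak interval plus ``flank`` bp each
    side, clipped at the genome ends."""
    out = []
    for p in peaks:
        s = max(0, p.start - flank)
        e = min(len(genome), p.end + flank)
        out.append(genome[s:e].upper())
    return out


@dataclass
class MotifResult:
    pwm: PWM
    sites: list[tuple[int, str] | None]     # per-sequence best (offset, strand)
    objective: float                        # final MAP objective of best restart
    objective_trace: list[float]            # per-iteration trace of best restart
    restart: int
    all_final_objectives: list[float] = field(default_factory=list)


def _encode(sequences: list[str], width: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad-encode sequences into an offset tensor.

    Returns ``idx`` (n, K, w) base indices of each window, ``valid`` (n, K)
    offset mask, and ``lengths`` (n,).
    """
    n = len(sequences)
    lengths = np.array([len(s) for s in sequences])
    kmax = int(lengths.max()) - width + 1
    idx = np.zeros((n, kmax, width), dtype=np.int8)
    valid = np.zeros((n, kmax), dtype=bool)
    for i, s in enumerate(sequences):
        codes = np.array([_BASE_INDEX[c] for c in s], dtype=np.int8)
        k = len(s) - width + 1
        if k <= 0:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, width)
        idx[i, :k] = windows
        valid[i, :k] = True
    return idx, valid, lengths


def discover_motif(sequences: list[str], width: int = 10, restarts: int = 20,
                   max_iter: int = 200, seed: int = 0, prior: float = 0.9,
                   pseudocount: float = 0.25, tol: float = 1e-8) -> MotifResult:
    """EM motif discovery over the double-stranded ZOOPS model.

    Restart ``r`` initializes its matrix from one window drawn (seeded by
    ``(seed, r)``) from the lexicographically sorted pool of all windows, so
    the result is invariant under permutation of the input sequences; ties
    between restarts break toward the lower restart index.
    """
    sequences = [s.upper() for s in sequences]
    if len(sequences) < 2:
        raise ValueError("motif discovery needs >= 2 sequences")
    usable = [s for s in sequences if len(s) >= width]
    if not usable:
        raise ValueError("all sequences shorter than the motif width")

    idx, valid, lengths = _encode(sequences, width)
    idx_rc = (3 - idx)[:, :, ::-1]          # window read as its reverse complement
    n, kmax, _ = idx.shape
    n_offsets = np.maximum(lengths - width + 1, 0)

    # strand-symmetric 0-order background from the input composition
    base_counts = np.bincount(
        np.concatenate([[ _BASE_INDEX[c] for c in s] for s in sequences]), minlength=4
    ).astype(float)
    base_counts = base_counts + base_counts[::-1]    # A<->T, C<->G symmetrized
    background = base_counts / base_counts.sum()
    log_bg = np.log(background)

    # per-window background log-probability and per-sequence whole-sequence term
    win_bg = log_bg[idx].sum(axis=2)
    seq_bg = np.array([log_bg[[_BASE_INDEX[c] for c in s]].sum() for s in sequences])

    with np.errstate(divide="ignore"):
        log_prior_site = np.where(
            valid, np.log(prior) - np.log(np.maximum(2 * n_offsets, 1))[:, None], -np.inf
        )
    log_prior_none = np.log1p(-prior) if prior < 1 else -np.inf

    pool = sorted("".join(_BASES[b] for b in idx[i, j]) for i in range(n)
                  for j in range(kmax) if valid[i, j])

    def run_em(mat: np.ndarray) -> tuple[np.ndarray, list[float]]:
        trace: list[float] = []
        for _ in range(max_iter):
            log_mat = np.log(mat)
            score_f = sum(log_mat[m][idx[:, :, m]] for m in range(width))
            score_r = sum(log_mat[m][idx_rc[:, :, m]] for m in range(width))
            lw_f = log_prior_site + score_f - win_bg
            lw_r = log_prior_site + score_r - win_bg
            stacked = np.concatenate(
                [np.full((n, 1), log_prior_none), lw_f, lw_r], axis=1
            )
            norm = logsumexp(stacked, axis=1)
            objective = float((norm + seq_bg).sum()
                              + pseudocount * np.log(mat).sum())
            resp = np.exp(stacked - norm[:, None])
            r_f, r_r = resp[:, 1:kmax + 1], resp[:, kmax + 1:]
            counts = np.full((width, 4), pseudocount)
            for m in range(width):
                counts[m] += np.bincount(idx[:, :, m].ravel(),
                                         weights=r_f.ravel(), minlength=4)
                counts[m] += np.bincount(idx_rc[:, :, m].ravel(),
                                         weights=r_r.ravel(), minlength=4)
            mat = counts / counts.sum(axis=1, keepdims=True)
            if trace and objective - trace[-1] < tol * (abs(trace[-1]) + 1e-3):
                trace.append(objective)
                break
            trace.append(objective)
        return mat, trace

    best: tuple[float, int, np.ndarray, list[float]] | None = None
    finals: list[float] = []
    for r in range(restarts):
        rng = np.random.default_rng([seed, r])
        seed_word = pool[rng.integers(len(pool))]
        init = np.full((width, 4), 0.1)
        for m, c in enumerate(seed_word):
            init[m, _BASE_INDEX[c]] = 0.7
        mat, trace = run_em(init)
        finals.append(trace[-1])
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], r, mat, trace)

    # phase refinement: EM can lock one column off the optimal register, so
    # re-run from shifted variants of the best matrix as extra restarts
    assert best is not None
    base_mat = best[2]
    for extra, shift in enumerate((-2, -1, 1, 2)):
        init = np.tile(background, (width, 1))
        for m in range(width):
            src = m - shift
            if 0 <= src < width:
                init[m] = base_mat[src]
        mat, trace = run_em(init)
        finals.append(trace[-1])
        if trace[-1] > best[0]:
            best = (trace[-1], restarts + extra, mat, trace)

    obj, r_best, mat, trace = best
    pwm = PWM(mat, background)

    # final site assignment under the best matrix
    log_mat = np.log(mat)
    score_f = sum(log_mat[m][idx[:, :, m]] for m in range(width))
    score_r = sum(log_mat[m][idx_rc[:, :, m]] for m in range(width))
    stacked = np.concatenate(
        [np.full((n, 1), log_prior_none),
         log_prior_site + score_f - win_bg,
         log_prior_site + score_r - win_bg], axis=1
    )
    sites: list[tuple[int, str] | None] = []
    for i in range(n):
        j = int(np.argmax(stacked[i]))
        if j == 0:
            sites.append(None)
        elif j <= kmax:
            sites.append((j - 1, "+"))
        else:
            sites.append((j - kmax - 1, "-"))
    log.info("motif EM: width=%d restarts=%d best restart %d objective %.2f",
             width, restarts, r_best, obj)
    return MotifResult(pwm, sites, obj, trace, r_best, finals)


def iupac_consensus(pwm: PWM) -> str:
    """Render a PWM as IUPAC letters: a single base at probability >= 0.6, the
    top-two code when their sum >= 0.8, the top-three code when >= 0.95, else N."""
    letters = []
    for col in pwm.matrix:
        order = np.argsort(-col, kind="stable")
        if col[order[0]] >= 0.6:
            letters.append(_BASES[order[0]])
        elif col[order[:2]].sum() >= 0.8:
            letters.append(_CODE_OF_SET[frozenset(_BASES[i] for i in order[:2])])
        elif col[order[:3]].sum() >= 0.95:
            letters.append(_CODE_OF_SET[frozenset(_BASES[i] for i in order[:3])])
        else:
            letters.append("N")
    return "".join(letters)


def scan_pwm(sequence: str, pwm: PWM, score_min: float = 0.0
             ) -> list[tuple[int, str, float]]:
    """Log-odds scan (bits) of both strands; reverse-strand hits are scored with
    the reverse-complemented matrix at the same forward offset."""
    sequence = sequence.upper()
    w = pwm.width
    if len(sequence) < w:
        raise ValueError("sequence shorter than PWM width")
    codes = np.array([_BASE_INDEX[c] for c in sequence], dtype=np.intp)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    lods = np.log2(pwm.matrix / pwm.background)
    lods_rc = np.log2(pwm.reverse_complement().matrix / pwm.reverse_complement().background)
    score_f = sum(lods[m][windows[:, m]] for m in range(w))
    score_r = sum(lods_rc[m][windows[:, m]] for m in range(w))
    hits = [(int(j), "+", float(s)) for j, s in enumerate(score_f) if s >= score_min]
    hits += [(int(j), "-", float(s)) for j, s in enumerate(score_r) if s >= score_min]
    return sorted(hits)
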