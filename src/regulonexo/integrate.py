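"""Integration of binding peaks with annotation and differential expression:
the causally classified regulon.

A peak is assigned to every transcription unit whose strand-aware TSS-relative
window (default -500 to +200 bp, negative = upstream) contains the peak
center; divergent promoters can therefore attach one peak to two TUs. The
regulatory mode of a bound TU is read off the knockout response of its member
genes: all significant genes at log2FC(KO/WT) <= -1 means the TF activated the
TU, all at >= +1 means it repressed it, no significant gene leaves causality
not determined, and mixed signs are flagged as a conflict rather than forced
into a mode.
"""
from __future__ import annotations

import logging
from dataclasses import asdict

import pandas as pd

from .model import GenomeAnnotation, Peak, RegulonEntry

__all__ = [
    "distance_to_tss", "classify_location", "assign_peaks_to_tus",
    "classify_mode", "build_regulon",
]

log = logging.getLogger("regulonexo.integrate")


def distance_to_tss(center: int, tss: int, strand: str) -> int:
    """Signed strand-aware distance from a peak center to a TSS (negative =
    upstream of the TSS in the direction of transcription)."""
    if strand == "+":
        return center - tss
    if strand == "-":
        return tss - center
    raise ValueError(f"bad strand {strand!r}")


def classify_location(distance: int, promoter_bound: int = 100) -> str:
    """Bin a TSS-relative distance: upstream (< -bound), promoter ([-bound, 0]),
    or 5'-proximal (> 0, inside the transcript)."""
    if distance < -promoter_bound:
        return "upstream"
    if distance <= 0:
        return "promoter"
    return "5p_proximal"


def assign_peaks_to_tus(peaks: list[Peak], annotation: GenomeAnnotation,
                        window: tuple[int, int] = (-500, 200)
                        ) -> tuple[dict[str, list[str]], list[str]]:
    """Map each peak to all TUs whose TSS window contains the peak center.

    Returns (peak name -> list of TU ids, names of unassigned peaks).
    """
    up, down = window
    assigned: dict[str, list[str]] = {}
    unassigned: list[str] = []
    for i, p in enumerate(peaks):
        name = p.name or f"peak{i + 1}"
        hits = []
        for tu in annotation.tus.values():
            d = distance_to_tss(p.center, tu.tss, tu.strand)
            if up <= d <= down:
                hits.append(tu.id)
        if hits:
            assigned[name] = hits
        else:
            unassigned.append(name)
    if unassigned:
        log.info("%d peaks matched no TU window: %s", len(unassigned), unassigned)
    return assigned, unassigned


def classify_mode(tu_genes: list[str], de_results: pd.DataFrame,
                  lfc_min: float = 1.0) -> str:
    """Causal mode of one bound TU from its member genes' knockout response."""
    sub = de_results.loc[[g for g in tu_genes if g in de_results.index]]
    sig = sub[sub["significant"]]
    if sig.empty:
        return "not_determined"
    if (sig["log2fc"] <= -lfc_min).all():
        return "activated"
    if (sig["log2fc"] >= lfc_min).all():
        return "repressed"
    return "conflict"


def build_regulon(peaks: list[Peak], annotation: GenomeAnnotation,
                  de_results: pd.DataFrame,
                  window: tuple[int, int] = (-500, 200),
                  promoter_bound: int = 100, lfc_min: float = 1.0
                  ) -> tuple[list[RegulonEntry], dict]:
    """Emit one regulon entry per bound TU plus the summary count block.

    A gene is counted once even when its TU carries several peaks; the reported
    distance/location of a multi-peak TU comes from the peak closest to the TSS.
    """
    assigned, unassigned = assign_peaks_to_tus(peaks, annotation, window)
    by_name = {p.name or f"peak{i + 1}": p for i, p in enumerate(peaks)}
    tu_peaks: dict[str, list[str]] = {}
    for pname, tus in assigned.items():
        for tid in tus:
            tu_peaks.setdefault(tid, []).append(pname)

    entries: list[RegulonEntry] = []
    for tid in sorted(tu_peaks):
        tu = annotation.tus[tid]
        dists = [distance_to_tss(by_name[p].center, tu.tss, tu.strand)
                 for p in tu_peaks[tid]]
        d = min(dists, key=abs)
        entries.append(RegulonEntry(
            tu_id=tid,
            gene_ids=list(tu.gene_ids),
            peak_names=sorted(tu_peaks[tid]),
            distance=d,
            location=classify_location(d, promoter_bound),
            mode=classify_mode(tu.gene_ids, de_results, lfc_min),
        ))

    genes = {g for e in entries for g in e.gene_ids}
    mode_genes = {m: 0 for m in ("activated", "repressed", "not_determined", "conflict")}
    for e in entries:
        mode_genes[e.mode] += len(e.gene_ids)
    direct_tus = [e for e in entries if e.mode in ("activated", "repressed")]
    summary = {
        "n_peaks": len(peaks),
        "n_unassigned_peaks": len(unassigned),
        "n_tus": len(entries),
        "n_genes": len(genes),
        "genes_activated": mode_genes["activated"],
        "genes_repressed": mode_genes["repressed"],
        "genes_not_determined": mode_genes["not_determined"],
        "genes_conflict": mode_genes["conflict"],
        "genes_direct": mode_genes["activated"] + mode_genes["repressed"],
        "tus_direct": len(direct_tus),
    }
    log.info("regulon: %(n_genes)d genes in %(n_tus)d TUs; "
             "%(genes_direct)d direct in %(tus_direct)d TUs "
             "(%(genes_activated)d activated / %(genes_repressed)d repressed / "
             "%(genes_not_determined)d not determined)", summary)
    return entries, summary


def regulon_frame(entries: list[RegulonEntry], de_results: pd.DataFrame) -> pd.DataFrame:
    """Flat per-gene table mirroring a supplementary-table layout."""
    rows = []
    for e in entries:
        for g in e.gene_ids:
            rec = asdict(e)
            rec.pop("gene_ids")
            rec["peak_names"] = ",".join(rec["peak_names"])
            rec["gene"] = g
            if g in de_results.index:
                rec["log2fc"] = float(de_results.at[g, "log2fc"])
                rec["qvalue"] = float(de_results.at[g, "qvalue"])
            rows.append(rec)
    return pd.DataFrame(rows).set_index("gene")
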