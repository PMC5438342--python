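"""Readers and writers for every on-disk format the pipeline touches.

Internally everything is 0-based half-open; GFF3 (1-based inclusive) and
bedGraph/BED (native 0-based half-open) conversion happens only here. Every
reader/writer pair is a lossless round trip, which the test suite asserts on
generated fixtures.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import RunConfig  # re-exported: run configuration lives with io
from .model import PWM, BorderProfile, Gene, GenomeAnnotation, GrowthCurve, CountTable, TU

__all__ = [
    "RunConfig",
    "read_fasta", "write_fasta",
    "read_annotation", "write_annotation_gff", "write_annotation_bed",
    "read_bedgraph", "write_bedgraph",
    "read_counts", "write_counts",
    "read_membership", "write_membership",
    "read_orthologs", "write_orthologs",
    "read_growth", "write_growth",
    "write_pwm_meme", "write_pwm_tsv",
    "write_peaks_bed", "write_peaks_tsv",
]

log = logging.getLogger("regulonexo.io")

CHROM = "chr"


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return str(records[0].seq).upper()


def write_fasta(sequence: str, path: str | Path, name: str = CHROM) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


# ---------------------------------------------------------------- annotation

def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().rstrip(";").split(";"):
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        out[key.strip()] = value.strip()
    return out


def write_annotation_gff(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write the annotation as GFF3 with per-gene ``tu_id`` grouping attributes."""
    lines = ["##gff-version 3", f"##sequence-region {CHROM} 1 {ann.genome_length}"]
    for tu in ann.tus.values():
        genes = [ann.genes[g] for g in tu.gene_ids]
        span = (min(g.start for g in genes), max(g.end for g in genes))
        lines.append(
            "\t".join(
                [CHROM, "regulonexo", "transcription_unit", str(span[0] + 1),
                 str(span[1]), ".", tu.strand, ".", f"ID={tu.id};tss={tu.tss + 1}"]
            )
        )
    for g in ann.genes.values():
        attrs = f"ID={g.id};tu_id={g.tu_id};cog={g.cog};localization={g.localization}"
        lines.append(
            "\t".join(
                [CHROM, "regulonexo", "gene", str(g.start + 1), str(g.end),
                 ".", g.strand, ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_annotation_bed(ann: GenomeAnnotation, path: str | Path) -> None:
    """BED6+4 dialect: chrom start end gene score strand tu_id tss cog localization."""
    rows = []
    for g in ann.genes.values():
        tu = ann.tus[g.tu_id]
        rows.append((CHROM, g.start, g.end, g.id, 0, g.strand, g.tu_id, tu.tss,
                     g.cog, g.localization))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_annotation(path: str | Path, genome_length: int | None = None) -> GenomeAnnotation:
    """Read a GFF3 (``.gff``/``.gff3``) or BED (``.bed``) annotation.

    Coordinates are normalized to internal 0-based half-open. TU membership is
    taken from the ``tu_id`` grouping attribute (GFF) or column 7 (BED).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        return _read_annotation_gff(path, genome_length)
    if suffix == ".bed":
        return _read_annotation_bed(path, genome_length)
    raise ValueError(f"{path}: unknown annotation dialect {suffix!r} (use .gff/.gff3/.bed)")


def _read_annotation_gff(path: Path, genome_length: int | None) -> GenomeAnnotation:
    genes: dict[str, Gene] = {}
    tus: dict[str, TU] = {}
    tu_members: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    genome_length = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns, got {len(fields)}")
            try:
                start = int(fields[3]) - 1  # 1-based inclusive -> 0-based half-open
                end = int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty interval after normalization")
            ftype, strand = fields[2], fields[6]
            attrs = _parse_gff_attributes(fields[8])
            if "ID" not in attrs:
                raise ValueError(f"{path}:{lineno}: missing ID attribute")
            if ftype == "transcription_unit":
                tus[attrs["ID"]] = TU(attrs["ID"], [], int(attrs["tss"]) - 1, strand)
            elif ftype == "gene":
                if "tu_id" not in attrs:
                    raise ValueError(f"{path}:{lineno}: gene without tu_id attribute")
                g = Gene(attrs["ID"], attrs["tu_id"], start, end, strand,
                         attrs.get("cog", "S"), attrs.get("localization", "ND"))
                genes[g.id] = g
                tu_members.setdefault(g.tu_id, []).append(g.id)
    for tid, members in tu_members.items():
        if tid not in tus:
            raise ValueError(f"{path}: gene references unknown TU {tid!r}")
        tus[tid].gene_ids = sorted(members, key=lambda gid: genes[gid].start)
        if tus[tid].strand == "-":
            tus[tid].gene_ids.reverse()
    if genome_length is None:
        genome_length = max(g.end for g in genes.values())
    ann = GenomeAnnotation(genes, tus, genome_length)
    ann.validate()
    return ann


def _read_annotation_bed(path: Path, genome_length: int | None) -> GenomeAnnotation:
    genes: dict[str, Gene] = {}
    tus: dict[str, TU] = {}
    tu_members: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(f"{path}:{lineno}: expected >= 10 BED columns, got {len(fields)}")
            try:
                start, end, tss = int(fields[1]), int(fields[2]), int(fields[7])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty interval")
            gid, strand, tid = fields[3], fields[5], fields[6]
            genes[gid] = Gene(gid, tid, start, end, strand, fields[8], fields[9])
            tu_members.setdefault(tid, []).append(gid)
            if tid not in tus:
                tus[tid] = TU(tid, [], tss, strand)
    for tid, members in tu_members.items():
        tus[tid].gene_ids = sorted(members, key=lambda gid: genes[gid].start)
        if tus[tid].strand == "-":
            tus[tid].gene_ids.reverse()
    if genome_length is None:
        genome_length = max(g.end for g in genes.values())
    ann = GenomeAnnotation(genes, tus, genome_length)
    ann.validate()
    return ann


# ---------------------------------------------------------------- bedGraph

def write_bedgraph(profile: BorderProfile, path: str | Path) -> None:
    """Write one strand-specific border track, zero runs compressed."""
    v = profile.counts
    header = (
        f"track type=bedGraph name={profile.label} strand={profile.strand} "
        f"library_size={profile.library_size}"
    )
    # change points delimit maximal constant runs
    edges = np.flatnonzero(np.diff(v) != 0) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [v.size]])
    lines = [header]
    for s, e in zip(starts, ends):
        if v[s] != 0:
            val = v[s]
            text = f"{int(val)}" if float(val).is_integer() else f"{val:.6g}"
            lines.append(f"{CHROM}\t{s}\t{e}\t{text}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bedgraph(path: str | Path, genome_length: int,
                  strand: str | None = None, label: str | None = None) -> BorderProfile:
    path = Path(path)
    counts = np.zeros(genome_length, dtype=float)
    library_size: int | None = None
    covered = np.zeros(genome_length, dtype=bool)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("track"):
                for tok in line.split():
                    key, _, value = tok.partition("=")
                    if key == "strand":
                        strand = strand or value
                    elif key == "library_size":
                        library_size = int(value)
                    elif key == "name":
                        label = label or value
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                s, e, val = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph record") from exc
            if not (0 <= s < e <= genome_length):
                raise ValueError(f"{path}:{lineno}: interval [{s},{e}) outside genome")
            if val < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if covered[s:e].any():
                raise ValueError(f"{path}:{lineno}: overlapping bedGraph intervals")
            covered[s:e] = True
            counts[s:e] = val
    total = counts.sum()
    if library_size is None:
        library_size = int(round(total))
    return BorderProfile(strand or "+", counts, library_size, label or path.stem)


# ---------------------------------------------------------------- tables

def write_counts(table: CountTable, counts_path: str | Path, samples_path: str | Path) -> None:
    out = table.counts.copy()
    out.insert(0, "length", table.lengths)
    out.to_csv(counts_path, sep="\t", index_label="gene")
    sheet = pd.DataFrame(
        {
            "sample": list(table.counts.columns),
            "condition": [table.conditions[s] for s in table.counts.columns],
            "library_size": [int(table.library_sizes[s]) for s in table.counts.columns],
        }
    )
    sheet.to_csv(samples_path, sep="\t", index=False)


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountTable:
    df = pd.read_csv(counts_path, sep="\t", index_col="gene")
    lengths = df.pop("length")
    sheet = pd.read_csv(samples_path, sep="\t")
    conditions = dict(zip(sheet["sample"], sheet["condition"]))
    libs = None
    if "library_size" in sheet.columns:
        libs = pd.Series(sheet["library_size"].to_numpy(float), index=sheet["sample"])
    return CountTable(df.astype(int), conditions, lengths.astype(int), libs)


def write_membership(membership: pd.DataFrame, path: str | Path) -> None:
    membership.astype(int).to_csv(path, sep="\t", index_label="gene")


def read_membership(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene").astype(int)


def write_orthologs(presence: pd.DataFrame, groups: pd.Series,
                    presence_path: str | Path, groups_path: str | Path) -> None:
    presence.astype(int).to_csv(presence_path, sep="\t", index_label="gene")
    groups.rename("group").to_csv(groups_path, sep="\t", index_label="genome")


def read_orthologs(presence_path: str | Path, groups_path: str | Path
                   ) -> tuple[pd.DataFrame, pd.Series]:
    presence = pd.read_csv(presence_path, sep="\t", index_col="gene").astype(int)
    groups = pd.read_csv(groups_path, sep="\t", index_col="genome")["group"]
    return presence, groups


def write_growth(curves: list[GrowthCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, od in zip(c.time, c.od):
            rows.append((c.strain, c.condition, t, od))
    pd.DataFrame(rows, columns=["strain", "condition", "time_h", "od600"]).to_csv(
        path, sep="\t", index=False
    )


def read_growth(path: str | Path) -> list[GrowthCurve]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (strain, cond), sub in df.groupby(["strain", "condition"], sort=False):
        sub = sub.sort_values("time_h")
        out.append(GrowthCurve(sub["time_h"].to_numpy(), sub["od600"].to_numpy(),
                               strain, cond))
    return out


# ---------------------------------------------------------------- PWM / peaks

def write_pwm_meme(pwm: PWM, path: str | Path, name: str = "motif1", nsites: int = 0) -> None:
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.6f}" for b, f in zip("ACGT", pwm.background)), "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= {nsites}",
    ]
    for row in pwm.matrix:
        lines.append(" ".join(f"{p:.6f}" for p in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_pwm_tsv(pwm: PWM, path: str | Path) -> None:
    pd.DataFrame(pwm.matrix, columns=list("ACGT")).to_csv(
        path, sep="\t", index_label="position"
    )


def write_peaks_bed(peaks, path: str | Path) -> None:
    """BED6+2: name, S/N x 1000 as score, '.' strand, plus the two border columns."""
    rows = []
    for i, p in enumerate(peaks):
        score = int(round((p.sn or 0.0) * 1000))
        rows.append((CHROM, p.start, p.end, p.name or f"peak{i + 1}", score, ".",
                     p.fwd_border, p.rev_border))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_peaks_tsv(peaks, path: str | Path) -> None:
    rows = [
        (p.name or f"peak{i + 1}", p.start, p.end, p.center, p.fwd_border,
         p.rev_border, p.sn, p.support)
        for i, p in enumerate(peaks)
    ]
    pd.DataFrame(
        rows,
        columns=["name", "start", "end", "center", "fwd_border", "rev_border", "sn", "support"],
    ).to_csv(path, sep="\t", index=False)
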