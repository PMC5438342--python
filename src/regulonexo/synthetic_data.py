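"""Synthetic study generator with planted ground truth.

Generates a desk-scale bacterial genome with operon (TU) structure, plants
transcription-factor binding sites with motif instances, simulates duplicate
strand-specific ChIP-exo border tracks plus a mock-IP control, knockout versus
wild-type RNA-seq count tables, regulon-membership tables, ortholog
presence/absence matrices, and OD600 growth curves — all mutually consistent
and fully determined by the seed, so every downstream stage can be tested
against the planted truth without any external data.

The ``paper_scale`` preset encodes the study conditions this pipeline targets:
25 ChIP-detectable sites regulating 24 TUs / 37 genes (14 activated, 12
repressed, 11 with no expression change), 8 previously-known sites of which one
carries no ChIP signal, a genome-wide total of 412 differentially expressed
genes, an 8-TF stress-regulon membership universe of 243 genes, and ortholog
groups of 13/3/2/7/134/40/58 genomes across proteobacterial taxa.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .config import RunConfig
from .model import (
    PWM, BorderProfile, CountTable, Gene, GenomeAnnotation, GrowthCurve,
    PlantedSite, ScenarioTruth, SyntheticDataset, TU,
)

__all__ = ["generate_scenario", "simulate_chipexo", "simulate_rnaseq_counts",
           "write_dataset", "PLANTED_CONSENSUS", "planted_pwm"]

log = logging.getLogger("regulonexo.synthetic")

PLANTED_CONSENSUS = "KWWGTTACAT"
STRESS_TFS = ["OmpR", "OxyR", "SoxR", "SoxS", "Fur", "GadE", "GadW", "GadX"]
ORTHOLOG_GROUPS = {
    "Escherichia": 13, "Shigella": 3, "Salmonella": 2, "Yersinia": 7,
    "Gammaproteobacteria": 134, "Betaproteobacteria": 40, "Alphaproteobacteria": 58,
}
_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "W": "AT", "K": "GT"}
_BASES = "ACGT"
_COG_POOL = list("CGMPEFHIJKNOT")    # 13 categories observed for the regulon

FOOTPRINT = 21          # bp, planted protected footprint span
TSS_OFFSET = 30         # bp, TSS upstream of the first gene start
ASSIGN_WINDOW = (-500, 200)   # the integration default the layout is validated against


def planted_pwm(consensus: str = PLANTED_CONSENSUS, strength: float = 0.94) -> PWM:
    """PWM realizing an IUPAC consensus: ``strength`` on a unique base, an even
    split over the bases of an ambiguity code."""
    mat = np.zeros((len(consensus), 4))
    for m, letter in enumerate(consensus):
        bases = _IUPAC[letter]
        rest = (1.0 - strength) / 3 if len(bases) == 1 else (1.0 - strength) / 2
        main = strength if len(bases) == 1 else strength / 2
        mat[m, :] = rest
        for b in bases:
            mat[m, _BASES.index(b)] = main
    return PWM(mat, np.full(4, 0.25))


# --------------------------------------------------------------- presets

@dataclass
class _Preset:
    name: str
    genome_length: int
    n_tus: int
    n_genes: int
    # regulon TU gene-count composition per mode
    activated_tus: list[int]
    repressed_tus: list[int]
    nd_tus: list[int]
    n_sites: int                    # ChIP-detectable sites (one TU gets two)
    n_known: int                    # previously reported sites
    known_without_signal: int       # of those, how many lack ChIP signal
    n_indirect_de: int              # DE genes without a binding site (TF gene excluded)
    depth: int
    mean_depth: float               # RNA-seq per-gene base expression level
    gene_length: tuple[int, int]
    membership: bool
    orthologs: bool


def _presets(config: RunConfig) -> dict[str, _Preset]:
    return {
        "paper_scale": _Preset(
            name="paper_scale", genome_length=500_000, n_tus=350, n_genes=600,
            activated_tus=[3, 2, 2, 2, 2, 1, 1, 1],
            repressed_tus=[2, 2, 2, 2, 1, 1, 1, 1],
            nd_tus=[2, 2, 2, 1, 1, 1, 1, 1],
            n_sites=25, n_known=8, known_without_signal=1,
            n_indirect_de=385, depth=config.sim_depth, mean_depth=800.0,
            gene_length=(250, 700), membership=True, orthologs=True,
        ),
        "small": _Preset(
            name="small", genome_length=30_000, n_tus=20, n_genes=30,
            activated_tus=[2], repressed_tus=[2], nd_tus=[1],
            n_sites=3, n_known=2, known_without_signal=0,
            n_indirect_de=3, depth=1_000_000, mean_depth=400.0,
            gene_length=(250, 700), membership=False, orthologs=False,
        ),
    }


# --------------------------------------------------------------- genome layout

@dataclass
class _Layout:
    annotation: GenomeAnnotation
    sites: list[PlantedSite]
    regulon_tus: list[str]
    tu_modes: dict[str, str]
    aux_centers: list[int]          # artifact + known-no-signal site centers
    tf_gene: str


def _compose_other_tus(rng: np.random.Generator, n_tus: int, n_genes: int) -> list[int]:
    """Gene counts for the non-regulon TUs, summing exactly to ``n_genes``."""
    sizes = [1] * n_tus
    remaining = n_genes - n_tus
    while remaining > 0:
        i = int(rng.integers(n_tus))
        if sizes[i] < 4:
            sizes[i] += 1
            remaining -= 1
    return sizes


def _build_layout(rng: np.random.Generator, preset: _Preset,
                  n_aux: int, config: RunConfig) -> _Layout:
    reg_specs = (
        [("activated", k) for k in preset.activated_tus]
        + [("repressed", k) for k in preset.repressed_tus]
        + [("not_determined", k) for k in preset.nd_tus]
    )
    n_reg = len(reg_specs)
    n_reg_genes = sum(k for _, k in reg_specs)
    other_sizes = _compose_other_tus(rng, preset.n_tus - n_reg,
                                     preset.n_genes - n_reg_genes)

    # slot the regulon TUs (and aux hosts for artifact / signal-less sites)
    # at shuffled positions along the chromosome
    entries: list[tuple[str, int, str | None]] = [("other", k, None) for k in other_sizes]
    for mode, k in reg_specs:
        entries.append(("regulon", k, mode))
    rng.shuffle(entries)
    # aux hosts: distinct forward-strand non-regulon TUs with an enlarged gap
    aux_slots = rng.choice(
        [i for i, e in enumerate(entries) if e[0] == "other"], size=n_aux, replace=False
    ) if n_aux else np.array([], dtype=int)
    aux_slots = set(int(i) for i in aux_slots)

    genes: dict[str, Gene] = {}
    tus: dict[str, TU] = {}
    tu_modes: dict[str, str] = {}
    regulon_tus: list[str] = []
    sites: list[PlantedSite] = []
    aux_centers: list[int] = []

    cursor = int(rng.integers(200, 400))
    prev_kind, prev_strand = "other", "+"
    gene_no = 0
    two_site_tu = rng.integers(len([e for e in entries if e[0] == "regulon"])) \
        if preset.n_sites > n_reg else -1
    reg_seen = 0

    for i, (kind, n_in_tu, mode) in enumerate(entries):
        strand = "+" if (kind != "other" or rng.random() < 0.5) else "-"
        if kind == "regulon":
            strand = "+" if rng.random() < 0.5 else "-"
        # inter-block gap: promoter-side clearance around regulon TUs keeps each
        # planted site inside exactly one TSS window of the integration default
        gap = int(rng.integers(150, 350))
        if kind == "regulon":
            gap = max(gap, 1000 if strand == "+" else 650)
        if i in aux_slots:
            strand = "+"
            gap = max(gap, 500)
        if prev_kind == "regulon":
            gap = max(gap, 1000 if prev_strand == "-" else 650)
        cursor += gap

        tid = f"tu{i:04d}"
        lengths = rng.integers(preset.gene_length[0], preset.gene_length[1] + 1,
                               size=n_in_tu)
        starts, pos = [], cursor
        for glen in lengths:
            starts.append(pos)
            pos += int(glen) + 20
        block_end = starts[-1] + int(lengths[-1])
        if strand == "+":
            tss = cursor - TSS_OFFSET
            ordered = list(range(n_in_tu))
        else:
            tss = block_end - 1 + TSS_OFFSET
            ordered = list(range(n_in_tu))[::-1]
        gids = []
        for j in ordered:
            gid = f"g{gene_no:04d}"
            gene_no += 1
            genes[gid] = Gene(gid, tid, starts[j], starts[j] + int(lengths[j]), strand)
            gids.append(gid)
        tus[tid] = TU(tid, gids, tss, strand)

        if kind == "regulon":
            regulon_tus.append(tid)
            tu_modes[tid] = mode or "not_determined"
            dists = [int(rng.integers(60, 241))]
            if reg_seen == two_site_tu:
                dists = [int(rng.integers(60, 161))]
                dists.append(dists[0] + int(rng.integers(140, 241)))
            for d in dists:
                center = tss - d if strand == "+" else tss + d
                sites.append(PlantedSite(center, center - FOOTPRINT // 2,
                                         center + FOOTPRINT // 2 + 1, tid))
            reg_seen += 1
        elif i in aux_slots:
            d = int(rng.integers(120, 260))
            aux_centers.append(tss - d)

        cursor = block_end
        prev_kind, prev_strand = kind, strand

    if cursor + 500 > preset.genome_length:
        raise ValueError("preset layout exceeds the genome length")

    ann = GenomeAnnotation(genes, tus, preset.genome_length)
    ann.validate()

    # hard consistency check: each planted site center falls in the default TSS
    # window of its target TU and of no other TU
    up, down = ASSIGN_WINDOW
    for s in sites:
        hits = [t.id for t in tus.values()
                if up <= (s.center - t.tss if t.strand == "+" else t.tss - s.center) <= down]
        if hits != [s.tu_id] and sorted(hits) != [s.tu_id]:
            raise AssertionError(
                f"planted site at {s.center} maps to TUs {hits}, expected [{s.tu_id}]"
            )

    tf_gene = rng.choice(
        [g for g in genes if genes[g].tu_id not in regulon_tus]
    )
    return _Layout(ann, sites, regulon_tus, tu_modes, aux_centers, str(tf_gene))


def _annotate_functions(rng: np.random.Generator, ann: GenomeAnnotation,
                        regulon_genes: list[str]) -> None:
    """COG categories and subcellular localizations.

    At the 37-gene regulon scale the products are mostly membrane-located
    (18 inner membrane, 7 outer membrane, 9 cytosolic, 3 undetermined) across
    13 COG categories; smaller regulons get a proportional split. Background
    genes are predominantly cytosolic.
    """
    n = len(regulon_genes)
    plan: list[str] = []
    for loc, frac in (("IM", 18 / 37), ("OM", 7 / 37), ("C", 9 / 37)):
        plan.extend([loc] * int(round(frac * n)))
    plan.extend(["ND"] * (n - len(plan)))
    plan = plan[:n]
    cogs = [_COG_POOL[i % len(_COG_POOL)] for i in range(n)]
    order = rng.permutation(n)
    for k, g in enumerate(regulon_genes):
        ann.genes[g].localization = plan[order[k]]
        ann.genes[g].cog = cogs[order[k]]
    background_locs = np.array(["C", "IM", "OM", "ND"])
    pool = np.array(list("CGMPEFHIJKLNOTUVS"))
    for g in ann.genes:
        if g in set(regulon_genes):
            continue
        ann.genes[g].localization = str(
            rng.choice(background_locs, p=[0.60, 0.25, 0.05, 0.10]))
        ann.genes[g].cog = str(rng.choice(pool))


# --------------------------------------------------------------- ChIP simulation

def simulate_chipexo(sites: list[PlantedSite], genome_length: int, depth: int,
                     noise: float | None, seed: int, target_sn: float = 5.0,
                     jitter: int = 2, labels: tuple[str, ...] = ("rep1", "rep2", "mock"),
                     ) -> dict[str, tuple[BorderProfile, BorderProfile]]:
    """Simulate strand-specific 5'-border tracks for duplicates and a mock IP.

    For each site with signal, forward-strand borders pile up at the footprint's
    left edge and reverse-strand borders at its right edge, each with a
    truncated-geometric jitter of ``+-jitter`` bp (decay 0.5). The remaining
    reads are uniform background. With ``noise=None`` the per-site read mass is
    set so the realized signal-to-noise ratio is ~``target_sn``; ``noise`` in
    [0, 1] instead fixes the background fraction directly (``noise=0`` puts
    every read on a site edge). Replicates are drawn independently; the mock
    track carries only background plus the artifact sites. Each strand profile
    carries exactly half the library depth.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    kernel = np.array([0.5 ** abs(o) for o in range(-jitter, jitter + 1)])
    kernel /= kernel.sum()

    out: dict[str, tuple[BorderProfile, BorderProfile]] = {}
    for label in labels:
        if label == "mock":
            active = [s for s in sites if s.is_artifact]
        else:
            active = [s for s in sites if s.has_signal]
        m = len(active)
        if noise is None:
            # reads jittered outside the footprint do not count toward the
            # called interval's density; correct by the kernel's interior mass
            interior = float(kernel[jitter:].sum())
            span = FOOTPRINT
            per_site = (max(target_sn - 1.0, 0.0) * span * depth
                        / genome_length / interior)
            bg = max(depth - m * per_site, 0.0)
        else:
            bg = noise * depth
            per_site = (depth - bg) / m if m else 0.0
        weights = {"+": np.full(genome_length, bg / (2 * genome_length)),
                   "-": np.full(genome_length, bg / (2 * genome_length))}
        for s in active:
            left, right = s.start, s.end - 1
            for strand, edge in (("+", left), ("-", right)):
                lo = edge - jitter
                for k, w in enumerate(kernel):
                    pos = lo + k
                    if 0 <= pos < genome_length:
                        weights[strand][pos] += per_site / 2 * w
        halves = {"+": depth // 2, "-": depth - depth // 2}
        pair = []
        for strand in "+-":
            p = weights[strand]
            total = p.sum()
            n_reads = halves[strand]
            if total <= 0:
                counts = np.zeros(genome_length)
            else:
                counts = rng.multinomial(n_reads, p / total).astype(float)
            pair.append(BorderProfile(strand, counts, n_reads, label))
        out[label] = (pair[0], pair[1])
        log.info("chip-exo %s: %d sites, depth %d, background %.3f",
                 label, m, depth, bg / depth if depth else 0.0)
    return out


# --------------------------------------------------------------- RNA-seq simulation

def simulate_rnaseq_counts(truth: ScenarioTruth, annotation: GenomeAnnotation,
                           mean_depth: float, dispersion: float, seed: int,
                           lib_factors: dict[str, float] | None = None) -> CountTable:
    """Negative-binomial count tables for WT and knockout duplicates.

    Wild-type expected counts are ``base_g x (length_g / 1 kb) x lib_factor_s``
    with lognormal per-gene base levels around ``mean_depth``. Knockout means
    follow the planted mode: activated targets drop by 2^effect, repressed
    targets rise by 2^effect, the deleted TF gene goes to zero, unchanged genes
    keep the wild-type mean. ``dispersion=0`` is the Poisson limit.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    lib_factors = lib_factors or {"WT1": 1.0, "WT2": 1.1, "KO1": 0.92, "KO2": 1.04}
    conditions = {s: ("WT" if s.startswith("WT") else "KO") for s in lib_factors}
    genes = list(annotation.genes)
    lengths = pd.Series({g: annotation.genes[g].length for g in genes})
    if truth.base_expression:
        base = np.array([truth.base_expression[g] for g in genes])
    else:
        base = np.exp(rng.normal(np.log(mean_depth), 0.35, size=len(genes)))

    ko_mult = np.ones(len(genes))
    for i, g in enumerate(genes):
        mode = truth.gene_modes.get(g, "unchanged")
        if g == truth.tf_gene:
            ko_mult[i] = 0.0
        elif mode == "activated":
            ko_mult[i] = 2.0 ** (-truth.effect_sizes[g])
        elif mode == "repressed":
            ko_mult[i] = 2.0 ** (truth.effect_sizes[g])
        elif g in truth.indirect_de:
            ko_mult[i] = 2.0 ** truth.indirect_de[g]

    data = {}
    for sample, factor in lib_factors.items():
        mu = base * (lengths.to_numpy() / 1e3) * factor
        if conditions[sample] == "KO":
            mu = mu * ko_mult
        if dispersion == 0:
            counts = rng.poisson(mu)
        else:
            n = 1.0 / dispersion
            counts = np.where(mu > 0, rng.negative_binomial(n, n / (n + mu)), 0)
        data[sample] = counts
    df = pd.DataFrame(data, index=genes)
    return CountTable(df, conditions, lengths)


# --------------------------------------------------------------- side tables

def _make_membership(rng: np.random.Generator, regulon_genes: list[str],
                     other_genes: list[str]) -> tuple[pd.DataFrame, list[str]]:
    """243-gene membership over 8 stress TFs (plus extra TF columns).

    Stress-TF composition: 206 genes with a single TF, 33 with two, 4 with
    three. Of the 37 focal-TF genes, 3 overlap the other stress regulons (two
    doubles, one triple) and 16 more are touched only by non-stress TFs.
    """
    extra_tfs = [f"TF{i:02d}" for i in range(1, 31)]
    others = list(rng.choice(other_genes, size=206, replace=False))
    rows = regulon_genes + others
    mem = pd.DataFrame(0, index=rows, columns=STRESS_TFS + extra_tfs)
    mem.loc[regulon_genes, "OmpR"] = 1

    overlap3 = list(rng.choice(regulon_genes, size=3, replace=False))
    mem.loc[overlap3[0], "GadX"] = 1                 # dtpA analogue
    mem.loc[overlap3[1], "OxyR"] = 1                 # znuA analogue
    mem.loc[overlap3[2], ["SoxS", "GadE"]] = 1       # micF analogue

    non_focal = [t for t in STRESS_TFS if t != "OmpR"]
    # 172 singles, 31 doubles, 3 triples among the other 206 genes
    k_per = [1] * 172 + [2] * 31 + [3] * 3
    rng.shuffle(others)
    for g, k in zip(others, k_per):
        for t in rng.choice(non_focal, size=k, replace=False):
            mem.loc[g, t] = 1

    # 16 more focal genes known only from non-stress TFs (two heavy regulators
    # echo highly co-regulated operons)
    remaining = [g for g in regulon_genes if g not in overlap3]
    touched = list(rng.choice(remaining, size=16, replace=False))
    heavy = {touched[0]: 7, touched[1]: 9}
    for g in touched:
        k = heavy.get(g, int(rng.integers(1, 3)))
        for t in rng.choice(extra_tfs, size=k, replace=False):
            mem.loc[g, t] = 1
    return mem, extra_tfs


def _make_orthologs(rng: np.random.Generator, regulon_genes: list[str],
                    tf_gene: str) -> tuple[pd.DataFrame, pd.Series]:
    genomes, groups = [], []
    for group, size in ORTHOLOG_GROUPS.items():
        for i in range(size):
            genomes.append(f"{group[:4]}_{i:03d}")
            groups.append(group)
    groups = pd.Series(groups, index=genomes, name="group")
    factor = {"Escherichia": 1.0, "Shigella": 0.95, "Salmonella": 0.9,
              "Yersinia": 0.8, "Gammaproteobacteria": 0.45,
              "Betaproteobacteria": 0.25, "Alphaproteobacteria": 0.15}
    rows = {}
    # the TF itself is nearly universal: absent from only 5 genomes
    tf_row = np.ones(len(genomes), dtype=int)
    tf_row[rng.choice(len(genomes), size=5, replace=False)] = 0
    rows[tf_gene] = tf_row
    for g in regulon_genes:
        base = rng.uniform(0.3, 0.9)
        p = np.array([base * factor[groups[gen]] for gen in genomes])
        rows[g] = (rng.random(len(genomes)) < p).astype(int)
    presence = pd.DataFrame(rows).T
    presence.columns = genomes
    return presence, groups


def _make_growth(rng: np.random.Generator) -> list[GrowthCurve]:
    """Logistic OD600 curves; the repressed-gene overexpression analogue grows
    40% slower than wild-type under osmotic stress."""
    t = np.arange(0.0, 10.5, 0.5)
    rates = {
        ("WT", "normal"): 0.90, ("WT", "osmotic"): 0.60,
        ("deltaTF", "normal"): 0.88, ("deltaTF", "osmotic"): 0.45,
        ("repressedOE", "normal"): 0.85, ("repressedOE", "osmotic"): 0.36,
    }
    out = []
    for (strain, cond), r in rates.items():
        od0, cap = 0.02, 1.4
        od = cap / (1 + (cap / od0 - 1) * np.exp(-r * t))
        od = od * np.exp(rng.normal(0, 0.01, size=t.size))
        out.append(GrowthCurve(t, od, strain, cond))
    return out


# --------------------------------------------------------------- top level

def generate_scenario(config: RunConfig | None = None, preset: str = "paper_scale",
                      seed: int | None = None) -> SyntheticDataset:
    """Generate one fully consistent synthetic dataset with planted truth.

    Same seed and configuration give a byte-identical dataset.
    """
    config = config or RunConfig()
    seed = config.seed if seed is None else seed
    presets = _presets(config)
    if preset not in presets and preset != "custom":
        raise ValueError(f"unknown preset {preset!r}; use {sorted(presets)}")
    ps = presets.get(preset, presets["paper_scale"])
    rng = np.random.default_rng([seed, 101])

    n_aux = config.sim_mock_artifacts + ps.known_without_signal
    layout = _build_layout(rng, ps, n_aux, config)
    ann = layout.annotation
    sites = list(layout.sites)
    if len(sites) != ps.n_sites:
        raise ValueError(f"preset inconsistency: planted {len(sites)} sites, "
                         f"expected {ps.n_sites}")

    # aux sites: mock-shared artifacts first, then known sites without signal
    aux = list(layout.aux_centers)
    for c in aux[:config.sim_mock_artifacts]:
        sites.append(PlantedSite(c, c - FOOTPRINT // 2, c + FOOTPRINT // 2 + 1,
                                 None, has_signal=True, is_artifact=True))
    for c in aux[config.sim_mock_artifacts:]:
        sites.append(PlantedSite(c, c - FOOTPRINT // 2, c + FOOTPRINT // 2 + 1,
                                 None, previously_known=True, has_signal=False))
    # flag known sites with signal
    signal_idx = [i for i, s in enumerate(sites) if s.has_signal and not s.is_artifact]
    n_known_signal = ps.n_known - ps.known_without_signal
    for i in rng.choice(signal_idx, size=n_known_signal, replace=False):
        sites[i].previously_known = True

    # genome sequence with motif instances planted at every real site
    pwm = planted_pwm()
    genome = rng.choice(list(_BASES), size=ps.genome_length)
    for s in sites:
        if s.is_artifact:
            continue
        inst = [_BASES[int(rng.choice(4, p=pwm.matrix[m]))] for m in range(pwm.width)]
        if rng.random() < 0.5:
            inst = [{"A": "T", "C": "G", "G": "C", "T": "A"}[b] for b in inst[::-1]]
        start = s.center - pwm.width // 2
        genome[start:start + pwm.width] = inst
    genome = "".join(genome)

    # per-gene modes and effects
    gene_modes: dict[str, str] = {g: "unchanged" for g in ann.genes}
    effects: dict[str, float] = {}
    regulon_genes: list[str] = []
    for tid in layout.regulon_tus:
        mode = layout.tu_modes[tid]
        for g in ann.tus[tid].gene_ids:
            regulon_genes.append(g)
            if mode in ("activated", "repressed"):
                gene_modes[g] = mode
                effects[g] = float(rng.uniform(2.0, 3.5))
    _annotate_functions(rng, ann, regulon_genes)

    candidates = [g for g in ann.genes
                  if g not in regulon_genes and g != layout.tf_gene]

    # Per-gene wild-type expression levels are drawn here so the indirect DE
    # composition can be mass-balanced: total expected RNA output must match
    # between conditions for total-count size factors (and the pooled binomial
    # test's library-mass proportion) to be unbiased. Indirect effect signs are
    # assigned greedily against the running expected-mass imbalance.
    base_expression = {
        g: float(v) for g, v in zip(
            ann.genes, np.exp(rng.normal(np.log(ps.mean_depth), 0.35,
                                         size=len(ann.genes))))
    }
    mass = {g: base_expression[g] * ann.genes[g].length / 1e3 for g in ann.genes}
    imbalance = -mass[layout.tf_gene]
    for g, e in effects.items():
        mult = 2.0 ** (-e if gene_modes[g] == "activated" else e)
        imbalance += mass[g] * (mult - 1.0)
    indirect: dict[str, float] = {}
    for g in rng.choice(candidates, size=ps.n_indirect_de, replace=False):
        e = float(rng.uniform(2.0, 3.0))
        signed = -e if imbalance > 0 else e
        indirect[str(g)] = signed
        imbalance += mass[str(g)] * (2.0 ** signed - 1.0)

    truth = ScenarioTruth(sites, gene_modes, effects, pwm, indirect,
                          layout.tf_gene, base_expression=base_expression)

    chip = simulate_chipexo(sites, ps.genome_length, ps.depth, noise=None,
                            seed=_sub(seed, 2), target_sn=config.sim_target_sn,
                            jitter=config.sim_jitter)
    counts = simulate_rnaseq_counts(truth, ann, ps.mean_depth,
                                    config.sim_dispersion, _sub(seed, 3))
    truth.library_sizes = {lbl: ps.depth for lbl in ("rep1", "rep2", "mock")}

    if ps.membership:
        membership, _ = _make_membership(
            np.random.default_rng([seed, 4]), regulon_genes, candidates
        )
    else:
        membership = pd.DataFrame(
            1, index=regulon_genes, columns=["OmpR"]
        )
    if ps.orthologs:
        orthologs, groups = _make_orthologs(
            np.random.default_rng([seed, 5]), regulon_genes, layout.tf_gene
        )
    else:
        genomes = [f"gen_{i}" for i in range(6)]
        groups = pd.Series(["Escherichia"] * 3 + ["Gammaproteobacteria"] * 3,
                           index=genomes, name="group")
        orth_rng = np.random.default_rng([seed, 5])
        orthologs = pd.DataFrame(
            orth_rng.integers(0, 2, size=(len(regulon_genes) + 1, 6)),
            index=[layout.tf_gene] + regulon_genes, columns=genomes,
        )
    growth = _make_growth(np.random.default_rng([seed, 6]))

    n_modes = {m: sum(1 for g in regulon_genes if gene_modes[g] == m)
               for m in ("activated", "repressed", "unchanged")}
    log.info("scenario %s seed %d: %d sites, %d regulon genes in %d TUs "
             "(%d act / %d rep / %d unchanged), %d DE genes total",
             preset, seed, len(truth.signal_sites), len(regulon_genes),
             len(layout.regulon_tus), n_modes["activated"], n_modes["repressed"],
             n_modes["unchanged"], len(truth.de_genes))
    return SyntheticDataset(genome, ann, chip, counts, membership,
                            STRESS_TFS, "OmpR", orthologs, groups, growth, truth)


def _sub(seed: int, stream: int) -> int:
    """Derived stream seed kept below 2**31."""
    return (seed * 1_000_003 + stream) % (2 ** 31 - 1)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write the full dataset: FASTA, GFF3, six bedGraphs, and the TSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rio.write_fasta(dataset.genome, out / "genome.fa")
    rio.write_annotation_gff(dataset.annotation, out / "annotation.gff3")
    for label, (fwd, rev) in dataset.chip.items():
        rio.write_bedgraph(fwd, out / f"chip_{label}_fwd.bedgraph")
        rio.write_bedgraph(rev, out / f"chip_{label}_rev.bedgraph")
    rio.write_counts(dataset.counts, out / "counts.tsv", out / "samples.tsv")
    rio.write_membership(dataset.membership, out / "membership.tsv")
    rio.write_orthologs(dataset.orthologs, dataset.genome_groups,
                        out / "orthologs.tsv", out / "genome_groups.tsv")
    rio.write_growth(dataset.growth, out / "growth.tsv")
    truth_rows = [
        (s.center, s.start, s.end, s.tu_id or "", int(s.previously_known),
         int(s.has_signal), int(s.is_artifact))
        for s in dataset.truth.sites
    ]
    pd.DataFrame(
        truth_rows,
        columns=["center", "start", "end", "tu", "known", "has_signal", "artifact"],
    ).to_csv(out / "truth_sites.tsv", sep="\t", index=False)
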