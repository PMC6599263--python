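"""Seeded generator for every input the pipeline consumes.

Builds a toy genome/transcriptome, accrues mutations over time according to
a repair-defect process (MSS, MMR-deficient, POLE-mutant, MUTYH-mutant) with
signature-specific trinucleotide contexts, samples read counts at
configurable depth, emits per-gene depth profiles consistent with an integer
copy-number landscape, and assigns FPKM expression values.  Every stage
draws from its own stream spawned from the master seed, so stages are
independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .neoantigens import Transcript
from .signatures import bundled_signatures
from .variants import LineageTree, Variant, VariantCatalog, annotate_consequence

__all__ = [
    "SimConfig",
    "Reference",
    "SimError",
    "TimecourseResult",
    "make_reference",
    "simulate_timecourse",
    "simulate_counts",
    "simulate_depth_profile",
    "simulate_expression",
    "preset",
    "PRESETS",
]

PROCESSES = ("MSS", "MMRd", "POLEmut", "MUTYHmut")

_COMP = str.maketrans("ACGT", "TGCA")
_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


class SimError(ValueError):
    pass


@dataclass
class SimConfig:
    """All knobs of the synthetic study design."""

    seed: int = 0
    n_genes: int = 30
    n_chroms: int = 2
    gene_len_range: tuple[int, int] = (300, 601)  # CDS bp, multiple-of-3 enforced
    process: str = "MSS"
    snv_rate: float = 1.0  # events per day
    indel_rate: float = 0.2
    signature_weights: dict[str, float] = field(
        default_factory=lambda: {"SYN_FLAT": 1.0}
    )
    clonal_fraction: float = 0.4
    depth_mean: float = 150.0
    depth_dispersion: float = 20.0
    error_rate: float = 0.01
    n_initial: int = 60
    lost_fraction: float = 0.10
    allow_clonal_loss: bool = False
    n_artifacts: int = 0
    timepoints: tuple[tuple[str, float], ...] = (("T0", 0.0), ("T90", 90.0))
    lineage: Optional[dict[str, tuple[Optional[str], float]]] = None
    ploidy_profile: tuple[tuple[int, int], ...] = ()  # (n_genes, cn) runs
    het_per_gene: int = 12
    hla_alleles: tuple[str, ...] = ("HLA-A*02:01", "HLA-B*07:02")
    low_expression_fraction: float = 0.2
    terminal_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.process not in PROCESSES:
            raise SimError(f"unknown process {self.process!r}")
        if self.snv_rate < 0 or self.indel_rate < 0:
            raise SimError("rates must be nonnegative")
        if not 0.0 <= self.clonal_fraction <= 1.0:
            raise SimError("clonal_fraction outside [0,1]")
        if self.depth_mean <= 0:
            raise SimError("depth_mean must be positive")
        total = sum(self.signature_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise SimError(f"signature weights sum to {total}, expected 1")
        if any(cn < 0 or not isinstance(cn, int) for _, cn in self.ploidy_profile):
            raise SimError("copy numbers must be integers >= 0")
        if self.n_genes < 1:
            raise SimError("need at least one gene")

    def streams(self) -> dict[str, np.random.Generator]:
        """One independent generator per simulation stage."""
        names = ("reference", "timecourse", "counts", "depth", "expression")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class Reference:
    """Toy genome with forward-strand single-exon genes."""

    genome: dict[str, str]
    transcripts: dict[str, Transcript]
    gene_model: pd.DataFrame  # chrom, start, end, gene, transcript, ordinal

    def gene_bounds(self, gene: str) -> tuple[str, int, int]:
        row = self.gene_model[self.gene_model["gene"] == gene].iloc[0]
        return str(row["chrom"]), int(row["start"]), int(row["end"])

    def transcript_of_gene(self, gene: str) -> Transcript:
        row = self.gene_model[self.gene_model["gene"] == gene].iloc[0]
        return self.transcripts[str(row["transcript"])]


#: Codon pairs spelling a 6-bp homopolymer without stop codons.
_HOMOPOLYMER_PAIRS = (("AAA", "AAA"), ("TTT", "TTT"), ("CCC", "CCC"), ("GGG", "GGG"))


def _random_cds(rng: np.random.Generator, n_codons: int, homopolymer: bool) -> str:
    codons = []
    safe = [
        a + b + c
        for a in _BASES
        for b in _BASES
        for c in _BASES
        if a + b + c not in _STOPS and a + b + c != "ATG"
    ]
    for _ in range(n_codons - 2):
        codons.append(safe[rng.integers(len(safe))])
    if homopolymer:
        # pepper the CDS with 6-bp runs (slippage hotspots), one per ~10 codons
        step = 10
        for start in range(1, len(codons) - 1, step):
            pair = _HOMOPOLYMER_PAIRS[rng.integers(len(_HOMOPOLYMER_PAIRS))]
            codons[start : start + 2] = pair
    return "ATG" + "".join(codons) + "TAA"


def make_reference(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> Reference:
    """Deterministic toy genome, transcripts and gene model from the seed."""
    rng = rng if rng is not None else cfg.streams()["reference"]
    lo, hi = cfg.gene_len_range
    if lo < 30:
        raise SimError("genes shorter than 30 bp are not supported")
    genome: dict[str, str] = {}
    transcripts: dict[str, Transcript] = {}
    rows = []
    per_chrom = [
        cfg.n_genes // cfg.n_chroms + (1 if i < cfg.n_genes % cfg.n_chroms else 0)
        for i in range(cfg.n_chroms)
    ]
    ordinal = 0
    gene_idx = 0
    homopolymer = cfg.process == "MMRd"
    for ci, n_here in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        parts = []
        pos = 0
        for _ in range(n_here):
            spacer = "".join(rng.choice(list(_BASES), size=int(rng.integers(60, 121))))
            parts.append(spacer)
            pos += len(spacer)
            n_codons = int(rng.integers(lo, hi)) // 3
            cds = _random_cds(rng, n_codons, homopolymer)
            gene_idx += 1
            ordinal += 1
            gene = f"G{gene_idx:04d}"
            tx_id = f"TX{gene_idx:04d}"
            start = pos + 1  # 1-based, closed
            end = pos + len(cds)
            parts.append(cds)
            pos = end
            transcripts[tx_id] = Transcript(
                id=tx_id, gene=gene, cdna=cds, cds_start=1, cds_end=len(cds)
            )
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "gene": gene,
                    "transcript": tx_id,
                    "ordinal": ordinal,
                }
            )
        tail = "".join(rng.choice(list(_BASES), size=int(rng.integers(60, 121))))
        parts.append(tail)
        genome[chrom] = "".join(parts)
    return Reference(genome=genome, transcripts=transcripts, gene_model=pd.DataFrame(rows))


def _context_index(ref: Reference) -> dict[str, list[tuple[str, int, str]]]:
    """Map pyrimidine-centric trinucleotide context -> coding positions.

    Each entry is (chrom, pos, pyr) where ``pyr`` is the pyrimidine-strand
    representation; purine genome bases are indexed by the reverse complement
    of their context.
    """
    index: dict[str, list[tuple[str, int, str]]] = {}
    for row in ref.gene_model.itertuples():
        seq = ref.genome[row.chrom]
        for pos in range(row.start, row.end + 1):
            if pos < 2 or pos > len(seq) - 1:
                continue
            tri = seq[pos - 2 : pos + 1]
            base = tri[1]
            if base in "CT":
                key = tri
            else:
                key = tri.translate(_COMP)[::-1]
            index.setdefault(key, []).append((row.chrom, pos, key[1]))
    return index


def _homopolymer_sites(ref: Reference, min_run: int = 6) -> list[tuple[str, int, str]]:
    """Anchor positions (chrom, pos, run_base) just before homopolymer runs in CDS."""
    sites = []
    for row in ref.gene_model.itertuples():
        seq = ref.genome[row.chrom]
        cds = seq[row.start - 1 : row.end]
        i = 0
        while i < len(cds):
            j = i
            while j < len(cds) and cds[j] == cds[i]:
                j += 1
            if j - i >= min_run and i >= 1:
                sites.append((row.chrom, row.start + i - 1, cds[i]))
            i = j
    return sites


@dataclass
class _Event:
    variant: Variant
    af_true: float
    clonal: bool
    born: str  # node label where the event appeared


@dataclass
class TimecourseResult:
    """Catalogs per node plus ground truth for recovery tests."""

    catalogs: dict[str, VariantCatalog]
    parents: dict[str, Optional[str]]
    af_true: dict[str, dict[tuple, float]]  # node -> key -> true AF
    gained_truth: dict[str, int]  # node -> events born there (root: baseline size)
    lost_truth: dict[str, int]
    elapsed_days: dict[str, float]  # node -> days since its parent

    def tree(self) -> LineageTree:
        tree = LineageTree()
        for node in self.catalogs:
            tree.add_node(node, self.catalogs[node], self.parents[node])
        return tree


def _annotated_variant(
    ref: Reference,
    chrom: str,
    pos: int,
    vref: str,
    valt: str,
    gene_row,
) -> Variant:
    cds_pos = pos - gene_row.start + 1
    tx = ref.transcripts[gene_row.transcript]
    v = Variant(
        chrom=chrom,
        pos=pos,
        ref=vref,
        alt=valt,
        gene=gene_row.gene,
        transcript=gene_row.transcript,
        cds_pos=cds_pos,
    )
    v.consequence = annotate_consequence(v, tx.cds, cds_pos)
    return v


def simulate_timecourse(cfg: SimConfig, ref: Reference) -> TimecourseResult:
    """Accrue mutations along the timepoints (or lineage tree) of the config.

    New events per edge are Poisson(days x rate) for SNVs and indels
    separately; SNV contexts follow the configured signature mixture; the
    MMRd process places indels at homopolymer runs.  Clonal events get true
    AF 0.5, subclonal ones uniform AF in [0.05, 0.25].  At every non-root
    node a ``lost_fraction`` of inherited subclonal (and, when allowed,
    clonal) events is dropped.
    """
    rng = cfg.streams()["timecourse"]
    sigs = bundled_signatures()
    for name in cfg.signature_weights:
        if name not in sigs.names:
            raise SimError(f"unknown signature {name!r}")
    ctx_index = _context_index(ref)
    homopolymers = _homopolymer_sites(ref)
    gene_rows = {row.gene: row for row in ref.gene_model.itertuples()}
    gene_lookup: list = list(gene_rows.values())

    # signature mixture restricted to channels realizable on this genome
    weights = np.array([cfg.signature_weights.get(n, 0.0) for n in sigs.names])
    mix = sigs.profiles @ weights  # length 96 channel probabilities
    from .signatures import CHANNELS

    usable = np.array(
        [f"{c[0]}{c[2]}{c[6]}" in ctx_index for c in CHANNELS], dtype=bool
    )
    mix = np.where(usable, mix, 0.0)
    if mix.sum() == 0:
        raise SimError("no signature channel is realizable on this genome")
    mix = mix / mix.sum()

    if cfg.lineage is not None:
        nodes = dict(cfg.lineage)
        roots = [n for n, (p, _) in nodes.items() if p is None]
        if len(roots) != 1:
            raise SimError("lineage spec must have exactly one root")
    else:
        tps = list(cfg.timepoints)
        nodes = {tps[0][0]: (None, 0.0)}
        for (prev, t_prev), (label, t_now) in zip(tps, tps[1:]):
            if t_now <= t_prev:
                raise SimError("timepoints must be strictly increasing")
            nodes[label] = (prev, t_now - t_prev)

    used_keys: set[tuple] = set()

    def row_for(chrom: str, pos: int):
        for row in gene_lookup:
            if row.chrom == chrom and row.start <= pos <= row.end:
                return row
        return None

    def new_snv() -> Optional[Variant]:
        for _ in range(200):
            ch = int(rng.choice(96, p=mix))
            label = CHANNELS[ch]
            five, pyr_ref, alt_pyr, three = label[0], label[2], label[4], label[6]
            sites = ctx_index.get(f"{five}{pyr_ref}{three}")
            if not sites:
                continue
            chrom, pos, _ = sites[rng.integers(len(sites))]
            genome_ref = ref.genome[chrom][pos - 1]
            if genome_ref in "CT":
                vref, valt = genome_ref, alt_pyr
            else:
                vref = genome_ref
                valt = alt_pyr.translate(_COMP)
            if (chrom, pos, vref, valt) in used_keys:
                continue
            row = row_for(chrom, pos)
            if row is None:
                continue
            return _annotated_variant(ref, chrom, pos, vref, valt, row)
        return None

    def new_indel() -> Optional[Variant]:
        for attempt in range(200):
            if cfg.process == "MMRd" and homopolymers and attempt < 100:
                chrom, pos, base = homopolymers[rng.integers(len(homopolymers))]
                anchor = ref.genome[chrom][pos - 1]
                size = int(rng.integers(1, 3))
                if rng.random() < 0.7:  # slippage contraction
                    vref, valt = anchor + base * size, anchor
                else:
                    vref, valt = anchor, anchor + base * size
            else:
                row = gene_lookup[rng.integers(len(gene_lookup))]
                pos = int(rng.integers(row.start, row.end - 3))
                chrom = row.chrom
                anchor = ref.genome[chrom][pos - 1]
                size = int(rng.integers(1, 3))
                if rng.random() < 0.5:
                    vref = ref.genome[chrom][pos - 1 : pos + size]
                    valt = anchor
                else:
                    ins = "".join(rng.choice(list(_BASES), size=size))
                    vref, valt = anchor, anchor + ins
            if (chrom, pos, vref, valt) in used_keys:
                continue
            row = row_for(chrom, pos)
            if row is None or not (row.start <= pos <= row.end - len(vref) + 1):
                continue
            return _annotated_variant(ref, chrom, pos, vref, valt, row)
        return None

    def spawn_events(n_snv: int, n_indel: int, node: str) -> list[_Event]:
        events = []
        for kind, n in (("snv", n_snv), ("indel", n_indel)):
            for _ in range(n):
                v = new_snv() if kind == "snv" else new_indel()
                if v is None:
                    continue
                used_keys.add(v.key)
                clonal = bool(rng.random() < cfg.clonal_fraction)
                af = 0.5 if clonal else float(rng.uniform(0.05, 0.25))
                events.append(_Event(variant=v, af_true=af, clonal=clonal, born=node))
        return events

    # walk the tree from the root, inheriting and mutating event sets
    order: list[str] = []
    pending = [n for n, (p, _) in nodes.items() if p is None]
    while pending:
        cur = pending.pop(0)
        order.append(cur)
        pending.extend(n for n, (p, _) in nodes.items() if p == cur)

    events_at: dict[str, list[_Event]] = {}
    gained_truth: dict[str, int] = {}
    lost_truth: dict[str, int] = {}
    elapsed: dict[str, float] = {}
    for node in order:
        parent, days = nodes[node]
        elapsed[node] = days
        if parent is None:
            base = spawn_events(cfg.n_initial, 0, node)
            events_at[node] = base
            gained_truth[node] = len(base)
            lost_truth[node] = 0
            continue
        inherited = []
        n_lost = 0
        for ev in events_at[parent]:
            can_lose = (not ev.clonal) or cfg.allow_clonal_loss
            if can_lose and rng.random() < cfg.lost_fraction:
                n_lost += 1
                continue
            inherited.append(ev)
        n_snv = int(rng.poisson(days * cfg.snv_rate))
        n_indel = int(rng.poisson(days * cfg.indel_rate))
        born = spawn_events(n_snv, n_indel, node)
        events_at[node] = inherited + born
        gained_truth[node] = len(born)
        lost_truth[node] = n_lost

    catalogs = {}
    af_true = {}
    for node, events in events_at.items():
        catalogs[node] = VariantCatalog(
            sample_id=node, timepoint=node, variants=[e.variant.copy() for e in events]
        )
        af_true[node] = {e.variant.key: e.af_true for e in events}
    return TimecourseResult(
        catalogs=catalogs,
        parents={n: p for n, (p, _) in nodes.items()},
        af_true=af_true,
        gained_truth=gained_truth,
        lost_truth=lost_truth,
        elapsed_days=elapsed,
    )


def _nb_depths(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return np.maximum(rng.negative_binomial(dispersion, p, size=n), 1)


def simulate_counts(
    catalog: VariantCatalog,
    cfg: SimConfig,
    af_true: dict[tuple, float],
    rng: Optional[np.random.Generator] = None,
    ref: Optional[Reference] = None,
) -> VariantCatalog:
    """Sample depth/alt/strand counts for every variant of a catalog.

    depth ~ NegBin(depth_mean, depth_dispersion); alt ~ Binomial(depth, AF);
    a small fraction of alt reads is deducted as read-terminal support before
    the remainder splits evenly across strands.  When ``ref`` is given,
    ``n_artifacts`` background artifact variants (true AF 2%, some
    single-stranded) are injected to exercise the filter cascade.
    """
    rng = rng if rng is not None else cfg.streams()["counts"]
    variants = catalog.sorted_variants()
    depths = _nb_depths(rng, len(variants), cfg.depth_mean, cfg.depth_dispersion)
    out = []
    for v, depth in zip(variants, depths):
        af = af_true.get(v.key)
        if af is None:
            raise SimError(f"no true AF recorded for {v.key}")
        alt = int(rng.binomial(depth, af))
        non_terminal = alt - int(rng.binomial(alt, cfg.terminal_fraction))
        fwd = int(rng.binomial(non_terminal, 0.5))
        out.append(
            v.copy(
                depth=int(depth),
                alt_count=alt,
                alt_fwd=fwd,
                alt_rev=non_terminal - fwd,
            )
        )
    if cfg.n_artifacts and ref is not None:
        existing = {v.key for v in out}
        rows = list(ref.gene_model.itertuples())
        n_made = 0
        while n_made < cfg.n_artifacts:
            row = rows[rng.integers(len(rows))]
            pos = int(rng.integers(row.start, row.end + 1))
            base = ref.genome[row.chrom][pos - 1]
            alt_base = _BASES[rng.integers(4)]
            if alt_base == base:
                continue
            key = (row.chrom, pos, base, alt_base)
            if key in existing:
                continue
            existing.add(key)
            depth = int(_nb_depths(rng, 1, cfg.depth_mean, cfg.depth_dispersion)[0])
            alt = max(int(rng.binomial(depth, 0.02)), 1)
            if rng.random() < 0.5:  # single-strand artifact
                fwd, rev = (alt, 0) if rng.random() < 0.5 else (0, alt)
            else:
                fwd = int(rng.binomial(alt, 0.5))
                rev = alt - fwd
            out.append(
                Variant(
                    chrom=row.chrom,
                    pos=pos,
                    ref=base,
                    alt=alt_base,
                    depth=depth,
                    alt_count=alt,
                    alt_fwd=fwd,
                    alt_rev=rev,
                    gene=row.gene,
                )
            )
            n_made += 1
    return catalog.with_variants(out)


@dataclass
class DepthProfileTruth:
    profile: "pd.DataFrame"
    cn_by_ordinal: dict[int, int]
    segments: list[tuple[str, int, int, int]]  # chrom, start, end, cn
    afs_by_gene: dict[str, list[float]]


def simulate_depth_profile(
    cfg: SimConfig,
    ref: Reference,
    rng: Optional[np.random.Generator] = None,
) -> DepthProfileTruth:
    """Per-gene median depths and heterozygous AFs for a CN landscape.

    The config's ``ploidy_profile`` is consumed along gene order as
    (n_genes, cn) runs; any remainder is diploid.  Gene depth scales as
    CN/2 with mild lognormal noise; each gene contributes ``het_per_gene``
    heterozygous AFs drawn binomially around k/CN.
    """
    rng = rng if rng is not None else cfg.streams()["depth"]
    model = ref.gene_model
    cn_by_ordinal: dict[int, int] = {}
    runs = list(cfg.ploidy_profile)
    ordinals = model["ordinal"].tolist()
    i = 0
    for n_run, cn in runs:
        for _ in range(n_run):
            if i >= len(ordinals):
                break
            cn_by_ordinal[ordinals[i]] = cn
            i += 1
    while i < len(ordinals):
        cn_by_ordinal[ordinals[i]] = 2
        i += 1

    rows = []
    afs_by_gene: dict[str, list[float]] = {}
    for row in model.itertuples():
        cn = cn_by_ordinal[row.ordinal]
        scale = cn / 2.0 if cn > 0 else 0.02
        depth = cfg.depth_mean * scale * float(np.exp(rng.normal(0.0, 0.05)))
        rows.append(
            {
                "chrom": row.chrom,
                "ordinal": row.ordinal,
                "gene": row.gene,
                "median_depth": depth,
            }
        )
        afs: list[float] = []
        if cn >= 1:
            for _ in range(cfg.het_per_gene):
                k = int(rng.integers(1, cn)) if cn > 1 else cn
                d = int(_nb_depths(rng, 1, max(depth, 1.0), cfg.depth_dispersion)[0])
                afs.append(rng.binomial(d, k / cn) / d)
        afs_by_gene[row.gene] = afs

    segments = []
    for chrom, sub in model.groupby("chrom", sort=False):
        ords = sorted(sub["ordinal"])
        start = ords[0]
        cur = cn_by_ordinal[start]
        prev = start
        for o in ords[1:]:
            if cn_by_ordinal[o] != cur:
                segments.append((chrom, start, prev, cur))
                start, cur = o, cn_by_ordinal[o]
            prev = o
        segments.append((chrom, start, prev, cur))
    return DepthProfileTruth(
        profile=pd.DataFrame(rows),
        cn_by_ordinal=cn_by_ordinal,
        segments=segments,
        afs_by_gene=afs_by_gene,
    )


def simulate_expression(
    ref: Reference,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Log-normal FPKM per gene; a configured fraction forced below 10."""
    rng = rng if rng is not None else cfg.streams()["expression"]
    genes = ref.gene_model["gene"].tolist()
    fpkm = np.exp(rng.normal(math.log(40.0), 0.8, size=len(genes)))
    n_low = int(round(cfg.low_expression_fraction * len(genes)))
    low_idx = rng.choice(len(genes), size=n_low, replace=False)
    fpkm[low_idx] = rng.uniform(0.0, 5.0, size=n_low)
    return pd.DataFrame({"gene": genes, "fpkm": fpkm})


def preset(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Named study designs mirroring the in-vitro and xenograft experiments."""
    if name not in PRESETS:
        raise SimError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return SimConfig(seed=seed, **params)


_PDX_LINEAGE = {
    "F1": (None, 0.0),
    "F2": ("F1", 60.0),
    "F3": ("F2", 60.0),
    "F4": ("F3", 60.0),
}

PRESETS: dict[str, dict] = {
    "mss": dict(
        process="MSS",
        snv_rate=0.8,
        indel_rate=0.2,
        signature_weights={"SYN_CPG": 0.5, "SYN_FLAT": 0.5},
        clonal_fraction=0.5,
    ),
    "msi": dict(
        process="MMRd",
        snv_rate=8.0,
        indel_rate=12.0,
        signature_weights={"SYN_MMR": 0.8, "SYN_FLAT": 0.2},
        clonal_fraction=0.6,
    ),
    "pole": dict(
        process="POLEmut",
        snv_rate=25.0,
        indel_rate=1.0,
        signature_weights={"SYN_POLE": 0.8, "SYN_FLAT": 0.2},
        clonal_fraction=0.6,
    ),
    "mutyh": dict(
        process="MUTYHmut",
        snv_rate=12.0,
        indel_rate=1.0,
        signature_weights={"SYN_MUTYH": 0.8, "SYN_FLAT": 0.2},
        clonal_fraction=0.6,
    ),
    "pdx": dict(
        process="MMRd",
        snv_rate=6.0,
        indel_rate=8.0,
        signature_weights={"SYN_MMR": 0.8, "SYN_FLAT": 0.2},
        clonal_fraction=0.5,
        allow_clonal_loss=True,
        lineage=_PDX_LINEAGE,
    ),
}
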