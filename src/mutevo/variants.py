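"""Somatic variant model, the filter cascade, subtraction and burden metrics.

A :class:`Variant` records one alteration with its read support; a
:class:`VariantCatalog` is the set of variants seen in one sample at one
timepoint or xenograft generation.  The filter cascade removes strand-biased
calls, low-frequency / noise-compatible calls (exact binomial upper tail)
and anything present in a germline/artifact database (dbSNP-style set or a
panel of normals).  Subtraction between timepoints yields gained and lost
variants; a :class:`LineageTree` generalizes this to serially passaged
generations, each compared against its immediate parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from scipy.stats import binom

__all__ = [
    "Variant",
    "VariantCatalog",
    "FilterConfig",
    "LineageTree",
    "SubtractionResult",
    "VariantError",
    "strand_filter",
    "af_binomial_filter",
    "database_filter",
    "filter_reasons",
    "apply_filters",
    "subtract",
    "lineage_subtract",
    "tmb",
    "annotate_consequence",
    "ns_s_ratio",
    "NONSYNONYMOUS",
    "CONSEQUENCES",
]

VariantKey = tuple[str, int, str, str]

#: Recognized consequence labels.
CONSEQUENCES = (
    "synonymous",
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "noncoding",
)

#: Consequences counted as non-synonymous for the NS:S ratio.
NONSYNONYMOUS = frozenset({"missense", "nonsense", "frameshift"})

#: Consequences counted as coding for mutational burden.
CODING = frozenset(
    {"synonymous", "missense", "nonsense", "frameshift", "inframe_indel"}
)

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class VariantError(ValueError):
    """Raised for invalid variants or invalid filter/annotation inputs."""


def _infer_vclass(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "INS"
    if len(alt) < len(ref):
        return "DEL"
    raise VariantError(f"cannot classify ref={ref!r} alt={alt!r} (MNV unsupported)")


@dataclass
class Variant:
    """One somatic alteration with read support and optional annotation.

    Coordinates are 1-based and fully closed (VCF convention); indels carry
    a leading anchor base in both ``ref`` and ``alt``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int = 0
    alt_count: int = 0
    alt_fwd: Optional[int] = None
    alt_rev: Optional[int] = None
    gene: Optional[str] = None
    transcript: Optional[str] = None
    cds_pos: Optional[int] = None
    consequence: Optional[str] = None
    vclass: str = field(init=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise VariantError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise VariantError(f"identity variant at {self.chrom}:{self.pos}")
        bad = set(self.ref + self.alt) - set("ACGTN")
        if bad:
            raise VariantError(f"non-nucleotide characters {bad}")
        self.vclass = _infer_vclass(self.ref, self.alt)
        if not 0 <= self.alt_count <= self.depth:
            raise VariantError(
                f"alt_count {self.alt_count} outside [0, depth={self.depth}]"
            )
        if (self.alt_fwd is None) != (self.alt_rev is None):
            raise VariantError("alt_fwd and alt_rev must be set together")
        if self.alt_fwd is not None:
            if self.alt_fwd < 0 or self.alt_rev < 0:
                raise VariantError("negative strand counts")
            if self.alt_fwd + self.alt_rev > self.alt_count:
                raise VariantError("alt_fwd + alt_rev exceeds alt_count")
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise VariantError(f"unknown consequence {self.consequence!r}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def af(self) -> float:
        """Allelic frequency alt_count / depth (0 when depth is 0)."""
        return self.alt_count / self.depth if self.depth else 0.0

    def copy(self, **changes) -> "Variant":
        return replace(self, **changes)


class VariantCatalog:
    """Variants for one sample at one timepoint, keyed by (chrom,pos,ref,alt)."""

    def __init__(
        self,
        sample_id: str,
        timepoint: str = "T0",
        variants: Iterable[Variant] = (),
    ) -> None:
        self.sample_id = sample_id
        self.timepoint = timepoint
        self._variants: dict[VariantKey, Variant] = {}
        for v in variants:
            self.add(v)

    def add(self, v: Variant) -> None:
        if v.key in self._variants:
            raise VariantError(f"duplicate variant key {v.key}")
        self._variants[v.key] = v

    def get(self, key: VariantKey) -> Optional[Variant]:
        return self._variants.get(key)

    def keys(self) -> set[VariantKey]:
        return set(self._variants)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._variants

    def __iter__(self) -> Iterator[Variant]:
        return iter(self._variants.values())

    def __len__(self) -> int:
        return len(self._variants)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantCatalog):
            return NotImplemented
        return self._variants.keys() == other._variants.keys()

    def sorted_variants(self) -> list[Variant]:
        return [self._variants[k] for k in sorted(self._variants)]

    def with_variants(self, variants: Iterable[Variant], timepoint=None) -> "VariantCatalog":
        return VariantCatalog(
            self.sample_id,
            self.timepoint if timepoint is None else timepoint,
            variants,
        )

    def __repr__(self) -> str:
        return (
            f"VariantCatalog({self.sample_id!r}, {self.timepoint!r}, "
            f"n={len(self)})"
        )


@dataclass
class FilterConfig:
    """Thresholds and databases for the somatic filter cascade."""

    min_af: float = 0.10
    alpha: float = 0.05
    error_rate: float = 0.01
    dbsnp_keys: frozenset[VariantKey] = frozenset()
    pon_keys: frozenset[VariantKey] = frozenset()

    def __post_init__(self) -> None:
        if not 0 < self.min_af < 1:
            raise VariantError(f"min_af out of (0,1): {self.min_af}")
        if not 0 < self.alpha < 1:
            raise VariantError(f"alpha out of (0,1): {self.alpha}")
        if not 0 < self.error_rate < self.min_af:
            raise VariantError(
                f"error_rate must lie in (0, min_af): {self.error_rate}"
            )
        self.dbsnp_keys = frozenset(self.dbsnp_keys)
        self.pon_keys = frozenset(self.pon_keys)


def strand_filter(v: Variant) -> bool:
    """Keep only alleles supported by both strands.

    Strand counts exclude read-terminal positions; a variant whose
    non-terminal support is confined to a single strand is discarded.
    """
    if v.alt_fwd is None or v.alt_rev is None:
        raise VariantError(f"strand counts missing for {v.key}")
    return v.alt_fwd >= 1 and v.alt_rev >= 1


def binomial_pvalue(alt_count: int, depth: int, error_rate: float) -> float:
    """Exact upper-tail P(X >= alt_count) for X ~ Binomial(depth, error_rate)."""
    if depth < 1:
        raise VariantError("depth must be >= 1 for the binomial test")
    # sf is exclusive of the bound, so shift by one to include it
    return float(binom.sf(alt_count - 1, depth, error_rate))


def af_binomial_filter(v: Variant, cfg: FilterConfig) -> bool:
    """Keep iff AF >= min_af and the exact binomial noise p-value <= alpha."""
    if v.depth < 1:
        raise VariantError(f"zero depth for {v.key}")
    if v.af < cfg.min_af:
        return False
    return binomial_pvalue(v.alt_count, v.depth, cfg.error_rate) <= cfg.alpha


def database_filter(v: Variant, cfg: FilterConfig) -> bool:
    """Keep iff the variant key is in neither the dbSNP set nor the panel of normals."""
    return v.key not in cfg.dbsnp_keys and v.key not in cfg.pon_keys


def filter_reasons(v: Variant, cfg: FilterConfig) -> list[str]:
    """All cascade failure reasons for one variant (empty list = PASS)."""
    reasons: list[str] = []
    try:
        if not strand_filter(v):
            reasons.append("strand_bias")
        if v.depth < 1:
            raise VariantError(f"zero depth for {v.key}")
        if v.af < cfg.min_af:
            reasons.append("low_af")
        if binomial_pvalue(v.alt_count, v.depth, cfg.error_rate) > cfg.alpha:
            reasons.append("binom_p")
        if v.key in cfg.dbsnp_keys:
            reasons.append("dbsnp")
        if v.key in cfg.pon_keys:
            reasons.append("pon")
    except VariantError as exc:
        raise VariantError(f"variant {v.key}: {exc}") from None
    return reasons


def apply_filters(cat: VariantCatalog, cfg: FilterConfig) -> VariantCatalog:
    """Run the filter cascade (strand, AF/binomial, databases) over a catalog.

    The output is a subset of the input and re-applying is a no-op.
    """
    kept = [v for v in cat if not filter_reasons(v, cfg)]
    return cat.with_variants(kept)


@dataclass
class SubtractionResult:
    """Gained/lost catalogs plus AF pairs for keys shared by both timepoints."""

    gained: VariantCatalog
    lost: VariantCatalog
    shared_afs: dict[VariantKey, tuple[float, float]]  # key -> (earlier, later)
    baseline: bool = False


def subtract(later: VariantCatalog, earlier: VariantCatalog) -> SubtractionResult:
    """Compare two catalogs of one lineage: gained = later-only, lost = earlier-only.

    Shared keys keep both allelic frequencies so trunk (clonal) variants can
    be told apart from subclonal turnover.
    """
    later_keys = later.keys()
    earlier_keys = earlier.keys()
    gained = later.with_variants(
        v for v in later if v.key not in earlier_keys
    )
    lost = earlier.with_variants(
        (v for v in earlier if v.key not in later_keys),
        timepoint=earlier.timepoint,
    )
    shared = {
        k: (earlier.get(k).af, later.get(k).af)
        for k in later_keys & earlier_keys
    }
    return SubtractionResult(gained=gained, lost=lost, shared_afs=shared)


class LineageTree:
    """Sample lineage (e.g., xenograft generations) with a catalog per node."""

    def __init__(self) -> None:
        self._parent: dict[str, Optional[str]] = {}
        self._catalog: dict[str, VariantCatalog] = {}

    def add_node(
        self,
        node: str,
        catalog: VariantCatalog,
        parent: Optional[str] = None,
    ) -> None:
        if node in self._parent:
            raise VariantError(f"duplicate node {node!r}")
        self._parent[node] = parent
        self._catalog[node] = catalog

    @property
    def nodes(self) -> list[str]:
        return list(self._parent)

    def parent(self, node: str) -> Optional[str]:
        return self._parent[node]

    def catalog(self, node: str) -> VariantCatalog:
        return self._catalog[node]

    def roots(self) -> list[str]:
        return [n for n, p in self._parent.items() if p is None]

    def validate(self) -> None:
        roots = self.roots()
        if len(roots) != 1:
            raise VariantError(f"expected a single root, found {len(roots)}")
        for node, parent in self._parent.items():
            if parent is not None and parent not in self._parent:
                raise VariantError(f"node {node!r} has unknown parent {parent!r}")
            seen = {node}
            cur = parent
            while cur is not None:
                if cur in seen:
                    raise VariantError(f"cycle through {cur!r}")
                seen.add(cur)
                cur = self._parent[cur]


def lineage_subtract(tree: LineageTree) -> dict[str, SubtractionResult]:
    """Generation-wise subtraction: every node is compared to its parent.

    The root carries no parent and is reported as the baseline: its full
    catalog appears as ``gained`` with ``baseline=True``.
    """
    tree.validate()
    out: dict[str, SubtractionResult] = {}
    for node in tree.nodes:
        parent = tree.parent(node)
        cat = tree.catalog(node)
        if parent is None:
            out[node] = SubtractionResult(
                gained=cat,
                lost=cat.with_variants(()),
                shared_afs={},
                baseline=True,
            )
        else:
            out[node] = subtract(cat, tree.catalog(parent))
    return out


def tmb(cat: VariantCatalog, coding_mb: float = 38.0) -> float:
    """Tumor mutational burden: coding variants per megabase.

    Variants must already be consequence-annotated; anything labeled
    ``noncoding`` (or unannotated) is not counted.
    """
    if coding_mb <= 0:
        raise VariantError(f"coding_mb must be positive, got {coding_mb}")
    n_coding = sum(1 for v in cat if v.consequence in CODING)
    return n_coding / coding_mb


def _translate_codon(codon: str) -> str:
    try:
        return _CODON_TABLE[codon.upper()]
    except KeyError:
        raise VariantError(f"untranslatable codon {codon!r}") from None


def annotate_consequence(
    v: Variant,
    cdna: Optional[str],
    cds_pos: Optional[int] = None,
) -> str:
    """Classify a variant against a coding sequence.

    ``cdna`` is the transcript coding sequence (frame starting at base 1)
    and ``cds_pos`` the 1-based position of the variant within it; when the
    variant lies outside any CDS, pass ``cdna=None`` to obtain ``noncoding``.
    SNVs are classified by codon translation; indels by length modulo 3.
    """
    if cdna is None:
        return "noncoding"
    pos = cds_pos if cds_pos is not None else v.cds_pos
    if pos is None:
        raise VariantError(f"cds_pos required to annotate {v.key}")
    if not 1 <= pos <= len(cdna):
        raise VariantError(f"cds_pos {pos} outside CDS of length {len(cdna)}")
    if cdna[pos - 1 : pos - 1 + len(v.ref)].upper() != v.ref.upper():
        raise VariantError(
            f"reference mismatch at CDS pos {pos}: expected {v.ref!r}, "
            f"found {cdna[pos - 1 : pos - 1 + len(v.ref)]!r}"
        )
    if v.vclass != "SNV":
        indel_len = abs(len(v.alt) - len(v.ref))
        return "frameshift" if indel_len % 3 else "inframe_indel"
    codon_index = (pos - 1) // 3
    offset = (pos - 1) % 3
    codon = cdna[codon_index * 3 : codon_index * 3 + 3].upper()
    if len(codon) < 3:
        raise VariantError(f"CDS length {len(cdna)} not a multiple of 3")
    mutant = codon[:offset] + v.alt.upper() + codon[offset + 1 :]
    aa_ref = _translate_codon(codon)
    aa_alt = _translate_codon(mutant)
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "missense"


def ns_s_ratio(cat: VariantCatalog) -> Optional[float]:
    """Non-synonymous over synonymous count; ``None`` when no synonymous calls."""
    ns = sum(1 for v in cat if v.consequence in NONSYNONYMOUS)
    s = sum(1 for v in cat if v.consequence == "synonymous")
    if s == 0:
        return None
    return ns / s
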