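"""Mutant peptide enumeration and neoantigen-candidate calling.

Given a gained variant inside a transcript CDS, the cDNA is edited at the
variant position, translated, and every 8-11-mer window containing altered
residues is collected; windows identical to a wild-type k-mer are dropped.
Peptides are scored against HLA alleles through a pluggable binding
predictor (percentile rank; rank < 0.5 is a strong binder) and candidates
are kept only when the source gene is expressed above 10 FPKM.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence

from .variants import Variant, VariantCatalog, annotate_consequence

__all__ = [
    "Transcript",
    "BindingPrediction",
    "NeoantigenCandidate",
    "NeoantigenError",
    "BindingPredictor",
    "MockPredictor",
    "mutate_cdna",
    "translate_cds",
    "enumerate_mutant_peptides",
    "predict_binding",
    "call_neoantigens",
    "CallSummary",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")

_STOPS = {"TAA", "TAG", "TGA"}

_CODONS = {
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


class NeoantigenError(ValueError):
    pass


@dataclass
class Transcript:
    """A cDNA with its CDS interval (1-based, closed) and gene of origin."""

    id: str
    gene: str
    cdna: str
    cds_start: int
    cds_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        self.cdna = self.cdna.upper()
        if not 1 <= self.cds_start <= self.cds_end <= len(self.cdna):
            raise NeoantigenError(
                f"{self.id}: CDS [{self.cds_start},{self.cds_end}] outside cDNA"
            )
        if (self.cds_end - self.cds_start + 1) % 3:
            raise NeoantigenError(f"{self.id}: CDS length not divisible by 3")
        if self.strand not in "+-":
            raise NeoantigenError(f"{self.id}: bad strand {self.strand!r}")

    @property
    def cds(self) -> str:
        return self.cdna[self.cds_start - 1 : self.cds_end]

    @property
    def protein(self) -> str:
        return translate_cds(self.cds)


@dataclass(frozen=True)
class BindingPrediction:
    """Predicted percentile rank of one peptide on one HLA allele."""

    peptide: str
    hla: str
    rank: float

    def __post_init__(self) -> None:
        if not 8 <= len(self.peptide) <= 11:
            raise NeoantigenError(f"peptide length {len(self.peptide)} outside 8-11")
        if self.rank < 0:
            raise NeoantigenError("rank must be nonnegative")


@dataclass(frozen=True)
class NeoantigenCandidate:
    """A mutant peptide that survived the rank and expression filters."""

    peptide: str
    hla: str
    rank: float
    variant_key: tuple
    gene: str
    fpkm: float
    source_class: str  # "SNV" or "frameshift"


class BindingPredictor(Protocol):
    """Adapter contract for MHC binding predictors.

    A real NetMHC-style wrapper must implement ``score(peptide, allele)``
    returning the percentile rank (0-100, smaller = stronger binder).
    """

    def score(self, peptide: str, allele: str) -> float: ...


class MockPredictor:
    """Deterministic hash-based stand-in for an external binding predictor.

    Ranks are uniform on [0, 100) as a function of (seed, allele, peptide)
    only, so runs are reproducible without the external tool.  ``strong_frac``
    rescales a slice of the hash space into the strong-binder range so that
    simulations yield a controllable hit rate.
    """

    def __init__(self, seed: int = 0, strong_frac: float = 0.0) -> None:
        if not 0.0 <= strong_frac <= 1.0:
            raise NeoantigenError("strong_frac must lie in [0,1]")
        self.seed = seed
        self.strong_frac = strong_frac

    def score(self, peptide: str, allele: str) -> float:
        digest = hashlib.sha256(
            f"{self.seed}|{allele}|{peptide}".encode()
        ).digest()
        u = int.from_bytes(digest[:8], "big") / 2**64
        if self.strong_frac and u < self.strong_frac:
            # remap the lowest slice onto strong-binder ranks [0, 0.5)
            return 0.5 * u / self.strong_frac
        return 100.0 * u


def translate_cds(cds: str, to_first_stop: bool = True) -> str:
    """Translate a coding sequence, halting at the first stop codon."""
    aa = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3].upper()
        if "N" in codon:
            break
        res = _CODONS[codon]
        if res == "*":
            if to_first_stop:
                break
            aa.append("*")
            continue
        aa.append(res)
    return "".join(aa)


def mutate_cdna(tx: Transcript, v: Variant) -> str:
    """Apply a variant (given via ``v.cds_pos``) to the transcript cDNA.

    SNVs substitute one base; indels follow the VCF anchor-base convention
    (ref and alt share their first base at ``cds_pos``).
    """
    if v.cds_pos is None:
        raise NeoantigenError(f"variant {v.key} lacks cds_pos")
    cds_len = tx.cds_end - tx.cds_start + 1
    if not 1 <= v.cds_pos <= cds_len:
        raise NeoantigenError(
            f"variant {v.key} cds_pos {v.cds_pos} outside CDS (len {cds_len})"
        )
    idx = tx.cds_start - 1 + v.cds_pos - 1  # 0-based index into cdna
    observed = tx.cdna[idx : idx + len(v.ref)]
    if observed != v.ref.upper():
        raise NeoantigenError(
            f"reference mismatch for {v.key} in {tx.id}: "
            f"cDNA has {observed!r}, variant ref {v.ref!r}"
        )
    return tx.cdna[:idx] + v.alt.upper() + tx.cdna[idx + len(v.ref) :]


def _kmers(protein: str, kmin: int, kmax: int) -> set[str]:
    out: set[str] = set()
    for k in range(kmin, kmax + 1):
        out.update(protein[i : i + k] for i in range(len(protein) - k + 1))
    return out


def enumerate_mutant_peptides(
    tx: Transcript,
    v: Variant,
    kmin: int = 8,
    kmax: int = 11,
) -> set[str]:
    """All mutant 8-11-mers carrying altered residues, minus wild-type k-mers.

    Missense: windows containing the substituted residue.  Frameshift and
    inframe indels: windows overlapping any residue from the variant codon
    through the (possibly new) C-terminus.  Synonymous and nonsense-only
    edits yield the empty set.
    """
    if v.cds_pos is None:
        raise NeoantigenError(f"variant {v.key} lacks cds_pos")
    consequence = annotate_consequence(v, tx.cds, v.cds_pos)
    if consequence in ("synonymous", "noncoding"):
        return set()

    wt_protein = tx.protein
    mutant_cdna = mutate_cdna(tx, v)
    mutant_cds = mutant_cdna[tx.cds_start - 1 :]
    mut_protein = translate_cds(mutant_cds)

    first_codon = (v.cds_pos - 1) // 3  # 0-based residue index of first change
    if consequence == "missense":
        changed = {first_codon}
    else:
        # indels (and nonsense truncations) alter everything downstream
        changed = set(range(first_codon, len(mut_protein)))
    if not changed:
        return set()

    wt_kmers = _kmers(wt_protein, kmin, kmax)
    peptides: set[str] = set()
    for k in range(kmin, kmax + 1):
        for start in range(len(mut_protein) - k + 1):
            if any(start <= c < start + k for c in changed):
                pep = mut_protein[start : start + k]
                if pep not in wt_kmers:
                    peptides.add(pep)
    return peptides


def predict_binding(
    peptides: Iterable[str],
    alleles: Sequence[str],
    predictor: BindingPredictor,
) -> list[BindingPrediction]:
    """Score every (peptide, allele) pair; order follows the inputs."""
    preds = []
    for pep in peptides:
        if set(pep) - _AA:
            raise NeoantigenError(f"non-amino-acid characters in peptide {pep!r}")
        for allele in alleles:
            preds.append(BindingPrediction(pep, allele, predictor.score(pep, allele)))
    return preds


@dataclass
class CallSummary:
    """Per-sample accounting of the neoantigen calling run."""

    n_candidates: int = 0
    n_unique_peptide_hla: int = 0
    by_source: dict = None
    dropped_no_expression: int = 0
    dropped_missing_gene: int = 0

    def __post_init__(self) -> None:
        if self.by_source is None:
            self.by_source = {"SNV": 0, "frameshift": 0}


def call_neoantigens(
    gained: VariantCatalog,
    transcripts: Mapping[str, Transcript],
    expression: Mapping[str, float],
    alleles: Sequence[str],
    predictor: BindingPredictor,
    kmin: int = 8,
    kmax: int = 11,
    rank_cutoff: float = 0.5,
    fpkm_cutoff: float = 10.0,
) -> tuple[list[NeoantigenCandidate], CallSummary]:
    """Full candidate calling: enumerate, score, then apply rank and FPKM filters.

    Keeps candidates with rank < ``rank_cutoff`` (strict) and source-gene
    FPKM > ``fpkm_cutoff`` (strict).  Variants in genes missing from the
    expression table are dropped and tallied.  SNV-derived and
    frameshift-derived candidates are counted separately (inframe indels
    count with SNVs as substitution-style sources).
    """
    candidates: list[NeoantigenCandidate] = []
    summary = CallSummary()
    for v in sorted(gained, key=lambda x: x.key):
        if v.transcript is None or v.transcript not in transcripts:
            continue
        tx = transcripts[v.transcript]
        if tx.gene not in expression:
            summary.dropped_missing_gene += 1
            continue
        fpkm = float(expression[tx.gene])
        peptides = enumerate_mutant_peptides(tx, v, kmin=kmin, kmax=kmax)
        if not peptides:
            continue
        if not fpkm > fpkm_cutoff:
            summary.dropped_no_expression += 1
            continue
        source = "frameshift" if v.consequence == "frameshift" or (
            v.consequence is None
            and annotate_consequence(v, tx.cds, v.cds_pos) == "frameshift"
        ) else "SNV"
        for pred in predict_binding(sorted(peptides), alleles, predictor):
            if pred.rank < rank_cutoff:
                candidates.append(
                    NeoantigenCandidate(
                        peptide=pred.peptide,
                        hla=pred.hla,
                        rank=pred.rank,
                        variant_key=v.key,
                        gene=tx.gene,
                        fpkm=fpkm,
                        source_class=source,
                    )
                )
                summary.by_source[source] += 1
    summary.n_candidates = len(candidates)
    summary.n_unique_peptide_hla = len({(c.peptide, c.hla) for c in candidates})
    return candidates, summary
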