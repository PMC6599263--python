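"""Trinucleotide mutation spectra, signature refitting and exposure clustering.

Substitutions are keyed by the pyrimidine of the mutated Watson-Crick pair:
six subtypes (C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 16 possible
5'/3' flanking-base combinations give the canonical 96 channels.  Exposures
of a sample spectrum to a signature matrix are refit by nonnegative least
squares; exposure profiles across samples are clustered with Euclidean
distance and average linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.optimize import nnls

__all__ = [
    "SUBSTITUTION_TYPES",
    "CHANNELS",
    "MutationSpectrum96",
    "SignatureMatrix",
    "ExposureVector",
    "InsufficientMutationsError",
    "SignatureError",
    "channel_for",
    "build_spectrum",
    "fit_exposures",
    "cluster_exposures",
    "linkage_to_tree",
    "bundled_signatures",
]

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Canonical channel order: substitution subtypes in the order above, and
#: within each subtype the 16 flank pairs alphabetical by (5' base, 3' base).
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in _BASES
    for three in _BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


class SignatureError(ValueError):
    """Raised for malformed spectra or signature matrices."""


class InsufficientMutationsError(SignatureError):
    """Raised when a sample has too few mutations to refit (minimum 10)."""


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def channel_for(ref: str, alt: str, five: str, three: str) -> str:
    """Map a single-base substitution with its flanks to its 96-channel label.

    Purine-reference substitutions are reverse-complemented (allele and both
    flanks) so every channel is pyrimidine-centric.
    """
    ref, alt, five, three = (x.upper() for x in (ref, alt, five, three))
    if ref in "AG":
        ref, alt = _revcomp(ref), _revcomp(alt)
        five, three = _revcomp(three), _revcomp(five)
    label = f"{five}[{ref}>{alt}]{three}"
    if label not in _CHANNEL_INDEX:
        raise SignatureError(f"invalid substitution context {label}")
    return label


@dataclass
class MutationSpectrum96:
    """96-channel trinucleotide catalog of SNV counts for one sample."""

    counts: np.ndarray
    sample_id: str = ""
    skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise SignatureError(f"expected 96 counts, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise SignatureError("negative channel counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CHANNELS, self.counts))


@dataclass
class SignatureMatrix:
    """96 x S matrix of per-signature channel probabilities (columns sum to 1)."""

    names: Sequence[str]
    profiles: np.ndarray

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (96, len(self.names)):
            raise SignatureError(
                f"profiles shape {self.profiles.shape} does not match "
                f"96 x {len(self.names)}"
            )
        if np.any(self.profiles < 0):
            raise SignatureError("negative signature probabilities")
        sums = self.profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = [self.names[i] for i in np.where(~np.isclose(sums, 1.0, atol=1e-9))[0]]
            raise SignatureError(f"signature columns not normalized: {bad}")

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        return self.profiles[:, self.names.index(name)]


@dataclass
class ExposureVector:
    """Fitted signature contributions for one sample (raw counts scale)."""

    names: Sequence[str]
    raw: np.ndarray
    residual: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (len(self.names),):
            raise SignatureError("exposure length does not match signature names")
        if np.any(self.raw < -1e-12):
            raise SignatureError("negative exposures")
        self.raw = np.clip(self.raw, 0.0, None)

    @property
    def normalized(self) -> np.ndarray:
        total = self.raw.sum()
        if total == 0:
            return np.zeros_like(self.raw)
        return self.raw / total

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.raw))


def build_spectrum(
    cat,
    genome: Mapping[str, str],
    sample_id: Optional[str] = None,
) -> MutationSpectrum96:
    """Bin a catalog's SNVs into the 96 trinucleotide channels.

    ``genome`` maps chromosome name to sequence (1-based positions map to
    ``seq[pos-1]``).  Indels are ignored; SNVs whose +/-1 bp context is
    unavailable (contig edge or unknown chromosome) are skipped and tallied.
    """
    counts = np.zeros(96)
    skipped = 0
    for v in cat:
        if v.vclass != "SNV":
            continue
        seq = genome.get(v.chrom)
        if seq is None or v.pos < 2 or v.pos > len(seq) - 1:
            skipped += 1
            continue
        ref_base = seq[v.pos - 1].upper()
        if ref_base != v.ref.upper():
            raise SignatureError(
                f"reference mismatch at {v.chrom}:{v.pos} "
                f"(genome {ref_base}, variant {v.ref})"
            )
        five = seq[v.pos - 2]
        three = seq[v.pos]
        if set((five + three).upper()) - set("ACGT"):
            skipped += 1
            continue
        label = channel_for(v.ref, v.alt, five, three)
        counts[_CHANNEL_INDEX[label]] += 1
    return MutationSpectrum96(
        counts, sample_id=sample_id or getattr(cat, "sample_id", ""), skipped=skipped
    )


def fit_exposures(
    spec: MutationSpectrum96,
    matrix: SignatureMatrix,
    min_mutations: int = 10,
) -> ExposureVector:
    """Refit a spectrum against a signature matrix by nonnegative least squares.

    Samples with fewer than ``min_mutations`` catalogued SNVs are refused.
    """
    if spec.total < min_mutations:
        raise InsufficientMutationsError(
            f"insufficient mutations: {spec.total:.0f} < {min_mutations}"
        )
    exposures, residual = nnls(matrix.profiles, spec.counts)
    return ExposureVector(
        names=matrix.names,
        raw=exposures,
        residual=float(residual),
        sample_id=spec.sample_id,
    )


def cluster_exposures(exposures: Sequence[ExposureVector]) -> np.ndarray:
    """Average-linkage / Euclidean hierarchical clustering of exposure profiles.

    Profiles are compared on their normalized contributions.  Returns a scipy
    linkage matrix; ties are broken by scipy's deterministic lowest-index
    ordering, so a fixed input order yields a fixed tree.
    """
    if len(exposures) < 2:
        raise SignatureError("clustering requires at least 2 exposure profiles")
    data = np.vstack([e.normalized for e in exposures])
    return linkage(data, method="average", metric="euclidean")


def linkage_to_tree(Z: np.ndarray, labels: Sequence[str]) -> dict:
    """Convert a scipy linkage matrix into a nested-dict merge tree."""
    n = len(labels)
    nodes: dict[int, dict] = {
        i: {"label": labels[i], "height": 0.0} for i in range(n)
    }
    for i, (a, b, height, _count) in enumerate(Z):
        nodes[n + i] = {
            "height": float(height),
            "children": [nodes[int(a)], nodes[int(b)]],
        }
    return nodes[n + len(Z) - 1]


def _peaked_profile(channel_weights: dict[str, float]) -> np.ndarray:
    """Dense profile concentrated on the given channels with a tiny uniform floor."""
    profile = np.full(96, 1e-4)
    for label, weight in channel_weights.items():
        profile[_CHANNEL_INDEX[label]] += weight
    return profile / profile.sum()


def bundled_signatures() -> SignatureMatrix:
    """Six synthetic, well-separated signature profiles for simulation/tests.

    Shapes loosely mimic known repair-defect processes: a C>T-rich
    MMR-deficient-like shape, a POLE-like shape (TCT C>A plus TCG C>T), a
    MUTYH-like C>A-rich shape, a CpG-deamination shape, a T>C-rich shape and
    a flat background.  These are fixtures, not the catalog signatures.
    """
    mmr = _peaked_profile(
        {f"{f}[C>T]{t}": 1.0 for f in _BASES for t in _BASES}
        | {"A[C>T]G": 3.0, "G[C>T]G": 3.0}
        | {f"{f}[T>C]{t}": 0.4 for f in _BASES for t in _BASES}
    )
    pole = _peaked_profile({"T[C>A]T": 6.0, "T[C>G]T": 1.5, "T[C>T]G": 3.0})
    mutyh = _peaked_profile(
        {f"{f}[C>A]{t}": 1.0 for f in _BASES for t in _BASES}
        | {"A[C>A]A": 2.5, "T[C>A]A": 2.5, "G[C>A]A": 2.0}
    )
    cpg = _peaked_profile({f"{f}[C>T]G": 1.0 for f in _BASES})
    tc = _peaked_profile(
        {f"{f}[T>C]{t}": 1.0 for f in _BASES for t in _BASES}
        | {"A[T>C]G": 2.0}
    )
    flat = np.full(96, 1.0 / 96)
    return SignatureMatrix(
        names=["SYN_MMR", "SYN_POLE", "SYN_MUTYH", "SYN_CPG", "SYN_TC", "SYN_FLAT"],
        profiles=np.column_stack([mmr, pole, mutyh, cpg, tc, flat]),
    )
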