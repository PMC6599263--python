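"""Readers and writers for the minimal text formats the pipeline speaks.

VCF dialect (documented here, enforced on read):

* ``##fileformat=VCFv4.2`` header; one sample column.
* ``INFO`` keys: ``GENE``, ``TX``, ``CDSPOS``, ``CSQ`` (annotations, optional)
  and ``SAF``/``SAR`` (alt-supporting reads per strand, counted excluding
  read-terminal positions).
* ``FORMAT`` is ``AD:DP`` with ``AD`` = ref,alt counts.
* ``FILTER`` is ``.``, ``PASS`` or a semicolon list of cascade failure
  reasons (``strand_bias``, ``low_af``, ``binom_p``, ``dbsnp``, ``pon``).
* Multi-allelic ALT fields are decomposed into one variant per alternate.

All other tables are plain TSV; lineage descriptions are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evolvability import GrowthRecord
from .neoantigens import NeoantigenCandidate, Transcript
from .ploidy import DepthProfile, Segment
from .signatures import CHANNELS, ExposureVector, MutationSpectrum96, SignatureMatrix
from .variants import Variant, VariantCatalog, VariantError

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_key_list",
    "read_fasta",
    "write_fasta",
    "read_gene_model",
    "write_gene_model",
    "read_expression",
    "write_expression",
    "read_depth_profile",
    "write_depth_profile",
    "read_growth_records",
    "read_signature_matrix",
    "write_signature_matrix",
    "read_spectrum",
    "write_spectrum",
    "write_exposures",
    "write_segments",
    "write_candidates",
    "read_lineage",
    "FormatError",
]


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=TX,Number=1,Type=String,Description="Transcript id">
##INFO=<ID=CDSPOS,Number=1,Type=Integer,Description="1-based position in CDS">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">
##INFO=<ID=SAF,Number=1,Type=Integer,Description="Alt reads forward strand, non-terminal">
##INFO=<ID=SAR,Number=1,Type=Integer,Description="Alt reads reverse strand, non-terminal">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt read counts">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""

_KNOWN_INFO = {"GENE", "TX", "CDSPOS", "CSQ", "SAF", "SAR"}


def write_vcf(
    cat: VariantCatalog,
    path,
    filter_reasons: Optional[Mapping[tuple, Sequence[str]]] = None,
) -> None:
    """Write a catalog in the minimal VCF dialect (sorted by key)."""
    lines = [_VCF_HEADER.format(sample=cat.sample_id)]
    for v in cat.sorted_variants():
        info = []
        if v.gene:
            info.append(f"GENE={v.gene}")
        if v.transcript:
            info.append(f"TX={v.transcript}")
        if v.cds_pos is not None:
            info.append(f"CDSPOS={v.cds_pos}")
        if v.consequence:
            info.append(f"CSQ={v.consequence}")
        if v.alt_fwd is not None:
            info.append(f"SAF={v.alt_fwd}")
            info.append(f"SAR={v.alt_rev}")
        if filter_reasons is None:
            filt = "."
        else:
            reasons = filter_reasons.get(v.key, [])
            filt = ";".join(reasons) if reasons else "PASS"
        lines.append(
            "\t".join(
                [
                    v.chrom,
                    str(v.pos),
                    ".",
                    v.ref,
                    v.alt,
                    ".",
                    filt,
                    ";".join(info) or ".",
                    "AD:DP",
                    f"{v.depth - v.alt_count},{v.alt_count}:{v.depth}",
                ]
            )
            + "\n"
        )
    Path(path).write_text("".join(lines))


def _parse_info(info: str) -> dict[str, str]:
    out = {}
    if info == ".":
        return out
    for item in info.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
        else:
            out[item] = ""
    return out


def read_vcf(path, pass_only: bool = False) -> VariantCatalog:
    """Read a minimal-dialect VCF back into a catalog.

    Violations (bad counts, malformed columns) raise :class:`FormatError`
    with the 1-based line number; unknown INFO keys are ignored with a
    warning collected on the returned catalog as ``.warnings``.
    """
    path = Path(path)
    sample_id = path.stem
    variants: list[Variant] = []
    warnings: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) >= 10:
                    sample_id = cols[9]
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(f"{path}:{lineno}: expected >= 8 columns")
            chrom, pos_s, _id, ref, alt_field, _qual, filt, info_s = fields[:8]
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad POS {pos_s!r}") from None
            if pass_only and filt not in (".", "PASS"):
                continue
            info = _parse_info(info_s)
            unknown = set(info) - _KNOWN_INFO
            if unknown:
                warnings.append(f"{path}:{lineno}: unknown INFO keys {sorted(unknown)}")
            depth = 0
            ad: list[int] = []
            if len(fields) >= 10:
                fmt_keys = fields[8].split(":")
                fmt_vals = fields[9].split(":")
                fmt = dict(zip(fmt_keys, fmt_vals))
                try:
                    depth = int(fmt.get("DP", 0))
                    if "AD" in fmt:
                        ad = [int(x) for x in fmt["AD"].split(",")]
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: bad FORMAT values") from None
            alts = alt_field.split(",")
            for ai, alt in enumerate(alts):
                alt_count = ad[1 + ai] if len(ad) > 1 + ai else 0
                try:
                    v = Variant(
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        depth=depth,
                        alt_count=alt_count,
                        alt_fwd=int(info["SAF"]) if "SAF" in info and len(alts) == 1 else None,
                        alt_rev=int(info["SAR"]) if "SAR" in info and len(alts) == 1 else None,
                        gene=info.get("GENE"),
                        transcript=info.get("TX"),
                        cds_pos=int(info["CDSPOS"]) if "CDSPOS" in info else None,
                        consequence=info.get("CSQ"),
                    )
                except (VariantError, ValueError) as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
                variants.append(v)
    cat = VariantCatalog(sample_id=sample_id, variants=variants)
    cat.warnings = warnings  # type: ignore[attr-defined]
    return cat


def read_key_list(path) -> frozenset[tuple]:
    """Variant keys from a VCF or a 4-column (chrom, pos, ref, alt) TSV."""
    path = Path(path)
    keys = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 columns")
            chrom, pos_s, ref = fields[0], fields[1], fields[3 if len(fields) >= 8 else 2]
            alt = fields[4 if len(fields) >= 8 else 3]
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad position {pos_s!r}") from None
            for a in alt.split(","):
                keys.add((chrom, pos, ref, a))
    return frozenset(keys)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_gene_model(model: pd.DataFrame, path) -> None:
    model.to_csv(path, sep="\t", index=False)


def read_gene_model(path, cdna: Optional[Mapping[str, str]] = None):
    """Gene-model TSV -> (DataFrame, transcripts dict when cDNA provided).

    Requires columns transcript, gene, cds_start, cds_end; genomic columns
    (chrom, start, end, ordinal) are carried through when present.  CDS
    lengths not divisible by 3 are rejected.
    """
    table = pd.read_csv(path, sep="\t")
    required = {"transcript", "gene", "cds_start", "cds_end"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path}: gene model missing columns {sorted(missing)}")
    bad = table[(table["cds_end"] - table["cds_start"] + 1) % 3 != 0]
    if len(bad):
        raise FormatError(
            f"{path}: CDS length not divisible by 3 for "
            f"{bad['transcript'].tolist()}"
        )
    transcripts = None
    if cdna is not None:
        transcripts = {}
        for row in table.itertuples():
            if row.transcript not in cdna:
                raise FormatError(f"{path}: no cDNA sequence for {row.transcript}")
            transcripts[str(row.transcript)] = Transcript(
                id=str(row.transcript),
                gene=str(row.gene),
                cdna=cdna[row.transcript],
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
            )
    return table, transcripts


def read_expression(path) -> dict[str, float]:
    table = pd.read_csv(path, sep="\t")
    if not {"gene", "fpkm"} <= set(table.columns):
        raise FormatError(f"{path}: expected columns gene, fpkm")
    if table["gene"].duplicated().any():
        dupes = table.loc[table["gene"].duplicated(), "gene"].tolist()
        raise FormatError(f"{path}: duplicate genes {dupes}")
    return dict(zip(table["gene"], table["fpkm"].astype(float)))


def write_expression(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_depth_profile(path) -> DepthProfile:
    return DepthProfile(pd.read_csv(path, sep="\t"))


def write_depth_profile(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, sep="\t", index=False)


def read_growth_records(path) -> list[GrowthRecord]:
    table = pd.read_csv(path, sep="\t")
    required = {"sample", "n", "t"}
    if not required <= set(table.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    records = []
    for row in table.itertuples():
        records.append(
            GrowthRecord(
                sample_id=str(row.sample),
                n=int(row.n),
                t=float(row.t),
                split_ratio=float(row.split_ratio)
                if "split_ratio" in table.columns
                else None,
            )
        )
    return records


def write_signature_matrix(matrix: SignatureMatrix, path) -> None:
    frame = pd.DataFrame(matrix.profiles, columns=list(matrix.names))
    frame.insert(0, "channel", CHANNELS)
    frame.to_csv(path, sep="\t", index=False)


def read_signature_matrix(path) -> SignatureMatrix:
    table = pd.read_csv(path, sep="\t")
    if "channel" not in table.columns:
        raise FormatError(f"{path}: signature matrix needs a 'channel' column")
    if list(table["channel"]) != list(CHANNELS):
        raise FormatError(f"{path}: channel order differs from the canonical 96")
    names = [c for c in table.columns if c != "channel"]
    return SignatureMatrix(names=names, profiles=table[names].to_numpy(float))


def write_spectrum(spec: MutationSpectrum96, path) -> None:
    pd.DataFrame({"channel": CHANNELS, "count": spec.counts}).to_csv(
        path, sep="\t", index=False
    )


def read_spectrum(path, sample_id: str = "") -> MutationSpectrum96:
    table = pd.read_csv(path, sep="\t")
    if "channel" not in table.columns or "count" not in table.columns:
        raise FormatError(f"{path}: spectrum needs channel and count columns")
    if list(table["channel"]) != list(CHANNELS):
        raise FormatError(f"{path}: channel order differs from the canonical 96")
    return MutationSpectrum96(table["count"].to_numpy(float), sample_id=sample_id)


def write_exposures(exposures: Sequence[ExposureVector], path) -> None:
    rows = []
    for e in exposures:
        for name, raw, norm in zip(e.names, e.raw, e.normalized):
            rows.append(
                {
                    "sample": e.sample_id,
                    "signature": name,
                    "raw": raw,
                    "normalized": norm,
                    "residual": e.residual,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_segments(segments: Sequence[Segment], path) -> None:
    rows = [
        {
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "log2ratio": s.mean_log2,
            "relative_gcn": s.relative_gcn,
            "absolute_cn": s.absolute_cn,
            "n_afs": s.n_afs,
            "fit_score": s.fit_score,
            "fallback": s.fallback,
        }
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_candidates(candidates: Sequence[NeoantigenCandidate], path) -> None:
    rows = [
        {
            "peptide": c.peptide,
            "length": len(c.peptide),
            "hla": c.hla,
            "rank": c.rank,
            "variant_key": "{}:{}:{}:{}".format(*c.variant_key),
            "gene": c.gene,
            "fpkm": c.fpkm,
            "source_class": c.source_class,
        }
        for c in candidates
    ]
    pd.DataFrame(
        rows,
        columns=[
            "peptide",
            "length",
            "hla",
            "rank",
            "variant_key",
            "gene",
            "fpkm",
            "source_class",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_lineage(path) -> dict[str, dict]:
    """Lineage JSON: {node: {"parent": str|null, "vcf": path, ...}}."""
    with open(path) as fh:
        spec = json.load(fh)
    if not isinstance(spec, dict) or not spec:
        raise FormatError(f"{path}: lineage JSON must be a non-empty object")
    for node, entry in spec.items():
        if "parent" not in entry:
            raise FormatError(f"{path}: node {node!r} lacks a 'parent' field")
    return spec
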