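"""Caller dialect parsing and canonicalization.

Six somatic callers (MuSE, Mutect2, SomaticSniper, Strelka2, VarScan2,
VarDict) emit VCFs that disagree on where the somatic verdict lives
(FILTER column, a somatic-status field, or an INFO tag), which FORMAT
tags carry allele counts, and how tumor/normal columns are named.  This
module declares one dialect table covering all six and harmonizes every
record into a shared :class:`CanonicalVariant` representation keyed the
same way regardless of origin.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from cyvcf2 import VCF

__all__ = [
    "CallerId",
    "CallerRecord",
    "CanonicalVariant",
    "VariantClass",
    "Dialect",
    "DIALECTS",
    "parse_caller_vcf",
    "is_somatic_pass",
    "canonicalize",
    "canonical_variants_to_frame",
]


class CallerId(str, enum.Enum):
    """The six somatic mutation callers."""

    MUSE = "MuSE"
    MUTECT2 = "Mutect2"
    SOMATICSNIPER = "SomaticSniper"
    STRELKA2 = "Strelka2"
    VARSCAN2 = "VarScan2"
    VARDICT = "VarDict"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    MNV = "MNV"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class DialectError(ValueError):
    """Malformed input for a declared caller dialect."""


@dataclass
class CallerRecord:
    """One raw VCF data line, with dialect-specific fields surfaced."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: list[str]
    filter_field: str
    info_field: dict
    caller: CallerId
    somatic_status_field: Optional[str] = None
    t_alt: int = 0
    t_ref: int = 0
    n_alt: int = 0
    n_ref: int = 0
    t_alt_fwd: Optional[int] = None
    t_alt_rev: Optional[int] = None
    t_ref_fwd: Optional[int] = None
    t_ref_rev: Optional[int] = None
    dp: Optional[int] = None
    # per-alt tumor counts for multi-allelic lines (parallel to alts);
    # falls back to t_alt when absent
    t_alt_per_allele: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("ref allele must be non-empty")
        for name in ("t_alt", "t_ref", "n_alt", "n_ref"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CanonicalVariant:
    """A harmonized single-alt variant observation from one caller.

    Alleles are in minimal representation (shared leading/trailing
    context trimmed).  ``maf`` is the tumor variant allele fraction
    t_alt / (t_alt + t_ref), or ``None`` when the denominator is zero.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    caller: CallerId
    dp: Optional[int] = None
    maf: Optional[float] = None
    t_alt: int = 0
    t_ref: int = 0
    n_alt: int = 0
    n_ref: int = 0
    t_alt_fwd: Optional[int] = None
    t_alt_rev: Optional[int] = None
    t_ref_fwd: Optional[int] = None
    t_ref_rev: Optional[int] = None
    multiallelic_source: bool = False

    @property
    def key(self) -> tuple[str, str, int]:
        """The merge key: (sample, chrom, pos), without alleles."""
        return (self.sample_id, self.chrom, self.pos)


# ---------------------------------------------------------------------------
# Dialect table


@dataclass(frozen=True)
class Dialect:
    """Declarative description of one caller's VCF conventions.

    ``pass_rule`` names which field carries the somatic verdict;
    ``count_style`` names which FORMAT tags carry allele counts.
    Tumor/normal genotype columns are located by regex on sample names
    (dialects disagree on column order), overridable per parse call.
    """

    caller: CallerId
    pass_rule: str  # "filter" | "varscan_ss" | "vardict_status"
    count_style: str  # "mutect2" | "ad" | "dp4" | "strelka" | "varscan" | "vardict"
    tumor_regex: str = r"(TUMOR|_T$|-T$)"
    normal_regex: str = r"(NORMAL|_N$|-N$)"
    calls_indels: bool = True
    has_strand_counts: bool = True


DIALECTS: dict[CallerId, Dialect] = {
    CallerId.MUSE: Dialect(
        CallerId.MUSE, "filter", "ad", calls_indels=False, has_strand_counts=False
    ),
    CallerId.MUTECT2: Dialect(CallerId.MUTECT2, "filter", "mutect2"),
    CallerId.SOMATICSNIPER: Dialect(
        CallerId.SOMATICSNIPER, "filter", "dp4", calls_indels=False
    ),
    CallerId.STRELKA2: Dialect(
        CallerId.STRELKA2, "filter", "strelka", has_strand_counts=False
    ),
    CallerId.VARSCAN2: Dialect(CallerId.VARSCAN2, "varscan_ss", "varscan"),
    CallerId.VARDICT: Dialect(CallerId.VARDICT, "vardict_status", "vardict"),
}


def _normalize_chrom(chrom: str) -> str:
    """Normalize chromosome naming to the 'chr'-prefixed convention."""
    return chrom if chrom.startswith("chr") else "chr" + chrom


def _find_sample_columns(
    samples: list[str], dialect: Dialect,
    tumor_regex: Optional[str], normal_regex: Optional[str],
) -> tuple[int, int]:
    t_re = re.compile(tumor_regex or dialect.tumor_regex)
    n_re = re.compile(normal_regex or dialect.normal_regex)
    t_idx = [i for i, s in enumerate(samples) if t_re.search(s)]
    n_idx = [i for i, s in enumerate(samples) if n_re.search(s)]
    if len(t_idx) != 1 or len(n_idx) != 1 or t_idx == n_idx:
        raise DialectError(
            f"cannot identify tumor/normal columns in {samples} "
            f"for {dialect.caller.value}"
        )
    return t_idx[0], n_idx[0]


def _fmt_int(variant, tag: str, sample_idx: int, sub: Optional[int] = None):
    """Read one integer from a FORMAT tag; None when the tag is absent."""
    try:
        arr = variant.format(tag)
    except KeyError:
        return None
    if arr is None:
        return None
    row = arr[sample_idx]
    try:
        val = row[sub] if sub is not None else row[0]
    except (TypeError, IndexError):
        val = row
    val = int(val)
    return None if val < 0 else val  # cyvcf2 encodes missing as negative


def _fmt_arr(variant, tag: str):
    """FORMAT tag as an array; None when absent from header or line."""
    try:
        return variant.format(tag)
    except KeyError:
        return None


_STRELKA_SNV_TAGS = {"A": "AU", "C": "CU", "G": "GU", "T": "TU"}


def _extract_counts(variant, dialect: Dialect, t: int, n: int) -> dict:
    """Pull tumor/normal ref/alt counts (and strand splits) per dialect."""
    style = dialect.count_style
    out: dict = {}
    alt0 = variant.ALT[0] if variant.ALT else ""
    if style in ("ad", "mutect2"):
        ad = _fmt_arr(variant, "AD")
        if ad is None:
            raise DialectError("missing FORMAT/AD")
        out.update(
            t_ref=int(ad[t][0]), t_alt=int(ad[t][1]),
            n_ref=int(ad[n][0]), n_alt=int(ad[n][1]),
            t_alt_per_allele=[int(x) for x in ad[t][1:]] if len(ad[t]) > 2 else None,
        )
        if style == "mutect2":
            sb = _fmt_arr(variant, "SB")
            if sb is not None:
                out.update(
                    t_ref_fwd=int(sb[t][0]), t_ref_rev=int(sb[t][1]),
                    t_alt_fwd=int(sb[t][2]), t_alt_rev=int(sb[t][3]),
                )
    elif style == "dp4":
        dp4 = _fmt_arr(variant, "DP4")
        if dp4 is None:
            raise DialectError("missing FORMAT/DP4")
        trf, trr, taf, tar = (int(x) for x in dp4[t][:4])
        nrf, nrr, naf, nar = (int(x) for x in dp4[n][:4])
        out.update(
            t_ref=trf + trr, t_alt=taf + tar, n_ref=nrf + nrr, n_alt=naf + nar,
            t_ref_fwd=trf, t_ref_rev=trr, t_alt_fwd=taf, t_alt_rev=tar,
        )
    elif style == "strelka":
        if len(variant.REF) == 1 and alt0 and len(alt0) == len(variant.REF):
            # SNV/MNV: per-base tier-1 counts; MNVs keyed by first base
            ref_tag = _STRELKA_SNV_TAGS.get(variant.REF[0])
            alt_tag = _STRELKA_SNV_TAGS.get(alt0[0])
            if ref_tag is None or alt_tag is None:
                raise DialectError(f"non-ACGT alleles {variant.REF}>{alt0}")
            out.update(
                t_ref=_fmt_int(variant, ref_tag, t, 0) or 0,
                t_alt=_fmt_int(variant, alt_tag, t, 0) or 0,
                n_ref=_fmt_int(variant, ref_tag, n, 0) or 0,
                n_alt=_fmt_int(variant, alt_tag, n, 0) or 0,
            )
        else:
            tar, tir = _fmt_arr(variant, "TAR"), _fmt_arr(variant, "TIR")
            if tar is None or tir is None:
                raise DialectError("missing FORMAT/TAR or TIR")
            out.update(
                t_ref=int(tar[t][0]), t_alt=int(tir[t][0]),
                n_ref=int(tar[n][0]), n_alt=int(tir[n][0]),
            )
    elif style == "varscan":
        rd = _fmt_int(variant, "RD", t)
        ad = _fmt_int(variant, "AD", t)
        if rd is None or ad is None:
            raise DialectError("missing FORMAT/RD or AD")
        out.update(
            t_ref=rd, t_alt=ad,
            n_ref=_fmt_int(variant, "RD", n) or 0,
            n_alt=_fmt_int(variant, "AD", n) or 0,
        )
        dp4 = _fmt_arr(variant, "DP4")
        if dp4 is not None:
            # VarScan emits DP4 as a comma-joined string
            raw = dp4[t]
            if not isinstance(raw, (str, bytes)):
                raw = raw[0]
            if isinstance(raw, bytes):
                raw = raw.decode()
            parts = [int(x) for x in str(raw).split(",")]
            if len(parts) == 4:
                out.update(
                    t_ref_fwd=parts[0], t_ref_rev=parts[1],
                    t_alt_fwd=parts[2], t_alt_rev=parts[3],
                )
    elif style == "vardict":
        ad = _fmt_arr(variant, "AD")
        if ad is None:
            raise DialectError("missing FORMAT/AD")
        out.update(
            t_ref=int(ad[t][0]), t_alt=int(ad[t][1]),
            n_ref=int(ad[n][0]), n_alt=int(ad[n][1]),
        )
        rd, ald = _fmt_arr(variant, "RD"), _fmt_arr(variant, "ALD")
        if rd is not None and ald is not None:
            out.update(
                t_ref_fwd=int(rd[t][0]), t_ref_rev=int(rd[t][1]),
                t_alt_fwd=int(ald[t][0]), t_alt_rev=int(ald[t][1]),
            )
    else:  # pragma: no cover - table is closed
        raise DialectError(f"unknown count style {style!r}")
    return out


def parse_caller_vcf(
    path: str | Path,
    caller: CallerId,
    sample_id: Optional[str] = None,
    tumor_regex: Optional[str] = None,
    normal_regex: Optional[str] = None,
) -> list[CallerRecord]:
    """Parse one tumor/normal paired VCF in the given caller's dialect.

    Parameters
    ----------
    path : VCF file (plain or bgzipped).
    caller : which dialect to apply.
    sample_id : patient identifier stored on every record; defaults to
        the tumor column name stripped of a trailing ``_T``/``-T``/
        ``TUMOR`` decoration.
    tumor_regex, normal_regex : override the dialect's sample-name
        regexes used to locate the tumor and normal genotype columns.

    Returns one :class:`CallerRecord` per VCF data line.  A line whose
    required genotype tag is missing raises :class:`DialectError`
    naming the line number.
    """
    dialect = DIALECTS[caller]
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad files
        raise DialectError(f"cannot open VCF {path}: {exc}") from exc
    if len(vcf.samples) < 2:
        vcf.close()
        raise DialectError(
            f"{path}: need tumor and normal genotype columns, "
            f"found {vcf.samples}"
        )
    t, n = _find_sample_columns(vcf.samples, dialect, tumor_regex, normal_regex)
    if sample_id is None:
        sample_id = re.sub(r"([_-]?(T|TUMOR))$", "", vcf.samples[t])

    records: list[CallerRecord] = []
    for lineno, v in enumerate(vcf, start=1):
        try:
            counts = _extract_counts(v, dialect, t, n)
        except DialectError as exc:
            vcf.close()
            raise DialectError(f"{path} line {lineno}: {exc}") from exc
        info = dict(v.INFO)
        status = None
        if dialect.pass_rule == "varscan_ss":
            status = info.get("SS")
        elif dialect.pass_rule == "vardict_status":
            status = info.get("STATUS")
        records.append(
            CallerRecord(
                sample_id=sample_id,
                chrom=_normalize_chrom(v.CHROM),
                pos=v.POS,
                ref=v.REF,
                alts=list(v.ALT),
                filter_field=v.FILTER or "PASS",  # cyvcf2: PASS -> None
                info_field=info,
                caller=caller,
                somatic_status_field=str(status) if status is not None else None,
                dp=_fmt_int(v, "DP", t),
                **counts,
            )
        )
    vcf.close()
    return records


def is_somatic_pass(record: CallerRecord) -> bool:
    """Apply the caller-specific somatic verdict.

    MuSE, Mutect2, SomaticSniper and Strelka2 calls pass iff FILTER is
    ``PASS``; VarScan2 iff its somatic status is ``Somatic``; VarDict
    iff INFO ``STATUS`` is ``StrongSomatic``.
    """
    rule = DIALECTS[record.caller].pass_rule
    if rule == "filter":
        return record.filter_field == "PASS"
    if rule == "varscan_ss":
        if record.somatic_status_field is None:
            raise DialectError(
                f"VarScan2 record at {record.chrom}:{record.pos} lacks the "
                "somatic status field (INFO/SS)"
            )
        return record.somatic_status_field == "Somatic"
    if rule == "vardict_status":
        if record.somatic_status_field is None:
            raise DialectError(
                f"VarDict record at {record.chrom}:{record.pos} lacks "
                "INFO/STATUS"
            )
        return record.somatic_status_field == "StrongSomatic"
    raise DialectError(f"unknown pass rule {rule!r}")  # pragma: no cover


def _trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal representation: strip shared suffix, then shared prefix."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    # one-sided trim for padded indels ("CA">"C") stays as-is: the VCF
    # anchor base is part of the minimal indel representation
    if len(ref) != len(alt):
        return pos, ref, alt
    # equal length: strip a remaining shared prefix down to length 1
    while len(ref) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _classify(ref: str, alt: str) -> VariantClass:
    if len(ref) == len(alt):
        return VariantClass.SNV if len(ref) == 1 else VariantClass.MNV
    return VariantClass.INSERTION if len(ref) < len(alt) else VariantClass.DELETION


def canonicalize(record: CallerRecord) -> list[CanonicalVariant]:
    """Split a record into per-alt canonical variants.

    Each alt allele yields one :class:`CanonicalVariant` with trimmed
    alleles and a variant class derived from allele lengths.  Degenerate
    counts yield ``maf=None`` rather than a division error.  Records
    with two or more alts mark every product ``multiallelic_source``.
    """
    out: list[CanonicalVariant] = []
    multi = len(record.alts) >= 2
    for i, alt in enumerate(record.alts):
        pos, ref, a = _trim(record.pos, record.ref, alt)
        t_alt = record.t_alt
        if record.t_alt_per_allele is not None and i < len(record.t_alt_per_allele):
            t_alt = record.t_alt_per_allele[i]
        denom = t_alt + record.t_ref
        maf = t_alt / denom if denom > 0 else None
        out.append(
            CanonicalVariant(
                sample_id=record.sample_id,
                chrom=record.chrom,
                pos=pos,
                ref=ref,
                alt=a,
                variant_class=_classify(ref, a),
                caller=record.caller,
                dp=record.dp if record.dp is not None else (denom or None),
                maf=maf,
                t_alt=t_alt,
                t_ref=record.t_ref,
                n_alt=record.n_alt,
                n_ref=record.n_ref,
                t_alt_fwd=record.t_alt_fwd,
                t_alt_rev=record.t_alt_rev,
                t_ref_fwd=record.t_ref_fwd,
                t_ref_rev=record.t_ref_rev,
                multiallelic_source=multi,
            )
        )
    return out


def canonical_variants_to_frame(variants: Iterable[CanonicalVariant]):
    """Export canonical variants as a MAF-like table."""
    import pandas as pd

    rows = [
        {
            "sample": v.sample_id, "chrom": v.chrom, "pos": v.pos,
            "ref": v.ref, "alt": v.alt, "class": v.variant_class.value,
            "caller": v.caller.value, "t_alt": v.t_alt, "n_alt": v.n_alt,
            "dp": v.dp, "maf": v.maf,
        }
        for v in variants
    ]
    cols = ["sample", "chrom", "pos", "ref", "alt", "class", "caller",
            "t_alt", "n_alt", "dp", "maf"]
    return pd.DataFrame(rows, columns=cols)
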