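"""Multi-caller merging, >=k-caller consensus, target restriction, and
dinucleotide MNV reconstruction.

Callsets are merged on the key (sample, chrom, pos) — deliberately
without alleles, so the same site reported with discordant alleles by
different callers still collapses to one record (the discordance is
annotated, not hidden).  Four of the six callers emit a dinucleotide
substitution as two adjacent SNVs; when an MNV-capable caller (Mutect2
or VarDict) reports the 2-bp event, the per-position SNVs from the
other callers are folded into a single MNV record so caller agreement
is counted per event, not per base.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .callers import CallerId, CanonicalVariant, VariantClass

__all__ = [
    "MergedVariant",
    "TargetRegion",
    "restrict_to_target",
    "merge_callsets",
    "consensus_filter",
    "reconstruct_mnvs",
    "agreement_histogram",
]

# deterministic representative-allele tie-break
CALLER_PRIORITY = [
    CallerId.MUTECT2,
    CallerId.STRELKA2,
    CallerId.VARDICT,
    CallerId.MUSE,
    CallerId.SOMATICSNIPER,
    CallerId.VARSCAN2,
]

MNV_CAPABLE = {CallerId.MUTECT2, CallerId.VARDICT}


@dataclass
class TargetRegion:
    """Capture target as merged half-open 0-based intervals per chromosome."""

    trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int]]
    ) -> "TargetRegion":
        trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for chrom, start, end in intervals:
            if end > start:
                trees[chrom].addi(int(start), int(end))
        for t in trees.values():
            t.merge_overlaps(strict=False)  # also merges bookended intervals
        return cls(trees=dict(trees))

    @classmethod
    def from_bed(cls, path: str | Path) -> "TargetRegion":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                intervals.append((chrom, int(start), int(end)))
        if not intervals:
            raise ValueError(f"empty BED file: {path}")
        return cls.from_intervals(intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree.overlaps(pos - 1))

    @property
    def total_bases(self) -> int:
        return sum(iv.end - iv.begin for t in self.trees.values() for iv in t)

    @property
    def total_size_mb(self) -> float:
        return self.total_bases / 1e6


@dataclass
class MergedVariant:
    """Consensus record for one (sample, chrom, pos) key."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    caller_hits: set[CallerId]
    payloads: dict[CallerId, CanonicalVariant]
    alt_discordant: bool = False
    class_discordant: bool = False
    min_callers: int = 2

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.sample_id, self.chrom, self.pos)

    @property
    def n_callers(self) -> int:
        return len(self.caller_hits)

    @property
    def consensus_pass(self) -> bool:
        return self.n_callers >= self.min_callers

    @property
    def dp(self) -> Optional[int]:
        return self._representative().dp

    @property
    def maf(self) -> Optional[float]:
        return self._representative().maf

    def _representative(self) -> CanonicalVariant:
        for c in CALLER_PRIORITY:
            if c in self.payloads:
                return self.payloads[c]
        raise ValueError("merged variant with no payloads")  # pragma: no cover

    @property
    def positions_covered(self) -> frozenset[int]:
        """Distinct mutated reference base positions this record spans."""
        if self.variant_class is VariantClass.MNV:
            return frozenset(range(self.pos, self.pos + len(self.ref)))
        return frozenset({self.pos})


def restrict_to_target(
    variants: list, region: TargetRegion
) -> tuple[list, int]:
    """Keep variants whose position falls inside the target region.

    Works on anything with ``chrom``/``pos`` attributes.  Returns the
    retained list and the count of dropped variants (including those on
    chromosomes absent from the BED).
    """
    kept = [v for v in variants if region.contains(v.chrom, v.pos)]
    return kept, len(variants) - len(kept)


def merge_callsets(
    per_caller_sets: dict[CallerId, list[CanonicalVariant]],
) -> list[MergedVariant]:
    """Merge per-caller callsets on (sample, chrom, pos).

    Each caller contributes at most one payload per key (duplicate
    per-caller reports at a key keep the first).  The representative
    ref/alt/class follows caller priority (Mutect2 > Strelka2 > VarDict
    > MuSE > SomaticSniper > VarScan2); disagreement on alt or on
    variant class across callers is annotated, never discarded.
    """
    groups: dict[tuple[str, str, int], dict[CallerId, CanonicalVariant]] = {}
    for caller, variants in per_caller_sets.items():
        for v in variants:
            payloads = groups.setdefault(v.key, {})
            payloads.setdefault(caller, v)
    merged: list[MergedVariant] = []
    for key in sorted(groups):
        payloads = groups[key]
        rep = next(payloads[c] for c in CALLER_PRIORITY if c in payloads)
        alts = {p.alt for p in payloads.values()}
        classes = {p.variant_class for p in payloads.values()}
        merged.append(
            MergedVariant(
                sample_id=key[0], chrom=key[1], pos=key[2],
                ref=rep.ref, alt=rep.alt, variant_class=rep.variant_class,
                caller_hits=set(payloads), payloads=payloads,
                alt_discordant=len(alts) > 1,
                class_discordant=len(classes) > 1,
            )
        )
    return merged


def consensus_filter(
    merged: list[MergedVariant], min_callers: int = 2
) -> list[MergedVariant]:
    """Retain records identified by at least ``min_callers`` callers."""
    if min_callers < 1:
        raise ValueError("min_callers must be >= 1")
    out = []
    for m in merged:
        m.min_callers = min_callers
        if m.n_callers >= min_callers:
            out.append(m)
    return out


def reconstruct_mnvs(
    merged: list[MergedVariant],
) -> tuple[list[MergedVariant], list[str]]:
    """Fold adjacent per-base SNV reports into dinucleotide MNV records.

    When Mutect2 or VarDict reports a 2-bp MNV at (pos, pos+1), other
    callers' SNVs at those positions whose alts match the MNV's
    per-base substitution are folded into the MNV record: the folding
    caller joins ``caller_hits`` (counted once even when it reported
    both constituent bases) and its per-position records are removed.
    A conflicting alt at a constituent position leaves that caller's
    SNVs unfolded and logs the conflict.  The set of distinct mutated
    base positions covered by the callset is unchanged.
    """
    by_key = {m.key: m for m in merged}
    conflicts: list[str] = []
    to_drop: set[tuple[str, str, int]] = set()

    for m in merged:
        mnv_payload = None
        for c in CALLER_PRIORITY:
            p = m.payloads.get(c)
            if (
                p is not None and c in MNV_CAPABLE
                and p.variant_class is VariantClass.MNV
                and len(p.ref) == 2 and len(p.alt) == 2
            ):
                mnv_payload = p
                break
        if mnv_payload is None:
            continue
        # promote the merged record to the MNV representation
        m.ref, m.alt = mnv_payload.ref, mnv_payload.alt
        m.variant_class = VariantClass.MNV
        expected = {
            m.pos: (mnv_payload.ref[0], mnv_payload.alt[0]),
            m.pos + 1: (mnv_payload.ref[1], mnv_payload.alt[1]),
        }
        next_rec = by_key.get((m.sample_id, m.chrom, m.pos + 1))
        for pos, rec in ((m.pos, m), (m.pos + 1, next_rec)):
            if rec is None:
                continue
            exp_ref, exp_alt = expected[pos]
            for caller in list(rec.payloads):
                p = rec.payloads[caller]
                if p.variant_class is not VariantClass.SNV:
                    continue
                if (p.ref, p.alt) == (exp_ref, exp_alt):
                    if rec is not m:
                        del rec.payloads[caller]
                        rec.caller_hits.discard(caller)
                    m.caller_hits.add(caller)
                    m.payloads.setdefault(caller, p)
                else:
                    conflicts.append(
                        f"{m.sample_id} {m.chrom}:{pos} {caller.value} "
                        f"reports {p.ref}>{p.alt}, MNV expects "
                        f"{exp_ref}>{exp_alt}; left unfolded"
                    )
        if next_rec is not None and not next_rec.payloads:
            to_drop.add(next_rec.key)

    out = [m for m in merged if m.key not in to_drop]
    return out, conflicts


def agreement_histogram(merged: list[MergedVariant]) -> dict[int, int]:
    """Count merged records per caller-agreement tier (1..6)."""
    hist: dict[int, int] = {k: 0 for k in range(1, len(CallerId) + 1)}
    for m in merged:
        hist[m.n_callers] += 1
    return hist
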