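"""Filter-flag annotation and PASS partitioning.

Somatic callsets are contaminated by germline leak-through and
process artifacts.  Variants are annotated (never mutated) with a set
of independent flags — common polymorphism, panel-of-normals, oxoG
orientation bias, strand bias, multiallelic site, clustered events,
and tumor/normal alt-count evidence flags — and then partitioned into
a PASS set (no flags) and a flagged set.  Keeping annotation and
partitioning separate enables per-caller, per-flag accounting reports.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd
from scipy.stats import fisher_exact

from .callers import CallerId, CanonicalVariant, VariantClass

__all__ = [
    "FilterFlag",
    "FilterConfig",
    "PanelOfNormals",
    "build_pon",
    "load_population_af",
    "annotate_flags",
    "apply_filter_flags",
    "flag_tally",
]


class FilterFlag(str, enum.Enum):
    COMMON_SNP = "CommonSNP"
    PON = "PoN"
    OXOG = "OxoG"
    STRAND_BIAS = "StrandBias"
    MULTIALLELIC = "MultiallelicSite"
    CLUSTERED = "ClusteredEvents"
    T_ALT_LOW = "TAltLow"
    N_ALT_HIGH = "NAltHigh"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class FilterConfig:
    """Every numeric threshold used by the flag engine.

    ``common_af_max``: population allele frequency above which a call is
    a common polymorphism (strictly greater than; 1% default).
    ``t_alt_min`` / ``n_alt_max``: evidence bounds — tumor alt reads
    below 4, or normal alt reads at or above 4, flag the call.
    PoN membership requires ``pon_min_alt_reads`` alt reads in at least
    ``pon_min_normals`` distinct normals.  OxoG is called on C>A / G>T
    SNVs whose alt reads are orientation-skewed beyond
    ``oxog_orientation_fraction`` (with at least ``oxog_min_alt`` alt
    reads); strand bias by a two-sided exact test on the ref/alt x
    fwd/rev table at ``strand_bias_p``; clustered events when
    ``cluster_min_events`` same-sample variants fall within any
    ``cluster_window_bp`` span.
    """

    common_af_max: float = 0.01
    t_alt_min: int = 4
    n_alt_max: int = 4
    pon_min_normals: int = 2
    pon_min_alt_reads: int = 2
    oxog_orientation_fraction: float = 0.9
    oxog_min_alt: int = 3
    strand_bias_p: float = 0.005
    cluster_window_bp: int = 50
    cluster_min_events: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.common_af_max < 1.0):
            raise ValueError("common_af_max must be in (0, 1)")
        for name in ("t_alt_min", "n_alt_max", "pon_min_normals",
                     "pon_min_alt_reads", "oxog_min_alt",
                     "cluster_window_bp", "cluster_min_events"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PanelOfNormals:
    """Sites recurrently alt-supported across the normal cohort.

    Keys are (chrom, pos, alt); values count the supporting normals
    (each with >= min_alt_reads alt reads at build time).
    """

    sites: dict[tuple[str, int, str], int] = field(default_factory=dict)

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return key in self.sites

    def __len__(self) -> int:
        return len(self.sites)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": c, "pos": p, "alt": a, "n_normals": n}
            for (c, p, a), n in sorted(self.sites.items())
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "alt", "n_normals"])


def build_pon(
    normal_evidence: pd.DataFrame | Iterable[tuple],
    config: FilterConfig = FilterConfig(),
) -> PanelOfNormals:
    """Build a panel of normals from per-normal site alt-read counts.

    ``normal_evidence`` rows carry (normal_sample, chrom, pos, alt,
    alt_reads).  A site enters the panel iff at least
    ``pon_min_normals`` distinct normals each show
    ``pon_min_alt_reads`` or more alt reads there.  Empty evidence
    yields an empty panel.
    """
    if isinstance(normal_evidence, pd.DataFrame):
        rows = normal_evidence.itertuples(index=False)
    else:
        rows = iter(normal_evidence)
    supporters: dict[tuple[str, int, str], set[str]] = defaultdict(set)
    for sample, chrom, pos, alt, alt_reads in rows:
        if int(alt_reads) >= config.pon_min_alt_reads:
            supporters[(str(chrom), int(pos), str(alt))].add(str(sample))
    sites = {
        site: len(samples)
        for site, samples in supporters.items()
        if len(samples) >= config.pon_min_normals
    }
    return PanelOfNormals(sites=sites)


def load_population_af(path) -> dict[tuple[str, int, str], float]:
    """Read a population allele-frequency table (chrom, pos, ref, alt, af)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (str(r.chrom), int(r.pos), str(r.alt)): float(r.af)
        for r in df.itertuples(index=False)
    }


_OXOG_PAIRS = {("C", "A"), ("G", "T")}


def _oxog_flag(v: CanonicalVariant, cfg: FilterConfig) -> Optional[bool]:
    """8-oxoguanine orientation-bias check; None = not evaluable.

    Only C>A and G>T SNVs are oxoG-compatible.  The artifact-consistent
    orientation is forward for C>A and reverse for G>T; a call is
    flagged when that orientation carries >= oxog_orientation_fraction
    of at least oxog_min_alt alt reads.
    """
    if v.variant_class is not VariantClass.SNV or (v.ref, v.alt) not in _OXOG_PAIRS:
        return False  # evaluable, definitionally clean
    if v.t_alt_fwd is None or v.t_alt_rev is None:
        return None
    total = v.t_alt_fwd + v.t_alt_rev
    if total < cfg.oxog_min_alt:
        return False
    consistent = v.t_alt_fwd if v.ref == "C" else v.t_alt_rev
    return consistent / total >= cfg.oxog_orientation_fraction


def _strand_bias_flag(v: CanonicalVariant, cfg: FilterConfig) -> Optional[bool]:
    """Two-sided exact test on the ref/alt x fwd/rev 2x2 table."""
    strands = (v.t_ref_fwd, v.t_ref_rev, v.t_alt_fwd, v.t_alt_rev)
    if any(s is None for s in strands):
        return None
    table = [[v.t_ref_fwd, v.t_ref_rev], [v.t_alt_fwd, v.t_alt_rev]]
    _, p = fisher_exact(table, alternative="two-sided")
    return bool(p < cfg.strand_bias_p)


def _clustered_keys(
    variants: list[CanonicalVariant], cfg: FilterConfig
) -> set[tuple[str, str, int]]:
    """Keys of variants lying in any window of >= cluster_min_events
    same-sample events within cluster_window_bp."""
    by_group: dict[tuple[str, str], set[int]] = defaultdict(set)
    for v in variants:
        by_group[(v.sample_id, v.chrom)].add(v.pos)
    flagged: set[tuple[str, str, int]] = set()
    for (sample, chrom), pos_set in by_group.items():
        positions = sorted(pos_set)
        n = len(positions)
        j = 0
        for i in range(n):
            while positions[i] - positions[j] > cfg.cluster_window_bp:
                j += 1
            if i - j + 1 >= cfg.cluster_min_events:
                for k in range(j, i + 1):
                    flagged.add((sample, chrom, positions[k]))
    return flagged


@dataclass
class FlagAnnotation:
    """Flag set plus the flags that could not be evaluated."""

    flags: frozenset[FilterFlag]
    not_evaluable: frozenset[FilterFlag] = frozenset()


def annotate_flags(
    variants: list[CanonicalVariant],
    pon: PanelOfNormals | None = None,
    pop_af: Mapping[tuple[str, int, str], float] | None = None,
    config: FilterConfig = FilterConfig(),
) -> dict[CanonicalVariant, FlagAnnotation]:
    """Annotate each variant with its filter flags.

    Flags are independent; a variant may carry several.  OxoG and
    StrandBias require stranded counts — when those are absent the flag
    is recorded as not-evaluable rather than silently passing or
    failing.  The result is order-independent in the input.
    """
    pon = pon or PanelOfNormals()
    pop_af = pop_af or {}
    clustered = _clustered_keys(variants, config)
    out: dict[CanonicalVariant, FlagAnnotation] = {}
    for v in variants:
        flags: set[FilterFlag] = set()
        not_ev: set[FilterFlag] = set()
        if pop_af.get((v.chrom, v.pos, v.alt), 0.0) > config.common_af_max:
            flags.add(FilterFlag.COMMON_SNP)
        if (v.chrom, v.pos, v.alt) in pon:
            flags.add(FilterFlag.PON)
        oxog = _oxog_flag(v, config)
        if oxog is None:
            not_ev.add(FilterFlag.OXOG)
        elif oxog:
            flags.add(FilterFlag.OXOG)
        sb = _strand_bias_flag(v, config)
        if sb is None:
            not_ev.add(FilterFlag.STRAND_BIAS)
        elif sb:
            flags.add(FilterFlag.STRAND_BIAS)
        if v.multiallelic_source:
            flags.add(FilterFlag.MULTIALLELIC)
        if (v.sample_id, v.chrom, v.pos) in clustered:
            flags.add(FilterFlag.CLUSTERED)
        if v.t_alt < config.t_alt_min:
            flags.add(FilterFlag.T_ALT_LOW)
        if v.n_alt >= config.n_alt_max:
            flags.add(FilterFlag.N_ALT_HIGH)
        out[v] = FlagAnnotation(flags=frozenset(flags),
                                not_evaluable=frozenset(not_ev))
    return out


def apply_filter_flags(
    variants: list[CanonicalVariant],
    flags: Mapping[CanonicalVariant, FlagAnnotation],
) -> tuple[list[CanonicalVariant], list[CanonicalVariant]]:
    """Partition into (pass_set, flagged_set); exhaustive and disjoint.

    A variant passes iff its flag set is empty; not-evaluable flags do
    not count against it.
    """
    pass_set, flagged = [], []
    for v in variants:
        ann = flags[v]
        (pass_set if not ann.flags else flagged).append(v)
    return pass_set, flagged


def flag_tally(
    flags: Mapping[CanonicalVariant, FlagAnnotation]
) -> pd.DataFrame:
    """Per-caller, per-flag counts (one variant may count under several
    flags), plus Total and PASS columns — the per-caller accounting
    report."""
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for v, ann in flags.items():
        row = counts[v.caller.value]
        row["Total"] += 1
        if not ann.flags:
            row["PASS"] += 1
        for f in ann.flags:
            row[f.value] += 1
    cols = ["Total", "PASS"] + [f.value for f in FilterFlag]
    callers = [c.value for c in CallerId if c.value in counts]
    df = pd.DataFrame(
        [[counts[c].get(col, 0) for col in cols] for c in callers],
        index=callers, columns=cols,
    )
    df.index.name = "caller"
    return df
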