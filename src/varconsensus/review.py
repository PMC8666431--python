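"""Automated read-evidence review, per-gene false-positive rates,
gene blacklisting, and recurrent-gene selection.

Manual IGV inspection of called variants is replaced by a
deterministic classifier over per-variant pileup evidence.  A call is
a review true-positive when (1) the normal shows fewer than 3 alt
reads while the tumor shows at least 3, (2) both strands carry at
least one alt read, (3) at most 3 other mismatch positions lie within
the 40-bp window centered on the site, and (4) the site's allelic
configuration is clean (exactly one distinct alt allele, by default;
the literal inverted reading is configurable).  Genes whose calls fail
review at a high rate are blacklisted and removed from downstream
burden and association analyses.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PileupEvidence",
    "ReviewConfig",
    "ReviewCriterion",
    "ReviewResult",
    "review_variant",
    "gene_false_positive_rates",
    "build_blacklist",
    "apply_blacklist",
    "select_recurrent_genes",
]


@dataclass(frozen=True)
class PileupEvidence:
    """Stranded read counts and local context for one called variant."""

    tumor_alt: int
    normal_alt: int
    tumor_alt_fwd: int
    tumor_alt_rev: int
    mismatches_in_window: int
    distinct_alt_alleles: int

    def __post_init__(self) -> None:
        for name in ("tumor_alt", "normal_alt", "tumor_alt_fwd",
                     "tumor_alt_rev", "mismatches_in_window",
                     "distinct_alt_alleles"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tumor_alt != self.tumor_alt_fwd + self.tumor_alt_rev:
            raise ValueError(
                "tumor_alt must equal tumor_alt_fwd + tumor_alt_rev"
            )


@dataclass(frozen=True)
class ReviewConfig:
    """Review thresholds.

    ``window_bp`` is the mismatch-context window centered on the
    variant (+-window_bp/2); ``normal_alt_max`` is an exclusive bound
    (normal_alt must be strictly below it).  ``multiallelic_passes``
    flips criterion 4 to its literal reading (multiallelic
    configurations pass) — default False.
    """

    tumor_alt_min: int = 3
    normal_alt_max: int = 3
    window_bp: int = 40
    window_mismatch_max: int = 3
    require_both_strands: bool = True
    multiallelic_passes: bool = False

    def __post_init__(self) -> None:
        for name in ("tumor_alt_min", "normal_alt_max", "window_bp",
                     "window_mismatch_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class ReviewCriterion(str, enum.Enum):
    C1_ALT_COUNTS = "C1_alt_counts"
    C2_BOTH_STRANDS = "C2_both_strands"
    C3_WINDOW_MISMATCH = "C3_window_mismatch"
    C4_ALLELIC_CONFIGURATION = "C4_allelic_configuration"


@dataclass(frozen=True)
class ReviewResult:
    passed: bool
    failed_criteria: frozenset[ReviewCriterion]

    def __post_init__(self) -> None:
        assert self.passed == (not self.failed_criteria)


def review_variant(
    ev: PileupEvidence, cfg: ReviewConfig = ReviewConfig()
) -> ReviewResult:
    """Classify one variant's read evidence as true- or false-positive."""
    failed: set[ReviewCriterion] = set()
    if not (ev.normal_alt < cfg.normal_alt_max
            and ev.tumor_alt >= cfg.tumor_alt_min):
        failed.add(ReviewCriterion.C1_ALT_COUNTS)
    if cfg.require_both_strands and not (
        ev.tumor_alt_fwd >= 1 and ev.tumor_alt_rev >= 1
    ):
        failed.add(ReviewCriterion.C2_BOTH_STRANDS)
    if ev.mismatches_in_window > cfg.window_mismatch_max:
        failed.add(ReviewCriterion.C3_WINDOW_MISMATCH)
    multi = ev.distinct_alt_alleles >= 2
    if multi != cfg.multiallelic_passes:
        failed.add(ReviewCriterion.C4_ALLELIC_CONFIGURATION)
    return ReviewResult(passed=not failed, failed_criteria=frozenset(failed))


def gene_false_positive_rates(
    reviewed: Mapping[str, Iterable[ReviewResult]],
) -> pd.DataFrame:
    """Per-gene review failure rates.

    Returns a frame (gene, non_pass, total, rate) ordered by rate then
    total, both descending.  Genes with zero reviewed variants are
    never emitted.
    """
    rows = []
    for gene, results in reviewed.items():
        results = list(results)
        total = len(results)
        if total == 0:
            continue
        non_pass = sum(1 for r in results if not r.passed)
        rows.append({"gene": gene, "non_pass": non_pass, "total": total,
                     "rate": non_pass / total})
    df = pd.DataFrame(rows, columns=["gene", "non_pass", "total", "rate"])
    return df.sort_values(
        ["rate", "total", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)


def build_blacklist(
    rates: pd.DataFrame, fp_rate_min: float = 0.9, min_total: int = 50
) -> set[str]:
    """Genes whose review failure rate is >= fp_rate_min over >= min_total
    reviewed calls."""
    return {
        str(r.gene)
        for r in rates.itertuples(index=False)
        if r.total >= min_total and r.rate >= fp_rate_min
    }


def apply_blacklist(variants: list, genes: Mapping, blacklist: set[str]):
    """Split variants into (retained, removed) by gene blacklist.

    ``genes`` maps a variant (or its key) to a gene symbol; variants
    without a gene assignment are retained.  Conservation holds:
    retained + removed == input.
    """
    retained, removed = [], []
    for v in variants:
        key = getattr(v, "key", None)
        if key is not None and key in genes:
            gene = genes[key]
        else:
            try:
                gene = genes.get(v)
            except TypeError:
                gene = None
        (removed if gene in blacklist else retained).append(v)
    return retained, removed


def select_recurrent_genes(
    sample_genes: Mapping[str, set[str]],
    min_patients: int,
    n_patients: int,
) -> list[tuple[str, int]]:
    """Rank genes mutated in at least ``min_patients`` of ``n_patients``.

    ``sample_genes`` maps sample -> set of mutated gene symbols.
    Returns (gene, patient_count) sorted by count descending, ties
    broken lexicographically.
    """
    if min_patients > n_patients:
        raise ValueError("min_patients cannot exceed n_patients")
    counts: dict[str, int] = defaultdict(int)
    for genes in sample_genes.values():
        for g in genes:
            counts[g] += 1
    hits = [(g, c) for g, c in counts.items() if c >= min_patients]
    return sorted(hits, key=lambda gc: (-gc[1], gc[0]))
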