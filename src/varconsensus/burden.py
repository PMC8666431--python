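"""Consequence classification and tumor mutational burden.

TMB is the number of non-synonymous mutations per megabase of the
interrogated target region.  The denominator is the true merged length
of the capture design (91.08 Mb for SureSelect Human All Exon v6+UTR),
not the conventional 38 Mb whole-exome constant — using a denominator
that does not match the actual target rescales TMB by exactly
target_mb / 38 and biases cross-study comparison.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .consensus import TargetRegion

__all__ = [
    "ConsequenceClass",
    "VEP_TERM_MAP",
    "classify_consequence",
    "is_nonsynonymous",
    "TMBResult",
    "compute_tmb",
    "target_size_mb",
    "cohort_summary",
]


class ConsequenceClass(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    START_LOSS = "start_loss"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    STOP_RETAINED = "stop_retained"
    SPLICE_SITE = "splice_site"
    DINUCLEOTIDE = "dinucleotide"
    FRAMESHIFT = "frameshift"
    INFRAME = "inframe"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# VEP-style consequence terms -> the ten reporting classes
VEP_TERM_MAP: dict[str, ConsequenceClass] = {
    "synonymous_variant": ConsequenceClass.SYNONYMOUS,
    "missense_variant": ConsequenceClass.MISSENSE,
    "start_lost": ConsequenceClass.START_LOSS,
    "stop_gained": ConsequenceClass.STOP_GAIN,
    "stop_lost": ConsequenceClass.STOP_LOSS,
    "stop_retained_variant": ConsequenceClass.STOP_RETAINED,
    "splice_acceptor_variant": ConsequenceClass.SPLICE_SITE,
    "splice_donor_variant": ConsequenceClass.SPLICE_SITE,
    "splice_region_variant": ConsequenceClass.SPLICE_SITE,
    "dinucleotide_variant": ConsequenceClass.DINUCLEOTIDE,
    "frameshift_variant": ConsequenceClass.FRAMESHIFT,
    "inframe_insertion": ConsequenceClass.INFRAME,
    "inframe_deletion": ConsequenceClass.INFRAME,
}

# classes counted as non-synonymous for TMB (configurable at call site)
NONSYNONYMOUS_CLASSES = frozenset(
    c for c in ConsequenceClass
    if c not in (ConsequenceClass.SYNONYMOUS, ConsequenceClass.STOP_RETAINED)
)


def classify_consequence(term: str) -> ConsequenceClass:
    """Map a VEP-style consequence term to a reporting class."""
    try:
        return VEP_TERM_MAP[term]
    except KeyError:
        raise ValueError(f"unknown consequence term {term!r}") from None


def is_nonsynonymous(
    c: ConsequenceClass | str,
    nonsyn_classes: frozenset[ConsequenceClass] = NONSYNONYMOUS_CLASSES,
) -> bool:
    """Whether a consequence class counts toward TMB.

    All classes except synonymous and stop-retained are
    non-synonymous by default.
    """
    if isinstance(c, str):
        c = ConsequenceClass(c)
    return c in nonsyn_classes


@dataclass(frozen=True)
class TMBResult:
    sample_id: str
    nonsyn_count: float
    target_mb: float
    tmb: float


def compute_tmb(
    nonsyn_count: float, target_mb: float, sample_id: str = ""
) -> TMBResult:
    """Mutations per megabase over the given target size."""
    if target_mb <= 0:
        raise ValueError("target_mb must be positive")
    if nonsyn_count < 0:
        raise ValueError("nonsyn_count must be non-negative")
    return TMBResult(
        sample_id=sample_id,
        nonsyn_count=nonsyn_count,
        target_mb=target_mb,
        tmb=nonsyn_count / target_mb,
    )


def target_size_mb(bed: TargetRegion) -> float:
    """Merged target length in megabases; overlaps are never
    double-counted."""
    mb = bed.total_size_mb
    if mb <= 0:
        raise ValueError("target region is empty")
    return mb


def cohort_summary(
    per_sample_counts: Mapping[str, int],
    per_sample_tmb: Mapping[str, float],
    class_tallies: Mapping[ConsequenceClass, int] | None = None,
) -> dict:
    """Cohort means/medians of per-sample mutation counts and TMB.

    When class tallies are supplied their sum must equal the total
    retained mutation count (conservation check).
    """
    if not per_sample_counts:
        raise ValueError("at least one sample required")
    counts = np.array(list(per_sample_counts.values()), dtype=float)
    tmbs = np.array(
        [per_sample_tmb[s] for s in per_sample_counts], dtype=float
    )
    out = {
        "n_samples": len(counts),
        "total_mutations": float(counts.sum()),
        "mean_mutations_per_patient": float(counts.mean()),
        "median_mutations_per_patient": float(np.median(counts)),
        "mean_tmb": float(tmbs.mean()),
        "median_tmb": float(np.median(tmbs)),
    }
    if class_tallies is not None:
        tally_sum = int(sum(class_tallies.values()))
        if tally_sum != int(counts.sum()):
            raise ValueError(
                f"consequence tallies sum to {tally_sum}, expected "
                f"{int(counts.sum())} retained mutations"
            )
        out["consequence_tallies"] = {
            k.value: int(v) for k, v in class_tallies.items()
        }
    return out
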