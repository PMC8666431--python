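"""Association of mutation burden and gene/pathway mutation status
with clinical covariates and overall survival.

Continuous burden is compared between covariate groups by the
Mann-Whitney U test (exact for small tie-free inputs, normal
approximation with tie correction otherwise); categorical associations
use Fisher's exact test for sparse 2x2 tables and chi-square
otherwise; overall survival is compared by Kaplan-Meier curves with
the two-group log-rank test.  Raw p-values are reported by default;
Benjamini-Hochberg adjustment is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "ClinicalRecord",
    "GeneSet",
    "NFKB_GENE_SET",
    "CALCIUM_GENE_SET",
    "load_clinical_table",
    "mann_whitney",
    "association_test",
    "km_logrank",
    "tmb_median_split",
    "geneset_status",
    "bh_adjust",
]


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient covariates and right-censored overall survival."""

    sample_id: str
    age: float
    sex: str
    t_stage: str
    n_stage: str
    clinical_stage: str
    differentiation: str
    perineural_invasion: bool
    lymphovascular_invasion: bool
    hpv_p16: bool
    os_time: float
    os_event: bool

    def __post_init__(self) -> None:
        if self.os_time < 0:
            raise ValueError("os_time must be non-negative")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene set must be non-empty")


NFKB_GENE_SET = GeneSet(
    "NFkB_signaling",
    frozenset({"CARD10", "CASP8", "EP300", "FGFR1", "IGF2R", "PIK3CA"}),
)
CALCIUM_GENE_SET = GeneSet(
    "calcium_signaling",
    frozenset({"ADCY2", "CASP8", "ITPR1", "ITPR2", "PIK3CA", "PLCB1", "PLCB3"}),
)


def load_clinical_table(path) -> list[ClinicalRecord]:
    """Read the clinical TSV (one row per patient)."""
    df = pd.read_csv(path, sep="\t")
    bools = ("perineural_invasion", "lymphovascular_invasion",
             "hpv_p16", "os_event")
    records = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        for b in bools:
            d[b] = bool(int(d[b]))
        records.append(ClinicalRecord(**{k: d[k] for k in
                                         ClinicalRecord.__dataclass_fields__}))
    return records


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample a, p).

    Exact null distribution (dynamic-programming enumeration) for
    tie-free inputs with n_a * n_b <= 400; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    tie_free = len(np.unique(np.r_[a, b])) == a.size + b.size
    method = "exact" if (tie_free and a.size * b.size <= 400) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def association_test(table) -> dict:
    """Association test on a 2xK contingency table of counts.

    Fisher's exact test for 2x2 tables with any expected cell of 5 or
    fewer, chi-square (no continuity correction) otherwise.  The test
    chosen is recorded in the result.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or (t < 0).any():
        raise ValueError("need a 2xK table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if t.shape == (2, 2) and (expected <= 5).any():
        stat, p = stats.fisher_exact(t, alternative="two-sided")
        test = "fisher_exact"
    else:
        stat, p, _, _ = stats.chi2_contingency(t, correction=False)
        test = "chi_square"
    return {"test": test, "statistic": float(stat), "p": float(p)}


def km_logrank(
    times: Sequence[float],
    events: Sequence[bool],
    group: Sequence[int],
) -> dict:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    ``group`` is binary (0/1).  Ties at event times use the standard
    hypergeometric variance.  Raises if no events at all were observed
    (the test statistic is undefined).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group, dtype=int)
    if not ((group == 0).any() and (group == 1).any()):
        raise ValueError("both groups must be non-empty")
    if not events.any():
        raise ValueError("no events observed; log-rank is undefined")
    curves = {}
    for g in (0, 1):
        m = group == g
        kmf = KaplanMeierFitter(label=f"group{g}")
        kmf.fit(times[m], event_observed=events[m])
        curves[g] = kmf
    res = logrank_test(
        times[group == 0], times[group == 1],
        event_observed_A=events[group == 0],
        event_observed_B=events[group == 1],
    )
    return {
        "curves": curves,
        "chi2": float(res.test_statistic),
        "p": float(res.p_value),
        "n": (int((group == 0).sum()), int((group == 1).sum())),
    }


def tmb_median_split(tmb: Mapping[str, float]) -> tuple[dict[str, int], float]:
    """Split samples at the cohort median TMB.

    Samples at or below the median go to the low group (0); above to
    the high group (1).  Returns (sample -> group, cutpoint).
    """
    if len(tmb) < 2:
        raise ValueError("need at least two samples")
    values = np.array(list(tmb.values()), dtype=float)
    cut = float(np.median(values))
    return {s: int(v > cut) for s, v in tmb.items()}, cut


def geneset_status(
    sample_genes: Mapping[str, set[str]], gene_set: GeneSet
) -> dict[str, int]:
    """Binary per-sample pathway status: 1 iff the sample's mutated
    gene set intersects the pathway gene set."""
    return {
        s: int(bool(genes & gene_set.genes))
        for s, genes in sample_genes.items()
    }


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; raw p is the
    default reporting)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
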