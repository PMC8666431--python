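"""Synthetic tumor/normal cohort generator.

Emits everything the pipeline consumes, fully labeled: per-patient
VCFs in all six caller dialects, a normals alt-read evidence table
(panel-of-normals input), a population allele-frequency table, the
capture-target BED, a VEP-style consequence annotation table, a
per-variant pileup-evidence table, a clinical table with a planted
burden-linked survival effect, and a truth table tracing every emitted
call to its origin.

The cohort emulates a 50-patient tumor/normal study on a two-
chromosome mini-genome (~5 Mb) with a declared gene map that includes
two FP-enriched mucin-like genes (recurrent artifact loci at extreme
read depth) and a titin-like large gene.  True somatic events are
clean by construction (balanced strands, ample tumor support, quiet
normals, minimum spacing) so that filter flags remove only what was
planted as an artifact; dinucleotide truths are emitted by all six
callers — as a 2-bp MNV by Mutect2 and VarDict and as two adjacent
SNVs by the other four — making planted-count recovery after MNV
reconstruction exact.  Ordinary SNV/indel detection is Bernoulli per
caller sensitivity, so single-caller detections (and hence the
union-vs-consensus recall gap) remain real.

Everything is driven by one seeded generator: the same seed yields
byte-identical output directories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .callers import CallerId, VariantClass

__all__ = ["SimulationConfig", "TruthRecord", "simulate_cohort", "emit_pileups"]

CHROM_SIZES = {"chr1": 3_000_000, "chr2": 2_000_000}
BASES = np.array(list("ACGT"))

SNV_CALLERS = list(CallerId)
INDEL_CALLERS = [CallerId.MUTECT2, CallerId.STRELKA2,
                 CallerId.VARSCAN2, CallerId.VARDICT]
MNV_AS_MNV = [CallerId.MUTECT2, CallerId.VARDICT]
STRANDED_CALLERS = [CallerId.MUTECT2, CallerId.SOMATICSNIPER,
                    CallerId.VARSCAN2, CallerId.VARDICT]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults mirror the emulated study design: 50 tumor/normal pairs,
    six callers with heterogeneous sensitivity/false-positive
    profiles, germline leak-through recurrent across normals, oxoG /
    strand-bias / clustered / multiallelic artifacts, FP-enriched
    blacklist genes, and a burden-linked hazard on overall survival.
    """

    n_patients: int = 50
    seed: int = 0
    # truth event intensities (per patient)
    snvs_per_patient: float = 40.0
    indels_per_patient: float = 6.0
    dinucleotides_per_patient: int = 3
    offtarget_per_patient: float = 5.0
    tmb_dispersion: float = 0.45  # lognormal sigma on the patient rate
    # artifact intensities (per patient unless noted)
    n_leak_sites: int = 30  # shared germline-leak pool (cohort-wide)
    leak_call_rate: float = 0.25
    n_common_snp_sites: int = 15
    common_snp_call_rate: float = 0.2
    oxog_per_patient: float = 5.0
    strand_bias_per_patient: float = 4.0
    clustered_groups_per_patient: float = 2.0
    multiallelic_per_patient: float = 3.0
    repeat_fp_per_patient: float = 10.0  # per blacklist gene
    blacklist_true_rate: float = 0.1  # true somatics in blacklist genes
    caller_fp_per_patient: float = 12.0
    # caller profiles
    # wide spread, mirroring the large per-caller disagreement in
    # multi-caller studies (call counts differing by almost an order
    # of magnitude between the weakest and strongest callers)
    sensitivity: dict = field(default_factory=lambda: {
        CallerId.MUSE: 0.45, CallerId.MUTECT2: 0.90,
        CallerId.SOMATICSNIPER: 0.30, CallerId.STRELKA2: 0.85,
        CallerId.VARSCAN2: 0.25, CallerId.VARDICT: 0.60,
    })
    caller_fp_weight: dict = field(default_factory=lambda: {
        CallerId.MUSE: 0.5, CallerId.MUTECT2: 2.0,
        CallerId.SOMATICSNIPER: 1.8, CallerId.STRELKA2: 0.6,
        CallerId.VARSCAN2: 0.7, CallerId.VARDICT: 0.9,
    })
    # review / evidence
    review_tp_rate: float = 0.98
    # clinical effect sizes
    hazard_ratio_high_tmb: float = 3.0
    base_hazard: float = 0.015  # events per month in the low-burden group
    stage_iv_prob_high: float = 0.85
    stage_iv_prob_low: float = 0.50
    age_shift_high: float = 7.0  # years added to the high-burden group mean

    def validate(self) -> None:
        rates = {
            "leak_call_rate": self.leak_call_rate,
            "common_snp_call_rate": self.common_snp_call_rate,
            "blacklist_true_rate": self.blacklist_true_rate,
            "review_tp_rate": self.review_tp_rate,
            "stage_iv_prob_high": self.stage_iv_prob_high,
            "stage_iv_prob_low": self.stage_iv_prob_low,
        }
        rates.update({f"sensitivity[{k.value}]": v
                      for k, v in self.sensitivity.items()})
        for name, r in rates.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.dinucleotides_per_patient < 0:
            raise ValueError("dinucleotides_per_patient must be >= 0")


# ---------------------------------------------------------------------------
# Gene map: driver genes at the emulated study's mutation frequencies,
# two FP-enriched blacklist genes, a large passenger gene, and fillers.

DRIVER_FREQS = {
    "TP53": 0.62, "FAT1": 0.40, "NOTCH1": 0.28, "CASP8": 0.22,
    "EPHA2": 0.16, "PIK3CA": 0.14, "HYDIN": 0.14, "KMT2D": 0.14,
    "EP300": 0.12, "IGF2R": 0.12, "ITPR2": 0.12, "CARD10": 0.10,
    "PLCB3": 0.10, "ADCY2": 0.08, "PLCB1": 0.08, "ITPR1": 0.08,
    "FGFR1": 0.08,
}
BLACKLIST_GENES = ["MUC16", "MUC19"]
N_FILLER_GENES = 20


def build_gene_map() -> pd.DataFrame:
    """Deterministic gene layout on the two-chromosome mini-genome."""
    rows = []

    def lay(chrom, start, names, length, gap=30_000):
        pos = start
        for name in names:
            rows.append({"gene": name, "chrom": chrom,
                         "start": pos, "end": pos + length})
            pos += length + gap
        return pos

    pos = lay("chr1", 100_000, list(DRIVER_FREQS)[:9], 20_000)
    pos = lay("chr1", pos, ["TTN"], 120_000)
    lay("chr1", pos, ["MUC16", "MUC19"], 60_000)
    pos = lay("chr2", 100_000, list(DRIVER_FREQS)[9:], 20_000)
    lay("chr2", pos, [f"GENE{i:02d}" for i in range(1, N_FILLER_GENES + 1)],
        15_000)
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


@dataclass
class TruthRecord:
    """One planted event (true somatic or labeled artifact) with the
    call evidence shared by every caller that emits it."""

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    label: str
    gene: str
    consequence: str
    in_target: bool
    variant_class: VariantClass
    callers: list[CallerId]
    # shared call evidence
    dp: int
    t_ref: int
    t_alt: int
    n_ref: int
    n_alt: int
    t_ref_fwd: int
    t_ref_rev: int
    t_alt_fwd: int
    t_alt_rev: int
    # pileup-review evidence
    mismatches_in_window: int
    distinct_alt_alleles: int
    # dialect verdicts
    somatic_pass: bool = True
    extra_alt: Optional[str] = None  # second alt for multiallelic lines

    @property
    def maf(self) -> float:
        return self.t_alt / (self.t_alt + self.t_ref)


# ---------------------------------------------------------------------------
# Event construction helpers


def _split_even(total: int) -> tuple[int, int]:
    return total - total // 2, total // 2


def _pick_pos(rng, lo: int, hi: int, used: set[int], spacing: int = 200) -> int:
    """Draw a position in [lo, hi) at least `spacing` from used ones."""
    for _ in range(200):
        p = int(rng.integers(lo, hi))
        if all(abs(p - u) >= spacing for u in used):
            used.add(p)
            return p
    raise RuntimeError("could not place variant; region too crowded")


def _alleles(rng, kind: str) -> tuple[str, str]:
    ref = str(rng.choice(BASES))
    if kind == "snv":
        alt = str(rng.choice([b for b in BASES if b != ref]))
        return ref, alt
    if kind == "dinuc":
        ref2 = ref + str(rng.choice(BASES))
        alt2 = "".join(str(rng.choice([b for b in BASES if b != r]))
                       for r in ref2)
        return ref2, alt2
    if kind == "ins":
        ins = "".join(rng.choice(BASES, size=int(rng.integers(1, 4))))
        return ref, ref + ins
    if kind == "del":
        tail = "".join(rng.choice(BASES, size=int(rng.integers(1, 4))))
        return ref + tail, ref
    raise ValueError(kind)


_SNV_TERMS = ["missense_variant", "synonymous_variant", "stop_gained",
              "splice_donor_variant", "splice_acceptor_variant",
              "start_lost", "stop_lost", "stop_retained_variant"]
_SNV_TERM_P = [0.595, 0.25, 0.06, 0.04, 0.03, 0.01, 0.01, 0.005]
_INDEL_TERMS = ["frameshift_variant", "inframe_insertion", "inframe_deletion"]


def _consequence(rng, kind: str, alt_longer: bool) -> str:
    if kind == "snv":
        return str(rng.choice(_SNV_TERMS, p=_SNV_TERM_P))
    if kind == "dinuc":
        return "dinucleotide_variant"
    if rng.random() < 0.7:
        return "frameshift_variant"
    return "inframe_insertion" if alt_longer else "inframe_deletion"


def _clean_evidence(rng, cfg: SimulationConfig) -> dict:
    """Evidence profile of a genuine clonal somatic call: ample
    balanced tumor support, quiet normal, quiet local context."""
    dp = int(rng.poisson(110)) + 30
    maf = float(rng.beta(8, 16))
    t_alt = max(5, int(round(dp * maf)))
    t_ref = dp - t_alt
    taf, tar = _split_even(t_alt)
    trf, trr = _split_even(t_ref)
    n_alt = int(rng.random() < 0.15)
    mism = int(min(rng.poisson(0.4), 3))
    if rng.random() > cfg.review_tp_rate:
        mism = int(rng.integers(4, 9))  # occasional noisy context
    return dict(dp=dp, t_ref=t_ref, t_alt=t_alt, n_ref=dp - n_alt,
                n_alt=n_alt, t_ref_fwd=trf, t_ref_rev=trr,
                t_alt_fwd=taf, t_alt_rev=tar,
                mismatches_in_window=mism, distinct_alt_alleles=1)


def _bernoulli_callers(rng, cfg: SimulationConfig, pool) -> list[CallerId]:
    return [c for c in pool if rng.random() < cfg.sensitivity[c]]


# ---------------------------------------------------------------------------
# Cohort generation


def _generate_truth(cfg: SimulationConfig, rng) -> tuple[list[TruthRecord], dict]:
    gene_map = build_gene_map()
    genes = {r.gene: (r.chrom, r.start, r.end)
             for r in gene_map.itertuples(index=False)}
    samples = [f"P{i:02d}" for i in range(1, cfg.n_patients + 1)]

    # capture target: all gene bodies plus deterministic intergenic probes;
    # a chr2 tail beyond 1.9 Mb is deliberately untargeted
    target = [(r.chrom, r.start, r.end)
              for r in gene_map.itertuples(index=False)]
    target += [("chr1", 50_000, 60_000), ("chr2", 50_000, 60_000)]
    offtarget_window = ("chr2", 1_900_000, CHROM_SIZES["chr2"])

    # shared germline-leak pool and common-SNP pool, placed inside genes
    gene_names = list(genes)
    pool_used: set[int] = set()

    def pool_sites(n):
        sites = []
        for _ in range(n):
            g = gene_names[int(rng.integers(0, len(gene_names)))]
            chrom, lo, hi = genes[g]
            pos = _pick_pos(rng, lo, hi, pool_used)
            ref, alt = _alleles(rng, "snv")
            sites.append((chrom, pos, ref, alt, g))
        return sites

    leak_sites = pool_sites(cfg.n_leak_sites)
    snp_sites = pool_sites(cfg.n_common_snp_sites)
    pop_af = [
        {"chrom": c, "pos": p, "ref": r, "alt": a,
         "af": round(float(rng.uniform(0.02, 0.30)), 4)}
        for c, p, r, a, _ in snp_sites
    ]

    # normals evidence: each leak site alt-supported in many normals
    normal_evidence = []
    for chrom, pos, ref, alt, _ in leak_sites:
        lo = max(2, int(0.4 * cfg.n_patients))
        hi = max(lo + 1, int(0.9 * cfg.n_patients))
        carriers = rng.choice(cfg.n_patients,
                              size=int(rng.integers(lo, hi + 1)),
                              replace=False)
        for i in sorted(carriers):
            normal_evidence.append({
                "sample": samples[i] + "_N", "chrom": chrom, "pos": pos,
                "alt": alt, "alt_reads": int(rng.integers(3, 13)),
            })

    truths: list[TruthRecord] = []
    per_patient_rate = cfg.snvs_per_patient * rng.lognormal(
        0.0, cfg.tmb_dispersion, size=cfg.n_patients
    )

    for pi, sid in enumerate(samples):
        used: set[int] = set(pool_used)

        def in_gene(g):
            chrom, lo, hi = genes[g]
            return chrom, _pick_pos(rng, lo, hi, used)

        def add(chrom, pos, ref, alt, label, gene, consequence, vclass,
                callers, ev, in_target=True, **kw):
            truths.append(TruthRecord(
                sample=sid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                label=label, gene=gene, consequence=consequence,
                in_target=in_target, variant_class=vclass,
                callers=callers, **ev, **kw))

        # --- true somatic background SNVs in filler + large genes
        n_bg = int(rng.poisson(per_patient_rate[pi]))
        bg_genes = [f"GENE{i:02d}" for i in range(1, N_FILLER_GENES + 1)]
        bg_genes += ["TTN", "HYDIN", "KMT2D"]
        for _ in range(n_bg):
            g = bg_genes[int(rng.integers(0, len(bg_genes)))]
            chrom, pos = in_gene(g)
            ref, alt = _alleles(rng, "snv")
            add(chrom, pos, ref, alt, "somatic", g,
                _consequence(rng, "snv", False), VariantClass.SNV,
                _bernoulli_callers(rng, cfg, SNV_CALLERS),
                _clean_evidence(rng, cfg))

        # --- driver-gene hits (planted recurrence)
        for g, freq in DRIVER_FREQS.items():
            if rng.random() < freq:
                chrom, pos = in_gene(g)
                ref, alt = _alleles(rng, "snv")
                terms = ["missense_variant", "stop_gained", "splice_donor_variant"]
                add(chrom, pos, ref, alt, "somatic", g,
                    str(rng.choice(terms, p=[0.7, 0.2, 0.1])), VariantClass.SNV,
                    _bernoulli_callers(rng, cfg, SNV_CALLERS),
                    _clean_evidence(rng, cfg))

        # --- indels
        for _ in range(int(rng.poisson(cfg.indels_per_patient))):
            g = bg_genes[int(rng.integers(0, len(bg_genes)))]
            chrom, pos = in_gene(g)
            kind = "ins" if rng.random() < 0.5 else "del"
            ref, alt = _alleles(rng, kind)
            add(chrom, pos, ref, alt, "somatic", g,
                _consequence(rng, "indel", len(alt) > len(ref)),
                VariantClass.INSERTION if kind == "ins" else VariantClass.DELETION,
                _bernoulli_callers(rng, cfg, INDEL_CALLERS),
                _clean_evidence(rng, cfg))

        # --- dinucleotide truths: clonal, detected by all six callers
        for _ in range(cfg.dinucleotides_per_patient):
            g = bg_genes[int(rng.integers(0, len(bg_genes)))]
            chrom, lo, hi = genes[g]
            pos = _pick_pos(rng, lo, hi - 1, used)
            used.add(pos + 1)
            ref, alt = _alleles(rng, "dinuc")
            add(chrom, pos, ref, alt, "somatic", g, "dinucleotide_variant",
                VariantClass.MNV, list(SNV_CALLERS),
                _clean_evidence(rng, cfg))

        # --- off-target somatics (must be removed by target restriction)
        oc, olo, ohi = offtarget_window
        for _ in range(int(rng.poisson(cfg.offtarget_per_patient))):
            pos = _pick_pos(rng, olo, ohi, used)
            ref, alt = _alleles(rng, "snv")
            add(oc, pos, ref, alt, "somatic", "", "missense_variant",
                VariantClass.SNV, _bernoulli_callers(rng, cfg, SNV_CALLERS),
                _clean_evidence(rng, cfg), in_target=False)

        # --- germline leak-through (PoN + N_Alt flags catch these)
        for chrom, pos, ref, alt, g in leak_sites:
            if rng.random() < cfg.leak_call_rate:
                ev = _clean_evidence(rng, cfg)
                n_alt = int(rng.integers(5, 16))
                ev.update(n_alt=n_alt, n_ref=ev["dp"] - n_alt)
                callers = [c for c in SNV_CALLERS if rng.random() < 0.9]
                add(chrom, pos, ref, alt, "germline_leak", g,
                    "missense_variant", VariantClass.SNV, callers, ev)

        # --- common polymorphisms (population-AF flag catches these)
        for chrom, pos, ref, alt, g in snp_sites:
            if rng.random() < cfg.common_snp_call_rate:
                ev = _clean_evidence(rng, cfg)
                callers = [c for c in SNV_CALLERS if rng.random() < 0.9]
                add(chrom, pos, ref, alt, "common_snp", g,
                    "missense_variant", VariantClass.SNV, callers, ev)

        # --- oxoG artifacts: C>A (forward-skew) or G>T (reverse-skew)
        for _ in range(int(rng.poisson(cfg.oxog_per_patient))):
            g = gene_names[int(rng.integers(0, len(gene_names)))]
            chrom, pos = in_gene(g)
            ref, alt = ("C", "A") if rng.random() < 0.5 else ("G", "T")
            ev = _clean_evidence(rng, cfg)
            skew_fwd = ref == "C"
            ev.update(t_alt_fwd=ev["t_alt"] if skew_fwd else 0,
                      t_alt_rev=0 if skew_fwd else ev["t_alt"])
            callers = [c for c in STRANDED_CALLERS if rng.random() < 0.85]
            add(chrom, pos, ref, alt, "oxoG_artifact", g,
                "missense_variant", VariantClass.SNV, callers, ev)

        # --- strand-bias artifacts: all alt reads on one strand
        for _ in range(int(rng.poisson(cfg.strand_bias_per_patient))):
            g = gene_names[int(rng.integers(0, len(gene_names)))]
            chrom, pos = in_gene(g)
            ref = str(rng.choice(["A", "T"]))
            alt = "G" if ref == "A" else "C"  # avoid the oxoG pairs
            ev = _clean_evidence(rng, cfg)
            ev.update(t_alt_fwd=ev["t_alt"], t_alt_rev=0)
            callers = [c for c in STRANDED_CALLERS if rng.random() < 0.85]
            add(chrom, pos, ref, alt, "strand_bias_artifact", g,
                "missense_variant", VariantClass.SNV, callers, ev)

        # --- clustered artifacts: bursts of 3 calls within a short span
        for _ in range(int(rng.poisson(cfg.clustered_groups_per_patient))):
            g = gene_names[int(rng.integers(0, len(gene_names)))]
            chrom, lo, hi = genes[g]
            anchor = _pick_pos(rng, lo, hi - 60, used)
            offsets = (0, int(rng.integers(5, 20)), int(rng.integers(20, 41)))
            callers = [c for c in SNV_CALLERS if rng.random() < 0.8]
            for off in offsets:
                used.add(anchor + off)
                ref, alt = _alleles(rng, "snv")
                add(chrom, anchor + off, ref, alt, "clustered_artifact", g,
                    "missense_variant", VariantClass.SNV, callers or
                    [CallerId.MUTECT2], _clean_evidence(rng, cfg))

        # --- multiallelic artifacts: two alts on one line
        for _ in range(int(rng.poisson(cfg.multiallelic_per_patient))):
            g = gene_names[int(rng.integers(0, len(gene_names)))]
            chrom, pos = in_gene(g)
            ref, alt = _alleles(rng, "snv")
            alt2 = str(rng.choice([b for b in BASES if b not in (ref, alt)]))
            ev = _clean_evidence(rng, cfg)
            ev.update(distinct_alt_alleles=2)
            callers = [c for c in SNV_CALLERS if rng.random() < 0.8]
            add(chrom, pos, ref, alt, "multiallelic_artifact", g,
                "missense_variant", VariantClass.SNV,
                callers or [CallerId.MUTECT2], ev, extra_alt=alt2)

        # --- repeat-locus FPs in the blacklist genes: shared across
        #     callers (they survive consensus), extreme depth, dirty
        #     local context (fail review)
        for g in BLACKLIST_GENES:
            for _ in range(int(rng.poisson(cfg.repeat_fp_per_patient))):
                chrom, pos = in_gene(g)
                ref, alt = _alleles(rng, "snv")
                dp = int(rng.integers(1000, 1600))
                t_alt = int(rng.integers(8, 25))
                taf, tar = _split_even(t_alt)
                trf, trr = _split_even(dp - t_alt)
                ev = dict(dp=dp, t_ref=dp - t_alt, t_alt=t_alt,
                          n_ref=dp, n_alt=int(rng.integers(0, 3)),
                          t_ref_fwd=trf, t_ref_rev=trr,
                          t_alt_fwd=taf, t_alt_rev=tar,
                          mismatches_in_window=int(rng.integers(4, 13)),
                          distinct_alt_alleles=1)
                callers = [c for c in SNV_CALLERS if rng.random() < 0.8]
                if len(callers) < 2:
                    callers = [CallerId.MUTECT2, CallerId.STRELKA2]
                add(chrom, pos, ref, alt, "repeat_fp", g,
                    "missense_variant", VariantClass.SNV, callers, ev)
            # an occasional genuine somatic in the same gene
            if rng.random() < cfg.blacklist_true_rate:
                chrom, pos = in_gene(g)
                ref, alt = _alleles(rng, "snv")
                add(chrom, pos, ref, alt, "somatic", g, "missense_variant",
                    VariantClass.SNV,
                    _bernoulli_callers(rng, cfg, SNV_CALLERS),
                    _clean_evidence(rng, cfg))

        # --- caller-private false positives (single caller by
        #     construction; consensus removes them)
        for c in SNV_CALLERS:
            lam = cfg.caller_fp_per_patient * cfg.caller_fp_weight[c]
            for _ in range(int(rng.poisson(lam))):
                g = gene_names[int(rng.integers(0, len(gene_names)))]
                chrom, pos = in_gene(g)
                ref, alt = _alleles(rng, "snv")
                ev = _clean_evidence(rng, cfg)
                t_alt = int(rng.integers(1, 7))
                taf, tar = _split_even(t_alt)
                ev.update(t_alt=t_alt, t_ref=ev["dp"] - t_alt,
                          t_alt_fwd=taf, t_alt_rev=tar)
                # some FPs fail the caller's own somatic verdict
                add(chrom, pos, ref, alt, "caller_fp", g,
                    "missense_variant", VariantClass.SNV, [c], ev,
                    somatic_pass=rng.random() < 0.7)

    aux = {
        "samples": samples,
        "gene_map": gene_map,
        "target": target,
        "pop_af": pd.DataFrame(pop_af,
                               columns=["chrom", "pos", "ref", "alt", "af"]),
        "normal_evidence": pd.DataFrame(
            normal_evidence,
            columns=["sample", "chrom", "pos", "alt", "alt_reads"]),
    }
    return truths, aux


# ---------------------------------------------------------------------------
# Clinical table with planted burden effects


def _clinical_table(cfg: SimulationConfig, rng,
                    truths: list[TruthRecord], samples, target_mb) -> pd.DataFrame:
    from .burden import is_nonsynonymous, classify_consequence

    nonsyn = {s: 0 for s in samples}
    for t in truths:
        if t.label == "somatic" and t.in_target and t.gene and \
                is_nonsynonymous(classify_consequence(t.consequence)):
            nonsyn[t.sample] += 1
    tmb = {s: nonsyn[s] / target_mb for s in samples}
    cut = float(np.median(list(tmb.values())))
    rows = []
    for i, s in enumerate(samples):
        high = tmb[s] > cut
        age = float(np.clip(rng.normal(57 + cfg.age_shift_high * high, 9),
                            40, 89))
        stage_iv = rng.random() < (cfg.stage_iv_prob_high if high
                                   else cfg.stage_iv_prob_low)
        hazard = cfg.base_hazard * (cfg.hazard_ratio_high_tmb if high else 1.0)
        t_death = float(rng.exponential(1.0 / hazard))
        t_censor = float(rng.uniform(24, 72))
        rows.append({
            "sample_id": s,
            "age": round(age, 1),
            "sex": "F" if i < 2 else "M",
            "t_stage": "T4" if stage_iv and rng.random() < 0.9 else
                       str(rng.choice(["T1", "T2", "T3"])),
            "n_stage": str(rng.choice(["N0", "N1", "N2"], p=[0.56, 0.24, 0.2])),
            "clinical_stage": "IV" if stage_iv else
                              str(rng.choice(["I", "II", "III"])),
            "differentiation": str(rng.choice(["well", "moderate", "poor"],
                                              p=[0.72, 0.2, 0.08])),
            "perineural_invasion": int(rng.random() < 0.34),
            "lymphovascular_invasion": int(rng.random() < 0.22),
            "hpv_p16": int(rng.random() < 0.08),
            "os_time": round(min(t_death, t_censor), 2),
            "os_event": int(t_death <= t_censor),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dialect VCF emission (plain text, deterministic)

_VCF_COMMON = (
    "##fileformat=VCFv4.2\n"
    + "".join(f"##contig=<ID={c},length={l}>\n" for c, l in CHROM_SIZES.items())
)

_DIALECT_HEADERS = {
    CallerId.MUSE: (
        '##FILTER=<ID=Tier5,Description="Low confidence">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
    ),
    CallerId.MUTECT2: (
        '##FILTER=<ID=germline,Description="Germline risk">\n'
        '##FILTER=<ID=weak_evidence,Description="Weak evidence">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        '##FORMAT=<ID=SB,Number=4,Type=Integer,Description="Per-strand ref/alt counts">\n'
    ),
    CallerId.SOMATICSNIPER: (
        '##FILTER=<ID=LowQual,Description="Low quality">\n'
        '##FORMAT=<ID=DP4,Number=4,Type=Integer,Description="ref-fwd,ref-rev,alt-fwd,alt-rev">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
    ),
    CallerId.STRELKA2: (
        '##FILTER=<ID=LowEVS,Description="Low evidence score">\n'
        '##FORMAT=<ID=AU,Number=2,Type=Integer,Description="A tier1,tier2">\n'
        '##FORMAT=<ID=CU,Number=2,Type=Integer,Description="C tier1,tier2">\n'
        '##FORMAT=<ID=GU,Number=2,Type=Integer,Description="G tier1,tier2">\n'
        '##FORMAT=<ID=TU,Number=2,Type=Integer,Description="T tier1,tier2">\n'
        '##FORMAT=<ID=TAR,Number=2,Type=Integer,Description="Ref-supporting tiers">\n'
        '##FORMAT=<ID=TIR,Number=2,Type=Integer,Description="Indel-supporting tiers">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
    ),
    CallerId.VARSCAN2: (
        '##INFO=<ID=SS,Number=1,Type=String,Description="Somatic status">\n'
        '##FORMAT=<ID=RD,Number=1,Type=Integer,Description="Ref depth">\n'
        '##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Alt depth">\n'
        '##FORMAT=<ID=DP4,Number=1,Type=String,Description="ref-fwd,ref-rev,alt-fwd,alt-rev">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
    ),
    CallerId.VARDICT: (
        '##INFO=<ID=STATUS,Number=1,Type=String,Description="Somatic status">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        '##FORMAT=<ID=RD,Number=2,Type=Integer,Description="Ref fwd,rev">\n'
        '##FORMAT=<ID=ALD,Number=2,Type=Integer,Description="Alt fwd,rev">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
    ),
}

# Mutect2 lists the normal column first (alphabetical), the rest tumor-first
_NORMAL_FIRST = {CallerId.MUTECT2}

_FAIL_VERDICT = {
    CallerId.MUSE: ("Tier5", "."),
    CallerId.MUTECT2: ("germline", "."),
    CallerId.SOMATICSNIPER: ("LowQual", "."),
    CallerId.STRELKA2: ("LowEVS", "."),
    CallerId.VARSCAN2: ("PASS", "SS=Germline"),
    CallerId.VARDICT: ("PASS", "STATUS=LikelySomatic"),
}
_PASS_VERDICT = {
    CallerId.MUSE: ("PASS", "."),
    CallerId.MUTECT2: ("PASS", "."),
    CallerId.SOMATICSNIPER: ("PASS", "."),
    CallerId.STRELKA2: ("PASS", "."),
    CallerId.VARSCAN2: ("PASS", "SS=Somatic"),
    CallerId.VARDICT: ("PASS", "STATUS=StrongSomatic"),
}


def _strelka_snv_fmt(t: TruthRecord, ref: str, alt: str) -> tuple[str, str, str]:
    counts_t = {b: [0, 0] for b in "ACGT"}
    counts_n = {b: [0, 0] for b in "ACGT"}
    counts_t[ref[0]] = [t.t_ref, t.t_ref]
    counts_t[alt[0]] = [t.t_alt, t.t_alt]
    counts_n[ref[0]] = [t.n_ref, t.n_ref]
    counts_n[alt[0]] = [t.n_alt, t.n_alt]
    fmt = "AU:CU:GU:TU:DP"
    tum = ":".join(f"{counts_t[b][0]},{counts_t[b][1]}" for b in "ACGT")
    nor = ":".join(f"{counts_n[b][0]},{counts_n[b][1]}" for b in "ACGT")
    return fmt, f"{tum}:{t.dp}", f"{nor}:{t.dp}"


def _format_line(t: TruthRecord, caller: CallerId,
                 ref: str, alt: str, alts: str) -> str:
    filt, info = (_PASS_VERDICT if t.somatic_pass else _FAIL_VERDICT)[caller]
    if caller in (CallerId.MUSE, CallerId.MUTECT2):
        ad_t = f"{t.t_ref},{t.t_alt}"
        ad_n = f"{t.n_ref},{t.n_alt}"
        if t.extra_alt is not None:
            ad_t += f",{max(3, t.t_alt // 2)}"
            ad_n += ",0"
        if caller is CallerId.MUTECT2:
            fmt = "AD:DP:SB"
            sb = f"{t.t_ref_fwd},{t.t_ref_rev},{t.t_alt_fwd},{t.t_alt_rev}"
            tum, nor = f"{ad_t}:{t.dp}:{sb}", f"{ad_n}:{t.dp}:0,0,0,0"
        else:
            fmt, tum, nor = "AD:DP", f"{ad_t}:{t.dp}", f"{ad_n}:{t.dp}"
    elif caller is CallerId.SOMATICSNIPER:
        fmt = "DP4:DP"
        tum = f"{t.t_ref_fwd},{t.t_ref_rev},{t.t_alt_fwd},{t.t_alt_rev}:{t.dp}"
        n_f, n_r = _split_even(t.n_alt)
        nr_f, nr_r = _split_even(t.n_ref)
        nor = f"{nr_f},{nr_r},{n_f},{n_r}:{t.dp}"
    elif caller is CallerId.STRELKA2:
        if len(ref) == len(alt):
            fmt, tum, nor = _strelka_snv_fmt(t, ref, alt)
        else:
            fmt = "TAR:TIR:DP"
            tum = f"{t.t_ref},{t.t_ref}:{t.t_alt},{t.t_alt}:{t.dp}"
            nor = f"{t.n_ref},{t.n_ref}:{t.n_alt},{t.n_alt}:{t.dp}"
    elif caller is CallerId.VARSCAN2:
        fmt = "RD:AD:DP4:DP"
        tum = (f"{t.t_ref}:{t.t_alt}:"
               f"{t.t_ref_fwd},{t.t_ref_rev},{t.t_alt_fwd},{t.t_alt_rev}:{t.dp}")
        n_f, n_r = _split_even(t.n_alt)
        nr_f, nr_r = _split_even(t.n_ref)
        nor = f"{t.n_ref}:{t.n_alt}:{nr_f},{nr_r},{n_f},{n_r}:{t.dp}"
    elif caller is CallerId.VARDICT:
        fmt = "AD:RD:ALD:DP"
        tum = (f"{t.t_ref},{t.t_alt}:{t.t_ref_fwd},{t.t_ref_rev}:"
               f"{t.t_alt_fwd},{t.t_alt_rev}:{t.dp}")
        n_f, n_r = _split_even(t.n_alt)
        nr_f, nr_r = _split_even(t.n_ref)
        nor = f"{t.n_ref},{t.n_alt}:{nr_f},{nr_r}:{n_f},{n_r}:{t.dp}"
    else:  # pragma: no cover
        raise ValueError(caller)
    cols = (nor, tum) if caller in _NORMAL_FIRST else (tum, nor)
    return "\t".join([
        t.chrom, str(t.pos), ".", ref, alts, ".", filt, info, fmt, *cols,
    ]) + "\n"


def _emission_lines(t: TruthRecord, caller: CallerId) -> list[tuple[int, str]]:
    """(pos, line) emissions of one truth record for one caller.

    Dinucleotide truths come out as one 2-bp MNV line from Mutect2 and
    VarDict, and as two adjacent SNV lines from the other callers.
    """
    alts = t.alt if t.extra_alt is None else f"{t.alt},{t.extra_alt}"
    if t.variant_class is VariantClass.MNV and caller not in MNV_AS_MNV:
        lines = []
        for i in range(2):
            sub = TruthRecord(**{**t.__dict__, "pos": t.pos + i,
                                 "ref": t.ref[i], "alt": t.alt[i],
                                 "variant_class": VariantClass.SNV})
            lines.append((t.pos + i,
                          _format_line(sub, caller, t.ref[i], t.alt[i],
                                       t.alt[i])))
        return lines
    return [(t.pos, _format_line(t, caller, t.ref, t.alt, alts))]


def _write_vcfs(truths: list[TruthRecord], samples, outdir: Path) -> None:
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(parents=True, exist_ok=True)
    chrom_order = {c: i for i, c in enumerate(CHROM_SIZES)}
    by_file: dict[tuple[str, CallerId], list] = {
        (s, c): [] for s in samples for c in CallerId
    }
    for t in truths:
        for c in t.callers:
            by_file[(t.sample, c)].extend(
                (chrom_order[t.chrom], pos, line)
                for pos, line in _emission_lines(t, c)
            )
    for (sid, caller), rows in by_file.items():
        cols = (f"{sid}_N", f"{sid}_T") if caller in _NORMAL_FIRST \
            else (f"{sid}_T", f"{sid}_N")
        header = (
            _VCF_COMMON + _DIALECT_HEADERS[caller]
            + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cols) + "\n"
        )
        rows.sort(key=lambda r: (r[0], r[1], r[2]))
        path = vcf_dir / f"{sid}.{caller.value}.vcf"
        with open(path, "w") as fh:
            fh.write(header)
            for _, _, line in rows:
                fh.write(line)


# ---------------------------------------------------------------------------
# Table emission


def truth_frame(truths: list[TruthRecord]) -> pd.DataFrame:
    rows = [{
        "sample": t.sample, "chrom": t.chrom, "pos": t.pos, "ref": t.ref,
        "alt": t.alt, "label": t.label, "gene": t.gene,
        "consequence": t.consequence, "in_target": int(t.in_target),
        "class": t.variant_class.value, "somatic_pass": int(t.somatic_pass),
        "callers": ",".join(c.value for c in t.callers),
        "extra_alt": t.extra_alt or "",
        "dp": t.dp, "maf": round(t.maf, 4), "t_alt": t.t_alt,
        "n_alt": t.n_alt,
    } for t in truths]
    df = pd.DataFrame(rows)
    return df.sort_values(["sample", "chrom", "pos"]).reset_index(drop=True)


def emit_pileups(truths: list[TruthRecord], path=None) -> pd.DataFrame:
    """Per-variant pileup-evidence table feeding the review classifier.

    True somatics satisfy all four review criteria with probability
    ~review_tp_rate (set at generation time); each artifact class
    violates its designated criterion — strand-bias artifacts carry no
    reverse-strand alt reads, repeat-locus FPs carry a dirty 40-bp
    window and kilobase-scale depth, leaks carry normal alt support,
    multiallelic artifacts carry a second alt allele.
    """
    rows = [{
        "sample": t.sample, "chrom": t.chrom, "pos": t.pos,
        "tumor_alt": t.t_alt, "normal_alt": t.n_alt,
        "tumor_alt_fwd": t.t_alt_fwd, "tumor_alt_rev": t.t_alt_rev,
        "mismatches_in_window": t.mismatches_in_window,
        "distinct_alt_alleles": t.distinct_alt_alleles,
        "dp": t.dp, "maf": round(t.maf, 4),
    } for t in truths]
    df = pd.DataFrame(rows).sort_values(["sample", "chrom", "pos"])
    df = df.drop_duplicates(["sample", "chrom", "pos"]).reset_index(drop=True)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def simulate_cohort(cfg: SimulationConfig, outdir) -> dict:
    """Generate the full cohort and write every pipeline input.

    Returns a manifest of output paths plus the in-memory truth frame.
    Same config (including seed) gives byte-identical output.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    truths, aux = _generate_truth(cfg, rng)

    target_bases = 0
    seen = []
    for chrom, start, end in sorted(aux["target"]):
        seen.append((chrom, start, end))
        target_bases += end - start
    target_mb = target_bases / 1e6

    _write_vcfs(truths, aux["samples"], outdir)
    (outdir / "target.bed").write_text(
        "".join(f"{c}\t{s}\t{e}\n" for c, s, e in seen)
    )
    aux["pop_af"].to_csv(outdir / "population_af.tsv", sep="\t", index=False)
    aux["normal_evidence"].to_csv(outdir / "normals_evidence.tsv",
                                  sep="\t", index=False)
    aux["gene_map"].to_csv(outdir / "gene_map.tsv", sep="\t", index=False)

    ann = pd.DataFrame([{
        "sample": t.sample, "chrom": t.chrom, "pos": t.pos, "ref": t.ref,
        "alt": t.alt, "gene": t.gene, "consequence": t.consequence,
    } for t in truths]).sort_values(["sample", "chrom", "pos"])
    ann = ann.drop_duplicates(["sample", "chrom", "pos"])
    ann.to_csv(outdir / "annotation.tsv", sep="\t", index=False)

    emit_pileups(truths, outdir / "pileup.tsv")
    clinical = _clinical_table(cfg, rng, truths, aux["samples"], target_mb)
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    tdf = truth_frame(truths)
    tdf.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    return {
        "outdir": outdir,
        "vcf_dir": outdir / "vcf",
        "target_bed": outdir / "target.bed",
        "population_af": outdir / "population_af.tsv",
        "normals_evidence": outdir / "normals_evidence.tsv",
        "gene_map": outdir / "gene_map.tsv",
        "annotation": outdir / "annotation.tsv",
        "pileup": outdir / "pileup.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.tsv",
        "samples": aux["samples"],
        "truth_frame": tdf,
        "target_mb": target_mb,
    }
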