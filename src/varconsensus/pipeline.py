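"""End-to-end orchestration: parse -> flag -> filter -> merge ->
consensus -> MNV fold -> review/blacklist -> TMB -> thresholds ->
clinical, with a per-stage funnel report whose counts reconcile.

Every stage is conservative: what goes in equals what is retained plus
what was removed, and the funnel report records both sides so the
whole filtering cascade can be audited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import thresholds as thr_mod
from .callers import (CallerId, CanonicalVariant, canonicalize,
                      canonical_variants_to_frame, is_somatic_pass,
                      parse_caller_vcf)
from .clinical import (CALCIUM_GENE_SET, NFKB_GENE_SET, association_test,
                       km_logrank, load_clinical_table, mann_whitney,
                       tmb_median_split, geneset_status)
from .consensus import (MergedVariant, TargetRegion, agreement_histogram,
                        consensus_filter, merge_callsets, reconstruct_mnvs,
                        restrict_to_target)
from .filters import (FilterConfig, annotate_flags, apply_filter_flags,
                      build_pon, flag_tally, load_population_af)
from .review import (PileupEvidence, ReviewConfig, apply_blacklist,
                     build_blacklist, gene_false_positive_rates,
                     review_variant, select_recurrent_genes)

__all__ = ["PipelineConfig", "FunnelReport", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration: inputs and every threshold."""

    vcf_dir: str
    target_bed: str
    annotation: str
    pileup: str
    clinical: str
    outdir: str
    normals_evidence: Optional[str] = None
    population_af: Optional[str] = None
    min_callers: int = 2
    review_min_patients: int = 7  # gene-recurrence bar for review
    report_min_patients: int = 4  # recurrence bar for the profile report
    blacklist_fp_rate_min: float = 0.9
    blacklist_min_total: int = 50
    filter: FilterConfig = field(default_factory=FilterConfig)
    review: ReviewConfig = field(default_factory=ReviewConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "filter" in raw:
            raw["filter"] = FilterConfig(**raw["filter"])
        if "review" in raw:
            raw["review"] = ReviewConfig(**raw["review"])
        return cls(**raw)


@dataclass
class FunnelReport:
    """Per-stage accounting of the filtering cascade."""

    parsed_per_caller: dict = field(default_factory=dict)
    somatic_pass_per_caller: dict = field(default_factory=dict)
    canonical_per_caller: dict = field(default_factory=dict)
    off_target_dropped: int = 0
    in_target_per_caller: dict = field(default_factory=dict)
    flag_counts: dict = field(default_factory=dict)  # caller -> flag -> n
    filter_pass_per_caller: dict = field(default_factory=dict)
    merged_sites: int = 0
    mnv_folded: int = 0
    agreement_tiers: dict = field(default_factory=dict)
    consensus_retained: int = 0
    blacklisted_genes: list = field(default_factory=list)
    blacklist_removed: int = 0
    final_retained: int = 0
    consequence_tallies: dict = field(default_factory=dict)

    def check_conservation(self) -> None:
        """Every stage's input must equal retained + removed."""
        for caller, n in self.canonical_per_caller.items():
            if self.in_target_per_caller.get(caller, 0) > n:
                raise AssertionError(f"target stage gained variants ({caller})")
        total_in = sum(self.in_target_per_caller.values())
        total_pass = sum(self.filter_pass_per_caller.values())
        total_flagged = sum(
            v.get("flagged_variants", 0) for v in self.flag_counts.values()
        )
        if total_pass + total_flagged != total_in:
            raise AssertionError(
                f"flag partition not conserved: {total_pass} + "
                f"{total_flagged} != {total_in}"
            )
        if sum(self.agreement_tiers.values()) != self.merged_sites:
            raise AssertionError("agreement tiers do not sum to merged sites")
        if self.final_retained + self.blacklist_removed != self.consensus_retained:
            raise AssertionError("blacklist stage not conserved")
        if self.consequence_tallies and \
                sum(self.consequence_tallies.values()) != self.final_retained:
            raise AssertionError("consequence tallies do not sum to retained")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    funnel: FunnelReport
    consensus: list
    final: list
    genes: dict  # merged-variant key -> gene
    tmb_table: pd.DataFrame
    summary: dict
    clinical: dict
    roc: dict
    outputs: dict
    recurrent_genes: list = field(default_factory=list)


def _load_annotation(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (r.sample, r.chrom, int(r.pos)): (str(r.gene) if pd.notna(r.gene) else "",
                                          str(r.consequence))
        for r in df.itertuples(index=False)
    }


def _load_pileup(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = {}
    for r in df.itertuples(index=False):
        out[(r.sample, r.chrom, int(r.pos))] = {
            "evidence": PileupEvidence(
                tumor_alt=int(r.tumor_alt), normal_alt=int(r.normal_alt),
                tumor_alt_fwd=int(r.tumor_alt_fwd),
                tumor_alt_rev=int(r.tumor_alt_rev),
                mismatches_in_window=int(r.mismatches_in_window),
                distinct_alt_alleles=int(r.distinct_alt_alleles),
            ),
            "dp": float(r.dp), "maf": float(r.maf),
        }
    return out


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str)
                    + "\n")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full consensus pipeline; deterministic given inputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    funnel = FunnelReport()
    region = TargetRegion.from_bed(config.target_bed)

    # stage 1: parse + caller somatic verdict + canonicalize + target
    vcf_dir = Path(config.vcf_dir)
    per_caller: dict[CallerId, list[CanonicalVariant]] = {c: [] for c in CallerId}
    for path in sorted(vcf_dir.glob("*.vcf")):
        sid, caller_name = path.stem.rsplit(".", 1)
        caller = CallerId(caller_name)
        records = parse_caller_vcf(path, caller, sample_id=sid)
        funnel.parsed_per_caller[caller.value] = (
            funnel.parsed_per_caller.get(caller.value, 0) + len(records)
        )
        passed = [r for r in records if is_somatic_pass(r)]
        funnel.somatic_pass_per_caller[caller.value] = (
            funnel.somatic_pass_per_caller.get(caller.value, 0) + len(passed)
        )
        for rec in passed:
            per_caller[caller].extend(canonicalize(rec))
    for c in CallerId:
        funnel.canonical_per_caller[c.value] = len(per_caller[c])
        kept, dropped = restrict_to_target(per_caller[c], region)
        per_caller[c] = kept
        funnel.off_target_dropped += dropped
        funnel.in_target_per_caller[c.value] = len(kept)

    # stage 2: filter flags
    pon = build_pon(
        pd.read_csv(config.normals_evidence, sep="\t", dtype={"chrom": str}),
        config.filter,
    ) if config.normals_evidence else None
    pop_af = (load_population_af(config.population_af)
              if config.population_af else None)
    all_variants = [v for c in CallerId for v in per_caller[c]]
    annotations = annotate_flags(all_variants, pon, pop_af, config.filter)
    tally = flag_tally(annotations)
    for caller_name, row in tally.iterrows():
        d = {k: int(v) for k, v in row.items()}
        d["flagged_variants"] = d["Total"] - d["PASS"]
        funnel.flag_counts[caller_name] = d
    pass_per_caller: dict[CallerId, list[CanonicalVariant]] = {}
    for c in CallerId:
        pass_set, _ = apply_filter_flags(per_caller[c], annotations)
        pass_per_caller[c] = pass_set
        funnel.filter_pass_per_caller[c.value] = len(pass_set)

    # stage 3: merge, MNV reconstruction, consensus
    merged = merge_callsets(pass_per_caller)
    n_before = len(merged)
    merged, mnv_conflicts = reconstruct_mnvs(merged)
    funnel.mnv_folded = n_before - len(merged)
    funnel.merged_sites = len(merged)
    funnel.agreement_tiers = {
        str(k): v for k, v in agreement_histogram(merged).items()
    }
    consensus = consensus_filter(merged, config.min_callers)
    funnel.consensus_retained = len(consensus)

    # stage 4: annotation join, recurrence-driven review, blacklist
    ann = _load_annotation(config.annotation)
    genes = {}
    consequences = {}
    for m in consensus:
        gene, cons = ann.get(m.key, ("", ""))
        genes[m.key] = gene
        consequences[m.key] = cons
    sample_ids = sorted({m.sample_id for m in merged})
    n_patients = len(sample_ids)
    sample_genes_all = {s: set() for s in sample_ids}
    for m in consensus:
        if genes[m.key]:
            sample_genes_all[m.sample_id].add(genes[m.key])
    review_bar = min(config.review_min_patients, n_patients)
    top_genes = select_recurrent_genes(sample_genes_all, review_bar, n_patients)
    pileup = _load_pileup(config.pileup)
    reviewed: dict[str, list] = {}
    review_rows = []
    roc_labels, roc_dp, roc_maf = [], [], []
    top_gene_set = {g for g, _ in top_genes}
    for m in consensus:
        g = genes[m.key]
        if g not in top_gene_set or m.key not in pileup:
            continue
        entry = pileup[m.key]
        res = review_variant(entry["evidence"], config.review)
        reviewed.setdefault(g, []).append(res)
        review_rows.append({
            "sample": m.sample_id, "chrom": m.chrom, "pos": m.pos,
            "gene": g, "passed": int(res.passed),
            "failed_criteria": ";".join(sorted(c.value
                                               for c in res.failed_criteria)),
        })
        roc_labels.append(res.passed)
        roc_dp.append(entry["dp"])
        roc_maf.append(entry["maf"])
    rates = gene_false_positive_rates(reviewed)
    blacklist = build_blacklist(rates, config.blacklist_fp_rate_min,
                                config.blacklist_min_total)
    final, removed = apply_blacklist(
        consensus, {m.key: genes[m.key] for m in consensus}, blacklist
    )
    funnel.blacklisted_genes = sorted(blacklist)
    funnel.blacklist_removed = len(removed)
    funnel.final_retained = len(final)

    # stage 5: consequence classes and TMB
    class_tallies: dict[burden_mod.ConsequenceClass, int] = {}
    per_sample_counts = {s: 0 for s in sample_ids}
    per_sample_nonsyn = {s: 0 for s in sample_ids}
    sample_genes_nonsyn = {s: set() for s in sample_ids}
    for m in final:
        term = consequences[m.key] or "missense_variant"
        cclass = burden_mod.classify_consequence(term)
        class_tallies[cclass] = class_tallies.get(cclass, 0) + 1
        per_sample_counts[m.sample_id] += 1
        if burden_mod.is_nonsynonymous(cclass):
            per_sample_nonsyn[m.sample_id] += 1
            if genes[m.key]:
                sample_genes_nonsyn[m.sample_id].add(genes[m.key])
    # post-blacklist recurrence profile (broader bar than the review set)
    sample_genes_final = {s: set() for s in sample_ids}
    for m in final:
        if genes[m.key]:
            sample_genes_final[m.sample_id].add(genes[m.key])
    recurrent_final = select_recurrent_genes(
        sample_genes_final, min(config.report_min_patients, n_patients),
        n_patients)

    target_mb = burden_mod.target_size_mb(region)
    tmb_rows = []
    for s in sample_ids:
        r_all = burden_mod.compute_tmb(per_sample_counts[s], target_mb, s)
        r_nonsyn = burden_mod.compute_tmb(per_sample_nonsyn[s], target_mb, s)
        tmb_rows.append({
            "sample": s, "mutations": per_sample_counts[s],
            "nonsyn_count": per_sample_nonsyn[s],
            "target_mb": round(target_mb, 4),
            "tmb_all": round(r_all.tmb, 4),
            "tmb": round(r_nonsyn.tmb, 4),
        })
    tmb_table = pd.DataFrame(tmb_rows)
    summary = burden_mod.cohort_summary(
        per_sample_counts,
        {s: per_sample_nonsyn[s] / target_mb for s in sample_ids},
        class_tallies,
    )
    funnel.consequence_tallies = {k.value: v for k, v in
                                  sorted(class_tallies.items())}

    # stage 6: DP/MAF ROC against review outcome
    roc_out = {}
    labels = np.array(roc_labels, dtype=bool)
    if labels.size and labels.any() and not labels.all():
        for name, scores in (("dp", roc_dp), ("maf", roc_maf)):
            curve = thr_mod.roc_curve(labels, np.array(scores))
            thr, tpr, fpr = thr_mod.optimal_threshold(curve)
            fpr_t, fnr_t = thr_mod.rates_at_threshold(labels,
                                                      np.array(scores), thr)
            roc_out[name] = {
                "auc": round(curve.auc, 4),
                "auc_ci": [round(x, 4) for x in curve.auc_ci],
                "optimal_threshold": thr,
                "tpr": round(tpr, 4), "fpr": round(fpr, 4),
                "fpr_at_threshold": round(fpr_t, 4),
                "fnr_at_threshold": round(fnr_t, 4),
            }
            curve.to_frame().to_csv(outdir / f"roc_{name}.tsv",
                                    sep="\t", index=False)

    # stage 7: clinical associations and survival
    clin_records = load_clinical_table(config.clinical)
    clin = {r.sample_id: r for r in clin_records}
    tmb_by_sample = {r["sample"]: r["tmb"] for r in tmb_rows
                     if r["sample"] in clin}
    clinical_out: dict = {}
    if len(tmb_by_sample) >= 2:
        groups, cut = tmb_median_split(tmb_by_sample)
        clinical_out["tmb_median_cutpoint"] = round(cut, 4)
        ordered = sorted(tmb_by_sample)
        times = [clin[s].os_time for s in ordered]
        events = [clin[s].os_event for s in ordered]
        gvec = [groups[s] for s in ordered]
        if any(events) and len(set(gvec)) == 2:
            km = km_logrank(times, events, gvec)
            clinical_out["tmb_survival"] = {
                "chi2": round(km["chi2"], 4), "p": round(km["p"], 6),
                "n_low": km["n"][0], "n_high": km["n"][1],
            }
        # burden vs covariates (Mann-Whitney on TMB between groups)
        def mw(split_fn, name):
            a = [tmb_by_sample[s] for s in ordered if split_fn(clin[s])]
            b = [tmb_by_sample[s] for s in ordered if not split_fn(clin[s])]
            if a and b:
                u, p = mann_whitney(a, b)
                clinical_out[name] = {"U": u, "p": round(p, 6),
                                      "n": [len(a), len(b)]}
        mw(lambda r: r.age > 60, "tmb_vs_age_gt60")
        mw(lambda r: r.clinical_stage == "IV", "tmb_vs_stage_iv")
        mw(lambda r: r.t_stage == "T4", "tmb_vs_t4")
        # stage vs TMB group contingency
        table = [[0, 0], [0, 0]]
        for s in ordered:
            table[groups[s]][int(clin[s].clinical_stage == "IV")] += 1
        try:
            clinical_out["stage_vs_tmb_group"] = association_test(table)
        except ValueError:
            pass
        # pathway gene-set survival
        for gs in (NFKB_GENE_SET, CALCIUM_GENE_SET):
            status = geneset_status(
                {s: sample_genes_nonsyn[s] for s in ordered}, gs)
            svec = [status[s] for s in ordered]
            clinical_out[f"{gs.name}_mutated_n"] = int(sum(svec))
            if any(events) and 0 < sum(svec) < len(svec):
                km = km_logrank(times, events, svec)
                clinical_out[f"{gs.name}_survival"] = {
                    "chi2": round(km["chi2"], 4), "p": round(km["p"], 6),
                }

    funnel.check_conservation()

    # write outputs
    outputs = {}

    def emit(name, df_or_text):
        path = outdir / name
        if isinstance(df_or_text, pd.DataFrame):
            df_or_text.to_csv(path, sep="\t", index=False)
        else:
            path.write_text(df_or_text)
        outputs[name] = path

    merged_rows = pd.DataFrame([{
        "sample": m.sample_id, "chrom": m.chrom, "pos": m.pos,
        "ref": m.ref, "alt": m.alt, "class": m.variant_class.value,
        "n_callers": m.n_callers,
        "callers": ",".join(sorted(c.value for c in m.caller_hits)),
        "gene": genes.get(m.key, ""),
        "alt_discordant": int(m.alt_discordant),
        "class_discordant": int(m.class_discordant),
    } for m in final])
    emit("consensus.tsv", merged_rows)
    emit("flag_tally.tsv", tally.reset_index())
    emit("agreement_histogram.tsv", pd.DataFrame(
        [{"n_callers": k, "count": v}
         for k, v in sorted(funnel.agreement_tiers.items())]))
    emit("review_report.tsv", pd.DataFrame(
        review_rows, columns=["sample", "chrom", "pos", "gene", "passed",
                              "failed_criteria"]))
    emit("gene_fp_rates.tsv", rates)
    emit("recurrent_genes.tsv", pd.DataFrame(
        recurrent_final, columns=["gene", "n_patients"]))
    emit("blacklist.txt", "".join(g + "\n" for g in sorted(blacklist)))
    emit("tmb.tsv", tmb_table)
    _json_dump(summary, outdir / "summary.json")
    _json_dump(clinical_out, outdir / "clinical.json")
    _json_dump(roc_out, outdir / "roc.json")
    (outdir / "funnel.json").write_text(funnel.to_json() + "\n")
    outputs.update({n: outdir / f"{n}.json"
                    for n in ("summary", "clinical", "roc", "funnel")})
    if mnv_conflicts:
        emit("mnv_conflicts.log", "".join(c + "\n" for c in mnv_conflicts))
    manifest = {k: v.name for k, v in sorted(outputs.items())}
    _json_dump(manifest, outdir / "manifest.json")

    return PipelineResult(
        funnel=funnel, consensus=consensus, final=final, genes=genes,
        tmb_table=tmb_table, summary=summary, clinical=clinical_out,
        roc=roc_out, outputs=outputs, recurrent_genes=recurrent_final,
    )
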