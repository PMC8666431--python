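"""Merging, >=k-caller consensus, target restriction, MNV folding."""

from collections import defaultdict

import numpy as np
import pytest

from varconsensus.callers import CallerId, CanonicalVariant, VariantClass
from varconsensus.consensus import (TargetRegion, agreement_histogram,
                                    consensus_filter, merge_callsets,
                                    reconstruct_mnvs, restrict_to_target)


def cv(sample="S1", chrom="chr1", pos=100, ref="A", alt="T",
       vclass=VariantClass.SNV, caller=CallerId.MUTECT2, **kw):
    return CanonicalVariant(sample_id=sample, chrom=chrom, pos=pos, ref=ref,
                            alt=alt, variant_class=vclass, caller=caller,
                            t_alt=10, t_ref=30, **kw)


class TestTargetRegion:
    def test_one_based_boundary_conversion(self):
        region = TargetRegion.from_intervals([("chr1", 99, 100)])
        kept, dropped = restrict_to_target(
            [cv(pos=100), cv(pos=101)], region)
        assert [v.pos for v in kept] == [100] and dropped == 1

    def test_absent_chromosome_dropped_and_counted(self):
        region = TargetRegion.from_intervals([("chr1", 0, 1000)])
        kept, dropped = restrict_to_target([cv(chrom="chrX")], region)
        assert kept == [] and dropped == 1

    def test_overlapping_intervals_merged(self):
        region = TargetRegion.from_intervals([("chr1", 0, 100),
                                              ("chr1", 50, 150)])
        assert region.total_bases == 150
        assert region.total_size_mb == pytest.approx(0.00015)

    def test_simulator_in_out_labels(self, cohort):
        """Exactly the truth-inside variants survive restriction."""
        manifest = cohort["manifest"]
        region = TargetRegion.from_bed(manifest["target_bed"])
        truth = manifest["truth_frame"]
        for row in truth.sample(n=200, random_state=0).to_dict("records"):
            assert region.contains(row["chrom"], row["pos"]) == bool(
                row["in_target"])

    def test_empty_bed_rejected(self, tmp_path):
        bed = tmp_path / "empty.bed"
        bed.write_text("")
        with pytest.raises(ValueError):
            TargetRegion.from_bed(bed)


class TestMerge:
    def test_six_callers_one_site(self):
        sets = {c: [cv(caller=c)] for c in CallerId}
        merged = merge_callsets(sets)
        assert len(merged) == 1 and merged[0].n_callers == 6

    def test_disjoint_sites_stay_separate(self):
        sets = {CallerId.MUSE: [cv(pos=10, caller=CallerId.MUSE)],
                CallerId.VARDICT: [cv(pos=20, caller=CallerId.VARDICT)]}
        merged = merge_callsets(sets)
        assert len(merged) == 2
        assert all(m.n_callers == 1 for m in merged)

    def test_alt_discordance_annotated_with_priority_representative(self):
        sets = {CallerId.MUTECT2: [cv(alt="T")],
                CallerId.VARSCAN2: [cv(alt="G", caller=CallerId.VARSCAN2)]}
        m, = merge_callsets(sets)
        assert m.alt_discordant and m.alt == "T"  # Mutect2 outranks VarScan2

    def test_matches_naive_grouping_oracle(self):
        rng = np.random.default_rng(17)
        sets = {c: [] for c in CallerId}
        callers = list(CallerId)
        for _ in range(500):
            c = callers[int(rng.integers(6))]
            sets[c].append(cv(sample=f"S{rng.integers(3)}",
                              chrom=f"chr{1 + rng.integers(2)}",
                              pos=int(rng.integers(1, 60)), caller=c))
        merged = merge_callsets(sets)
        # brute-force O(N^2)-style grouping oracle
        oracle = defaultdict(set)
        for c, vs in sets.items():
            for v in vs:
                oracle[(v.sample_id, v.chrom, v.pos)].add(c)
        assert len(merged) == len(oracle)
        for m in merged:
            assert m.caller_hits == oracle[m.key]


class TestConsensusFilter:
    def test_min_one_is_identity(self):
        merged = merge_callsets({c: [cv(pos=p, caller=c)]
                                 for p, c in zip((10, 20), CallerId)})
        assert consensus_filter(merged, 1) == merged

    def test_singletons_removed_at_two(self):
        merged = merge_callsets({CallerId.MUSE: [cv(caller=CallerId.MUSE)]})
        assert consensus_filter(merged, 2) == []

    def test_monotone_in_min_callers(self):
        rng = np.random.default_rng(23)
        sets = {c: [cv(pos=int(p), caller=c)
                    for p in rng.integers(1, 40, size=30)]
                for c in CallerId}
        merged = merge_callsets(sets)
        previous = None
        for k in range(1, 7):
            keys = {m.key for m in consensus_filter(merged, k)}
            if previous is not None:
                assert keys <= previous
            previous = keys

    def test_invalid_min_callers(self):
        with pytest.raises(ValueError):
            consensus_filter([], 0)


class TestMnvReconstruction:
    def build(self, with_mnv_caller=True, conflict=False):
        sets = {
            CallerId.MUSE: [
                cv(pos=10, ref="C", alt="T", caller=CallerId.MUSE),
                cv(pos=11, ref="A", alt="G" if conflict else "T",
                   caller=CallerId.MUSE),
            ],
        }
        if with_mnv_caller:
            sets[CallerId.MUTECT2] = [
                cv(pos=10, ref="CA", alt="TT", vclass=VariantClass.MNV)
            ]
        return merge_callsets(sets)

    def test_fold_adjacent_snvs_into_mnv(self):
        merged, conflicts = reconstruct_mnvs(self.build())
        assert conflicts == []
        assert len(merged) == 1
        m = merged[0]
        assert m.variant_class is VariantClass.MNV
        assert (m.ref, m.alt) == ("CA", "TT")
        assert m.caller_hits >= {CallerId.MUTECT2, CallerId.MUSE}

    def test_no_mnv_capable_caller_leaves_snvs(self):
        merged, _ = reconstruct_mnvs(self.build(with_mnv_caller=False))
        assert len(merged) == 2
        assert all(m.variant_class is VariantClass.SNV for m in merged)

    def test_conflicting_alt_left_unfolded_and_logged(self):
        merged, conflicts = reconstruct_mnvs(self.build(conflict=True))
        assert len(conflicts) == 1 and "left unfolded" in conflicts[0]
        # the second-position SNV record survives with its own caller
        assert any(m.pos == 11 and CallerId.MUSE in m.caller_hits
                   for m in merged)

    def test_positions_covered_preserved(self):
        before = self.build()
        covered_before = {(m.sample_id, m.chrom, p)
                          for m in before for p in m.positions_covered}
        after, _ = reconstruct_mnvs(before)
        covered_after = {(m.sample_id, m.chrom, p)
                        for m in after for p in m.positions_covered}
        assert covered_before == covered_after


def test_agreement_histogram_totals():
    sets = {c: [cv(pos=10, caller=c)] for c in CallerId}
    sets[CallerId.MUSE].append(cv(pos=99, caller=CallerId.MUSE))
    merged = merge_callsets(sets)
    hist = agreement_histogram(merged)
    assert hist[6] == 1 and hist[1] == 1 and sum(hist.values()) == len(merged)
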