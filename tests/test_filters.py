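"""Filter-flag engine: panel of normals, per-flag annotation, partition."""

import itertools

import numpy as np
import pytest
from scipy.stats import fisher_exact

from varconsensus.callers import CallerId, CanonicalVariant, VariantClass
from varconsensus.filters import (FilterConfig, FilterFlag, PanelOfNormals,
                                  annotate_flags, apply_filter_flags,
                                  build_pon, flag_tally)


def make_variant(pos=100, **kw):
    base = dict(
        sample_id="S1", chrom="chr1", pos=pos, ref="A", alt="T",
        variant_class=VariantClass.SNV, caller=CallerId.MUTECT2,
        dp=100, maf=0.25, t_alt=25, t_ref=75, n_alt=0, n_ref=100,
        t_alt_fwd=13, t_alt_rev=12, t_ref_fwd=38, t_ref_rev=37,
    )
    base.update(kw)
    return CanonicalVariant(**base)


class TestPanelOfNormals:
    def test_site_rule(self):
        cfg = FilterConfig(pon_min_normals=2, pon_min_alt_reads=2)
        ev = [("N1", "chr1", 10, "T", 3), ("N2", "chr1", 10, "T", 3),
              ("N1", "chr1", 20, "C", 5)]
        pon = build_pon(ev, cfg)
        assert ("chr1", 10, "T") in pon          # 2 normals with >=2 reads
        assert ("chr1", 20, "C") not in pon      # only one normal

    def test_reads_threshold_per_normal(self):
        cfg = FilterConfig(pon_min_normals=2, pon_min_alt_reads=4)
        ev = [("N1", "chr1", 10, "T", 3), ("N2", "chr1", 10, "T", 9),
              ("N3", "chr1", 10, "T", 4)]
        pon = build_pon(ev, cfg)
        assert ("chr1", 10, "T") in pon  # N2 and N3 qualify, N1 does not

    def test_empty_evidence_gives_empty_panel(self):
        assert len(build_pon([], FilterConfig())) == 0

    def test_completeness_against_brute_force(self):
        """Every site constructible from the rule is in the panel."""
        rng = np.random.default_rng(42)
        cfg = FilterConfig(pon_min_normals=3, pon_min_alt_reads=2)
        ev = [(f"N{rng.integers(8)}", "chr1", int(rng.integers(5)), "T",
               int(rng.integers(0, 5))) for _ in range(300)]
        pon = build_pon(ev, cfg)
        # brute-force oracle over all (site, normal) evidence
        for pos in range(5):
            site = ("chr1", pos, "T")
            qualifying = {s for s, _, p, _, reads in ev
                          if p == pos and reads >= 2}
            expected = len(qualifying) >= 3
            assert (site in pon) == expected


class TestFlags:
    def test_common_snp_threshold_strictly_greater(self):
        v_common = make_variant(pos=10)
        v_at_bound = make_variant(pos=20)
        pop = {("chr1", 10, "T"): 0.02, ("chr1", 20, "T"): 0.01}
        flags = annotate_flags([v_common, v_at_bound], pop_af=pop)
        assert FilterFlag.COMMON_SNP in flags[v_common].flags
        assert FilterFlag.COMMON_SNP not in flags[v_at_bound].flags

    def test_alt_count_evidence_flags(self):
        low_t = make_variant(pos=10, t_alt=3)
        high_n = make_variant(pos=20, n_alt=4)
        flags = annotate_flags([low_t, high_n])
        assert FilterFlag.T_ALT_LOW in flags[low_t].flags
        assert FilterFlag.N_ALT_HIGH in flags[high_n].flags
        assert FilterFlag.T_ALT_LOW not in flags[high_n].flags

    def test_pon_membership_flag(self):
        v = make_variant(pos=10)
        pon = PanelOfNormals(sites={("chr1", 10, "T"): 5})
        flags = annotate_flags([v], pon=pon)
        assert FilterFlag.PON in flags[v].flags

    def test_multiallelic_source_flag(self):
        v = make_variant(multiallelic_source=True)
        assert FilterFlag.MULTIALLELIC in annotate_flags([v])[v].flags

    def test_clustered_events_window(self):
        vs = [make_variant(pos=p) for p in (100, 120, 140)]
        lone = make_variant(pos=5000)
        flags = annotate_flags(vs + [lone],
                               config=FilterConfig(cluster_window_bp=50,
                                                   cluster_min_events=3))
        for v in vs:
            assert FilterFlag.CLUSTERED in flags[v].flags
        assert FilterFlag.CLUSTERED not in flags[lone].flags

    def test_clustered_against_sliding_window_oracle(self):
        rng = np.random.default_rng(7)
        cfg = FilterConfig(cluster_window_bp=50, cluster_min_events=3)
        positions = sorted(set(int(p) for p in rng.integers(1, 400, size=40)))
        vs = [make_variant(pos=p) for p in positions]
        flags = annotate_flags(vs, config=cfg)
        for v in vs:
            # oracle: any window [a, a+50] containing v and >=3 events
            expected = any(
                sum(1 for q in positions if a <= q <= a + 50) >= 3
                for a in positions if a <= v.pos <= a + 50
            )
            assert (FilterFlag.CLUSTERED in flags[v].flags) == expected

    def test_oxog_orientation_skew(self):
        skewed = make_variant(pos=10, ref="C", alt="A",
                              t_alt=20, t_alt_fwd=19, t_alt_rev=1)
        balanced = make_variant(pos=2000, ref="C", alt="A",
                                t_alt=20, t_alt_fwd=10, t_alt_rev=10)
        not_oxog_pair = make_variant(pos=4000, ref="A", alt="T",
                                     t_alt=20, t_alt_fwd=19, t_alt_rev=1)
        flags = annotate_flags([skewed, balanced, not_oxog_pair])
        assert FilterFlag.OXOG in flags[skewed].flags
        assert FilterFlag.OXOG not in flags[balanced].flags
        assert FilterFlag.OXOG not in flags[not_oxog_pair].flags

    def test_missing_strand_counts_not_evaluable(self):
        v = make_variant(ref="C", alt="A", t_alt_fwd=None, t_alt_rev=None,
                         t_ref_fwd=None, t_ref_rev=None)
        ann = annotate_flags([v])[v]
        assert FilterFlag.OXOG in ann.not_evaluable
        assert FilterFlag.STRAND_BIAS in ann.not_evaluable
        assert FilterFlag.OXOG not in ann.flags

    def test_strand_bias_matches_exact_test(self):
        biased = make_variant(pos=10, t_alt=15, t_alt_fwd=15, t_alt_rev=0,
                              t_ref_fwd=40, t_ref_rev=45)
        _, p = fisher_exact([[40, 45], [15, 0]])
        assert p < 0.005
        flags = annotate_flags([biased])
        assert FilterFlag.STRAND_BIAS in flags[biased].flags

    def test_annotation_order_independent(self):
        rng = np.random.default_rng(3)
        vs = [make_variant(pos=int(p), t_alt=int(rng.integers(1, 30)))
              for p in rng.integers(1, 1000, size=25)]
        vs = list({v.pos: v for v in vs}.values())
        a = annotate_flags(vs)
        b = annotate_flags(vs[::-1])
        assert all(a[v].flags == b[v].flags for v in vs)

    def test_stricter_thresholds_shrink_pass_set(self):
        rng = np.random.default_rng(5)
        vs = list({int(p): make_variant(pos=int(p),
                                        t_alt=int(rng.integers(1, 10)))
                   for p in rng.integers(1, 10_000, size=60)}.values())
        loose = annotate_flags(vs, config=FilterConfig(t_alt_min=2))
        strict = annotate_flags(vs, config=FilterConfig(t_alt_min=6))
        pass_loose, _ = apply_filter_flags(vs, loose)
        pass_strict, _ = apply_filter_flags(vs, strict)
        assert set(v.pos for v in pass_strict) <= set(v.pos for v in pass_loose)


class TestPartition:
    def test_unflagged_pass_through(self):
        vs = [make_variant(pos=p) for p in (10, 2000)]
        flags = annotate_flags(vs)
        pass_set, flagged = apply_filter_flags(vs, flags)
        assert pass_set == vs and flagged == []

    def test_partition_exhaustive_disjoint_with_reasons(self):
        v = make_variant(t_alt=2, n_alt=6)
        flags = annotate_flags([v])
        pass_set, flagged = apply_filter_flags([v], flags)
        assert pass_set == [] and flagged == [v]
        assert flags[v].flags >= {FilterFlag.T_ALT_LOW, FilterFlag.N_ALT_HIGH}

    def test_flag_tally_accounting(self):
        vs = [make_variant(pos=10, t_alt=2), make_variant(pos=2000)]
        tally = flag_tally(annotate_flags(vs))
        row = tally.loc["Mutect2"]
        assert row["Total"] == 2 and row["PASS"] == 1
        assert row["TAltLow"] == 1


def test_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(common_af_max=0.0)
    with pytest.raises(ValueError):
        FilterConfig(t_alt_min=0)
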