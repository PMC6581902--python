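import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelforge.genome import Region, SampleSiteRecord
from panelforge.joint_panel import (
    FilterConfigError,
    PloidyConflictError,
    VariantSite,
    annotate_sites,
    apply_hard_filters,
    compute_frequencies,
    compute_site_annotations,
    fisher_exact_two_sided,
    joint_genotype_region,
    mean_depth_track,
    per_sample_tstv,
    reconcile_overlaps,
    run_chunked,
    tstv,
)

from .oracles import fisher_two_sided_exact


def _rec(sample, pos, ref, alts, gt, pl=None, dp=None, ad=None, sac=None,
         contig="1", ploidy=None):
    return SampleSiteRecord(
        sample=sample, contig=contig, pos=pos, ref=ref, alts=tuple(alts),
        genotype=tuple(gt) if gt is not None else None,
        ploidy=ploidy if ploidy is not None else (len(gt) if gt else 2),
        likelihoods=tuple(pl) if pl else None, depth=dp,
        allele_depths=tuple(ad) if ad else None,
        strand_counts=tuple(sac) if sac else None,
    )


REGION = Region("1", 1, 10_000)


class TestJointGenotypeRegion:
    def test_shared_biallelic_site_keeps_genotypes(self):
        records = {
            "A": [_rec("A", 100, "A", ["G"], (0, 1), pl=[30, 0, 50])],
            "B": [_rec("B", 100, "A", ["G"], (1, 1), pl=[60, 20, 0])],
        }
        (site,) = joint_genotype_region(records, REGION)
        assert site.alts == ("G",)
        assert site.genotypes == {"A": (0, 1), "B": (1, 1)}

    def test_distinct_alts_merge_with_reindexing(self):
        """Two samples present different alts; merged order follows pooled AD
        and each genotype is re-expressed in the merged indexing (checked by
        manual reindexing)."""
        records = {
            "A": [_rec("A", 100, "A", ["T"], (0, 1), pl=[30, 0, 50], ad=[5, 5])],
            "B": [_rec("B", 100, "A", ["C"], (1, 1), pl=[70, 30, 0], ad=[0, 20])],
        }
        (site,) = joint_genotype_region(records, REGION)
        # pooled AD: C=20 > T=5, so merged alts are (C, T)
        assert site.alts == ("C", "T")
        assert site.genotypes["A"] == (0, 2)  # A's T is merged allele 2
        assert site.genotypes["B"] == (1, 1)  # B's C is merged allele 1

    def test_all_hom_ref_position_is_absent(self):
        records = {
            "A": [_rec("A", 100, "A", ["G"], (0, 0), pl=[0, 40, 80])],
            "B": [_rec("B", 100, "A", ["G"], (0, 0), pl=[0, 35, 70])],
        }
        assert joint_genotype_region(records, REGION) == []

    def test_missing_record_becomes_no_call(self):
        records = {
            "A": [_rec("A", 100, "A", ["G"], (1, 1), pl=[80, 40, 0])],
            "B": [],
        }
        (site,) = joint_genotype_region(records, REGION)
        assert site.genotypes["B"] is None

    def test_pl_argmax_overrides_stated_gt_with_low_tie_break(self):
        # stated GT het, but PL has a tie between hom-ref and het: lower
        # genotype index (hom-ref) wins, so no variant is presented
        records = {"A": [_rec("A", 100, "A", ["G"], (0, 1), pl=[0, 0, 50])]}
        assert joint_genotype_region(records, REGION) == []

    def test_ploidy_conflict_is_detected(self):
        records = {"A": [_rec("A", 100, "A", ["G"], (0, 1), pl=[30, 0, 50])]}
        with pytest.raises(PloidyConflictError, match="A at 1:100"):
            joint_genotype_region(records, REGION, lambda s, c, p: 1)


class TestReconcileOverlaps:
    def _site(self, pos, alt="G", gt=(0, 1)):
        return VariantSite(contig="1", pos=pos, ref="A", alts=(alt,),
                           genotypes={"A": gt})

    def test_identical_calls_kept_once(self):
        ov = Region("1", 90, 110)
        kept, report = reconcile_overlaps([self._site(100)], [self._site(100)], ov)
        assert [s.pos for s in kept] == [100]
        assert report.count == 0

    def test_conflicting_alts_removed_and_reported(self):
        ov = Region("1", 90, 110)
        kept, report = reconcile_overlaps(
            [self._site(100, alt="T")], [self._site(100, alt="C")], ov
        )
        assert kept == []
        assert report.count == 1
        assert report.removed[0].pos == 100

    def test_single_chunk_only_call_treated_as_discordant(self):
        ov = Region("1", 90, 110)
        kept, report = reconcile_overlaps([self._site(100)], [], ov)
        assert kept == [] and report.count == 1
        assert report.removed[0].summary_b == "absent"

    def test_outside_overlap_passes_through(self):
        ov = Region("1", 90, 110)
        kept, report = reconcile_overlaps(
            [self._site(50), self._site(100)], [self._site(100), self._site(200)], ov
        )
        assert [s.pos for s in kept] == [50, 100, 200]
        assert report.count == 0


@pytest.fixture(scope="module")
def chunked_cohort():
    from panelforge.synthetic import CohortSpec, observe, simulate_truth

    spec = CohortSpec(n_samples=30, contig_plan=(("autosome", 2_000_000),),
                      n_sites=800, genotype_error=0.005, seed=55)
    truth = simulate_truth(spec)
    return truth, observe(truth)


class TestRunChunked:
    def test_single_chunk_equals_plain_call(self, chunked_cohort):
        truth, records = chunked_cohort
        contig = truth.contigs[0]
        single = joint_genotype_region(records, Region("1", 1, contig.length))
        merged, report = run_chunked(records, contig, contig.length + 1, 10)
        assert report.count == 0
        assert [s.signature() for s in merged] == [s.signature() for s in single]

    def test_chunked_equals_single_pass(self, chunked_cohort):
        """A deterministic caller must make chunking invisible."""
        truth, records = chunked_cohort
        contig = truth.contigs[0]
        single = joint_genotype_region(records, Region("1", 1, contig.length))
        merged, report = run_chunked(records, contig, 500_000, 1_000)
        assert report.count == 0
        assert len(merged) == len(single)
        for a, b in zip(merged, single):
            assert a.pos == b.pos and a.signature() == b.signature()

    def test_injected_perturbation_is_removed_and_reported(self, chunked_cohort):
        truth, records = chunked_cohort
        contig = truth.contigs[0]
        plain = joint_genotype_region(records, Region("1", 1, contig.length))
        # choose a variant inside the first overlap zone [500_000-999, 500_000]
        ov_pos = [s.pos for s in plain if 499_001 <= s.pos <= 500_000]
        if not ov_pos:  # ensure at least one by construction
            pytest.skip("no variant in overlap zone for this seed")
        target = ov_pos[0]

        def perturbed_caller(recs, region, ploidy_map):
            sites = joint_genotype_region(recs, region, ploidy_map)
            if region.start == 1:  # corrupt only the first chunk's copy
                for s in sites:
                    if s.pos == target:
                        victim = next(k for k, v in s.genotypes.items() if v is not None)
                        s.genotypes[victim] = (0, 0)
            return sites

        merged, report = run_chunked(records, contig, 500_000, 1_000,
                                     caller=perturbed_caller)
        assert target not in {s.pos for s in merged}
        assert {r.pos for r in report.removed} == {target}

    def test_conservation_sum_ac_le_an(self, chunked_cohort):
        truth, records = chunked_cohort
        contig = truth.contigs[0]
        merged, _ = run_chunked(records, contig, 500_000, 1_000)
        for e in compute_frequencies(merged):
            assert sum(e.ac) <= e.an <= 2 * len(truth.samples)


class TestAnnotations:
    def _strand_site(self, strand, genotypes=None, qual=30.0, alt_dp=10):
        return VariantSite(
            contig="1", pos=1, ref="A", alts=("G",),
            genotypes=genotypes or {"A": (0, 1)},
            qual=qual, depth_sum=sum(f + r for f, r in strand),
            alt_depth_sum=alt_dp, strand=tuple(strand),
        )

    def test_balanced_strands_give_fs_zero(self):
        ann = compute_site_annotations(self._strand_site([(10, 10), (10, 10)]))
        assert ann.fs == 0.0

    def test_equal_pseudocount_table_gives_sor_ln2(self):
        # all four cells equal after +1 pseudocounts: R = 1, ratios 1
        ann = compute_site_annotations(self._strand_site([(4, 4), (4, 4)]))
        assert ann.sor == pytest.approx(math.log(2), abs=1e-12)

    def test_hwe_proportioned_genotypes_give_zero_inbreeding(self):
        # p = 0.5, 2pq*n = 2 hets out of 4: exactly HWE proportions
        genotypes = {"a": (0, 0), "b": (0, 1), "c": (0, 1), "d": (1, 1)}
        ann = compute_site_annotations(self._strand_site([(5, 5), (5, 5)], genotypes))
        assert ann.inbreeding_coeff == pytest.approx(0.0, abs=1e-12)

    def test_inbreeding_is_absent_without_diploid_calls(self):
        ann = compute_site_annotations(self._strand_site([(5, 5), (5, 5)], {"a": (1,)}))
        assert ann.inbreeding_coeff is None

    def test_qd_normalises_qual_by_alt_carrier_depth(self):
        site = self._strand_site([(10, 10), (10, 10)], qual=60.0, alt_dp=30)
        assert compute_site_annotations(site).qd == pytest.approx(2.0)

    @settings(max_examples=150, deadline=None)
    @given(a=st.integers(0, 12), b=st.integers(0, 12),
           c=st.integers(0, 12), d=st.integers(0, 12))
    def test_fisher_matches_exact_enumeration(self, a, b, c, d):
        assert fisher_exact_two_sided([[a, b], [c, d]]) == pytest.approx(
            fisher_two_sided_exact(a, b, c, d), rel=1e-10, abs=1e-12
        )


class TestHardFilters:
    def _sites(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        sites = []
        for i in range(n):
            strand = ((int(rng.integers(0, 30)), int(rng.integers(0, 30))),
                      (int(rng.integers(0, 30)), int(rng.integers(0, 30))))
            s = VariantSite(
                contig="1", pos=i + 1, ref="A", alts=("G",),
                genotypes={"a": (0, 1), "b": (0, 0)},
                qual=float(rng.integers(0, 99)),
                depth_sum=sum(f + r for f, r in strand),
                alt_depth_sum=int(rng.integers(1, 40)),
                strand=strand,
            )
            sites.append(s)
        annotate_sites(sites)
        return sites

    def test_empty_threshold_set_passes_everything(self):
        sites = self._sites()
        apply_hard_filters(sites)
        assert all(s.filter == "PASS" for s in sites)

    def test_fs_threshold_names_the_failed_annotation(self):
        site = VariantSite(contig="1", pos=1, ref="A", alts=("G",),
                           genotypes={"a": (0, 1)}, qual=10.0, depth_sum=60,
                           alt_depth_sum=30, strand=((30, 0), (0, 30)))
        apply_hard_filters([site], snv_thresholds={"FS": 60.0})
        assert site.filter == "FS"
        balanced = VariantSite(contig="1", pos=2, ref="A", alts=("G",),
                               genotypes={"a": (0, 1)}, qual=10.0, depth_sum=40,
                               alt_depth_sum=20, strand=((10, 10), (10, 10)))
        apply_hard_filters([balanced], snv_thresholds={"FS": 60.0})
        assert balanced.filter == "PASS"

    def test_pass_count_matches_brute_force_recheck(self):
        sites = self._sites(n=1000, seed=42)
        thresholds = {"QD": 2.0, "FS": 10.0, "SOR": 3.0}
        apply_hard_filters(sites, snv_thresholds=thresholds)
        expected_pass = 0
        for s in sites:
            a = s.annotations
            ok = a.qd >= 2.0 and a.fs <= 10.0 and a.sor <= 3.0
            expected_pass += ok
            assert (s.filter == "PASS") == ok
        assert sum(s.filter == "PASS" for s in sites) == expected_pass

    def test_unknown_annotation_is_a_config_error(self):
        with pytest.raises(FilterConfigError):
            apply_hard_filters(self._sites(5), snv_thresholds={"BOGUS": 1.0})


class TestComputeFrequencies:
    def test_autosomal_an_counts_called_diploids(self):
        genotypes = {"a": (0, 1), "b": (1, 1), "c": (0, 0), "d": None, "e": None}
        site = VariantSite(contig="1", pos=1, ref="A", alts=("G",), genotypes=genotypes)
        (entry,) = compute_frequencies([site])
        assert entry.an == 6 and entry.ac == (3,)

    def test_x_nonpar_an_mixes_ploidies(self):
        # 3 females diploid + 2 males haploid, all called -> AN = 8
        genotypes = {"f1": (0, 1), "f2": (1, 1), "f3": (0, 0), "m1": (1,), "m2": (0,)}
        ploidy = {"f1": 2, "f2": 2, "f3": 2, "m1": 1, "m2": 1}
        site = VariantSite(contig="X", pos=1, ref="A", alts=("G",), genotypes=genotypes)
        entries = compute_frequencies([site], lambda s, c, p: ploidy[s])
        assert entries[0].an == 8 and entries[0].ac == (4,)

    def test_x_par_an_is_fully_diploid(self):
        genotypes = {"f1": (0, 1), "f2": (1, 1), "f3": (0, 0),
                     "m1": (1, 1), "m2": (0, 1)}
        site = VariantSite(contig="X", pos=1, ref="A", alts=("G",), genotypes=genotypes)
        entries = compute_frequencies([site], lambda s, c, p: 2)
        assert entries[0].an == 10

    def test_arity_ploidy_mismatch_raises(self):
        site = VariantSite(contig="X", pos=1, ref="A", alts=("G",),
                           genotypes={"m1": (0, 1)})
        with pytest.raises(PloidyConflictError):
            compute_frequencies([site], lambda s, c, p: 1)


class TestTsTv:
    def _entry(self, ref, alts, pos=1):
        from panelforge.joint_panel import PanelEntry

        n = len(alts)
        return PanelEntry(
            contig="1", pos=pos, ref=ref, alts=tuple(alts),
            ac=(1,) * n, an=10, af=(0.1,) * n, multiallelic=n > 1,
        )

    def test_hand_counted_ratio(self):
        entries = [self._entry("A", ["G"]), self._entry("C", ["T"], 2),
                   self._entry("A", ["C"], 3)]
        assert tstv(entries) == pytest.approx(2.0)

    def test_undefined_without_transversions(self):
        assert tstv([self._entry("A", ["G"])]) is None

    def test_multiallelic_counts_each_alt(self):
        # A->(G,T): one transition plus one transversion
        assert tstv([self._entry("A", ["G", "T"])]) == pytest.approx(1.0)

    def test_per_sample_x_restricted_to_females(self):
        site = VariantSite(contig="X", pos=1, ref="A", alts=("G",),
                           genotypes={"f": (0, 1), "m": (1,)})
        out = per_sample_tstv([site], sex={"f": "female", "m": "male"})
        assert "m" not in out
        assert out["f"] is None  # one transition, no transversion


class TestMeanDepthTrack:
    def test_constant_depths_average(self):
        a = np.full((2, 10), 10.0)
        a[1] = 20.0
        mean_all, mean_q20, diff = mean_depth_track(a, a)
        assert (mean_all == 15.0).all() and (diff == 0.0).all()

    def test_span_mismatch_raises(self):
        with pytest.raises(ValueError, match="spans differ"):
            mean_depth_track(np.zeros((2, 10)), np.zeros((2, 9)))

    def test_difference_flags_multimapped_bases(self):
        all_reads = np.full((3, 20), 30.0)
        q20 = all_reads.copy()
        q20[:, 5:10] = 3.0
        _, _, diff = mean_depth_track(all_reads, q20)
        assert (diff[5:10] == 27.0).all() and (diff[:5] == 0.0).all()
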