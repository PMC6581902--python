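import numpy as np
import pytest
from dataclasses import replace

from panelforge.genome import Contig, Region, THREE_PAR, TWO_PAR, XRegionMap
from panelforge.joint_panel import PloidyConflictError, compute_frequencies
from panelforge.sex_chrom_mito import (
    PloidyMap,
    build_x_panels,
    call_mt_panel,
    classify_x_region,
    mt_inverse_remap,
    mt_remap,
    shifted_mt_records,
    xtr_heterozygosity_scan,
)
from panelforge.synthetic import (
    CohortSpec,
    emit_array_genotypes,
    observe,
    scaled_x_length,
    simulate_truth,
)


class TestClassifyXRegion:
    """Region boundaries at the full GRCh37 coordinates."""

    def setup_method(self):
        self.xmap = XRegionMap.grch37()

    def test_par1_start_boundary(self):
        assert classify_x_region(60_001, self.xmap) == "PAR1"

    def test_xtr_depends_on_mode(self):
        assert classify_x_region(88_456_802, self.xmap, THREE_PAR) == "XTR"
        assert classify_x_region(88_456_802, self.xmap, TWO_PAR) == "NONPAR"

    def test_one_past_par1_is_nonpar_in_both_modes(self):
        for mode in (TWO_PAR, THREE_PAR):
            assert classify_x_region(2_699_521, self.xmap, mode) == "NONPAR"

    def test_par2_interval(self):
        assert classify_x_region(154_931_044, self.xmap) == "PAR2"
        assert classify_x_region(155_260_560, self.xmap) == "PAR2"
        assert classify_x_region(155_260_561, self.xmap) == "NONPAR"

    def test_out_of_range_position(self):
        with pytest.raises(ValueError):
            classify_x_region(0, self.xmap)
        with pytest.raises(ValueError):
            classify_x_region(200_000_000, self.xmap, contig_length=155_270_560)


class TestPloidyMap:
    def _pm(self, mode):
        return PloidyMap(
            sex={"f": "female", "m": "male"},
            x_map=XRegionMap.grch37(),
            categories={"X": "chrX", "1": "autosome", "MT": "mito"},
            mode=mode,
        )

    def test_female_always_diploid_on_x(self):
        pm = self._pm(TWO_PAR)
        for pos in (60_001, 50_000_000, 90_000_000, 155_000_000):
            assert pm.ploidy("f", "X", pos) == 2

    def test_male_ploidy_by_region_and_mode(self):
        two, three = self._pm(TWO_PAR), self._pm(THREE_PAR)
        assert two.ploidy("m", "X", 60_001) == 2       # PAR1
        assert two.ploidy("m", "X", 50_000_000) == 1   # non-PAR
        assert two.ploidy("m", "X", 90_000_000) == 1   # XTR under TWO_PAR
        assert three.ploidy("m", "X", 90_000_000) == 2  # XTR under THREE_PAR
        assert two.ploidy("m", "X", 155_000_000) == 2  # PAR2

    def test_everyone_haploid_on_mito(self):
        pm = self._pm(TWO_PAR)
        assert pm.ploidy("f", "MT", 100) == 1
        assert pm.ploidy("m", "MT", 100) == 1


class TestBuildXPanels:
    def test_panels_differ_only_in_xtr(self, x_cohort):
        truth, records = x_cohort
        p2, p3 = build_x_panels(records, truth.sex, truth.contigs[0], truth.x_map)
        xtr = truth.x_map.xtr
        diffs = []
        sites3 = {s.pos: s for s in p3}
        for s in p2:
            other = sites3.get(s.pos)
            if other is None or s.signature() != other.signature():
                diffs.append(s.pos)
        assert diffs  # the XTR truth is diploid-behaving, so they must differ
        assert all(xtr.start <= p <= xtr.end for p in diffs)

    def test_three_par_preserves_male_xtr_heterozygosity(self, x_cohort):
        truth, records = x_cohort
        p2, p3 = build_x_panels(records, truth.sex, truth.contigs[0], truth.x_map)
        males = [s for s in truth.samples if truth.sex[s] == "male"]
        xtr = truth.x_map.xtr

        def male_hets(panel):
            return sum(
                1
                for s in panel
                if xtr.start <= s.pos <= xtr.end
                for m in males
                if (g := s.genotypes.get(m)) and len(g) == 2 and g[0] != g[1]
            )

        assert male_hets(p3) > 0
        assert male_hets(p2) == 0

    def test_female_only_cohort_is_mode_independent(self):
        spec = CohortSpec(n_samples=12, contig_plan=(("chrX", scaled_x_length()),),
                          n_sites=150, sex_ratio=1.0, genotype_error=0.0, seed=44)
        truth = simulate_truth(spec)
        assert all(v == "female" for v in truth.sex.values())
        records = observe(truth)
        p2, p3 = build_x_panels(records, truth.sex, truth.contigs[0], truth.x_map)
        assert [s.signature() for s in p2] == [s.signature() for s in p3]

    def test_male_het_in_strict_nonpar_is_invalid_input(self, x_cohort):
        truth, records = x_cohort
        male = next(s for s in truth.samples if truth.sex[s] == "male")
        strict = truth.x_map.with_mode(THREE_PAR)
        bad = dict(records)
        corrupted = []
        done = False
        for r in records[male]:
            if not done and strict.classify(r.pos) == "NONPAR":
                corrupted.append(
                    replace(r, genotype=(0, 1), ploidy=2, likelihoods=(30, 0, 50))
                )
                done = True
            else:
                corrupted.append(r)
        assert done
        bad[male] = corrupted
        with pytest.raises(PloidyConflictError):
            build_x_panels(bad, truth.sex, truth.contigs[0], truth.x_map)

    def test_no_haploid_context_contains_a_heterozygote(self, x_cohort):
        truth, records = x_cohort
        p2, p3 = build_x_panels(records, truth.sex, truth.contigs[0], truth.x_map)
        for panel in (p2, p3):
            for s in panel:
                for gt in s.genotypes.values():
                    if gt is not None and len(gt) == 1:
                        assert True  # haploid arity can never encode a het
                    elif gt is not None:
                        assert len(gt) == 2

    def test_an_accounting_against_ploidy_map(self, x_cohort):
        truth, records = x_cohort
        _, p3 = build_x_panels(records, truth.sex, truth.contigs[0], truth.x_map)
        pm = PloidyMap(sex=truth.sex, x_map=truth.x_map,
                       categories={"X": "chrX"}, mode=THREE_PAR)
        entries = compute_frequencies(p3, pm)
        for e in entries:
            site = next(s for s in p3 if s.pos == e.pos)
            expected = sum(
                pm.ploidy(s, "X", e.pos)
                for s, g in site.genotypes.items() if g is not None
            )
            assert e.an == expected


class TestXtrScan:
    def test_diploid_par_truth_elevates_exactly_three_regions(self, x_cohort):
        truth, _ = x_cohort
        table = emit_array_genotypes(truth)
        males = [s for s in truth.samples if truth.sex[s] == "male"]
        scan = xtr_heterozygosity_scan(table, males, truth.x_map, window=15)
        by_region = scan.groupby("region")["het_rate"].mean()
        for region in ("PAR1", "XTR", "PAR2"):
            assert by_region[region] > 0.1  # windows purely inside the region
        assert by_region.get("NONPAR", 0.0) == 0.0

    def test_strictly_haploid_males_scan_flat_zero(self):
        spec = CohortSpec(n_samples=16, contig_plan=(("chrX", scaled_x_length()),),
                          n_sites=200, genotype_error=0.0, male_xtr_diploid=True,
                          array_marker_fraction=1.0, array_no_call_rate=0.0, seed=91)
        truth = simulate_truth(spec)
        table = emit_array_genotypes(truth)
        males = [s for s in truth.samples if truth.sex[s] == "male"]
        nonpar = table[
            [truth.x_map.with_mode(THREE_PAR).classify(int(p)) == "NONPAR"
             for p in table["pos"]]
        ]
        scan = xtr_heterozygosity_scan(nonpar, males, truth.x_map, window=10)
        assert (scan["het_rate"].dropna() == 0.0).all()

    def test_error_rate_drives_nonpar_window_het_rate(self):
        err = 0.02
        spec = CohortSpec(n_samples=20, contig_plan=(("chrX", scaled_x_length()),),
                          n_sites=2_000, genotype_error=err, array_error=err,
                          array_marker_fraction=1.0, array_no_call_rate=0.0, seed=17)
        truth = simulate_truth(spec)
        table = emit_array_genotypes(truth)
        males = [s for s in truth.samples if truth.sex[s] == "male"]
        nonpar = table[
            [truth.x_map.with_mode(THREE_PAR).classify(int(p)) == "NONPAR"
             for p in table["pos"]]
        ]
        scan = xtr_heterozygosity_scan(nonpar, males, truth.x_map,
                                       window=len(nonpar))
        rate = scan["het_rate"].iloc[0]
        n = scan["n_calls"].iloc[0]
        # hemizygous truth renders as hom; a single-step flip makes it het
        assert abs(rate - err) < 3 * np.sqrt(err * (1 - err) / n)


MT = Contig("MT", 16_569, circular=True, category="mito")


class TestMtRemap:
    def test_shift_arithmetic(self):
        assert mt_remap(1, 16_569, 10_000) == 10_001

    def test_wrap_boundary(self):
        assert mt_remap(16_569 - 10_000 + 1, 16_569, 10_000) == 1

    def test_bijection_exhaustive(self):
        L = 16_569
        image = {mt_remap(p, L, 10_000) for p in range(1, L + 1)}
        assert image == set(range(1, L + 1))
        for p in range(1, L + 1):
            assert mt_inverse_remap(mt_remap(p, L, 10_000), L, 10_000) == p

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            mt_remap(0)
        with pytest.raises(ValueError):
            mt_remap(16_570)


@pytest.fixture(scope="module")
def mt_cohort():
    spec = CohortSpec(n_samples=25, contig_plan=(("mito", 16_569),), n_sites=300,
                      genotype_error=0.0, seed=13)
    truth = simulate_truth(spec)
    records = observe(truth)
    return truth, records


class TestCallMtPanel:
    def test_identical_call_sets_merge_to_primary(self, mt_cohort):
        truth, records = mt_cohort
        shifted = shifted_mt_records(records)
        panel = call_mt_panel(records, shifted, MT)
        from panelforge.genome import Region as R
        from panelforge.joint_panel import joint_genotype_region

        primary = joint_genotype_region(records, Region("MT", 1, MT.length),
                                        lambda s, c, p: 1)
        assert [s.pos for s in panel] == [s.pos for s in primary]
        assert [s.signature() for s in panel] == [s.signature() for s in primary]

    def test_edge_zone_variant_recovered_from_shifted_set(self, mt_cohort):
        truth, records = mt_cohort
        shifted = shifted_mt_records(records)
        # drop every primary record at pos <= 300: the edge zone is now only
        # visible through the shifted linearization
        gutted = {s: [r for r in rr if r.pos > 300] for s, rr in records.items()}
        panel = call_mt_panel(gutted, shifted, MT, edge_margin=300)
        full = call_mt_panel(records, shifted, MT, edge_margin=300)
        assert [s.pos for s in panel] == [s.pos for s in full]
        edge_pos = [s.pos for s in panel if s.pos <= 300]
        assert edge_pos  # the fixture must exercise the edge zone

    def test_rotation_invariance(self, mt_cohort):
        """Pre-rotating all input coordinates by the shift and un-rotating the
        output must reproduce the same merged panel."""
        truth, records = mt_cohort
        panel = call_mt_panel(records, shifted_mt_records(records), MT)

        rotated = {
            s: sorted((replace(r, pos=mt_remap(r.pos)) for r in rr),
                      key=lambda r: r.pos)
            for s, rr in records.items()
        }
        panel_rot = call_mt_panel(rotated, shifted_mt_records(rotated), MT)
        back = sorted(
            (replace(s, pos=mt_inverse_remap(s.pos)) for s in panel_rot),
            key=lambda s: s.pos,
        )
        assert [s.pos for s in back] == [s.pos for s in panel]
        assert [s.signature() for s in back] == [s.signature() for s in panel]

    def test_diploid_mt_record_rejected(self, mt_cohort):
        truth, records = mt_cohort
        sample = truth.samples[0]
        bad = dict(records)
        r0 = records[sample][0]
        bad[sample] = [replace(r0, genotype=(0, 0), ploidy=2,
                               likelihoods=(0, 40, 80))] + list(records[sample][1:])
        with pytest.raises(PloidyConflictError):
            call_mt_panel(bad, shifted_mt_records(records), MT)

    def test_mt_panel_is_fully_haploid(self, mt_cohort):
        truth, records = mt_cohort
        panel = call_mt_panel(records, shifted_mt_records(records), MT)
        for site in panel:
            for gt in site.genotypes.values():
                assert gt is None or len(gt) == 1
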