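"""Normalization, gene dosage, Y segmentation and mosaic estimation tests."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import noiseless_profile
from exomy import depthcnv, simcov
from exomy.depthcnv import (CallerConfig, CnvCall, estimate_mosaic_fraction,
                            gene_dosage, normalize, segment_y)
from exomy.simcov import DepthParams, GenotypeSpec, simulate_sample


def _normalized(spec, targets, params, batch, reference, seed=0):
    rng = np.random.default_rng(seed)
    table = simulate_sample(spec, params, targets, batch, rng)
    return normalize(table, reference, targets)


class TestNormalize:
    def test_normal_male_single_copy_y_near_one(self, targets, params, batch,
                                                reference):
        profile = _normalized(GenotypeSpec.normal_male(), targets, params,
                              batch, reference)
        for gene in ("USP9Y", "DDX3Y", "KDM5D", "EIF1AY", "RPS4Y2"):
            gd = gene_dosage(profile, gene)
            assert gd.estimate == pytest.approx(1.0, abs=0.15)

    def test_autosomal_median_exactly_two(self, targets, params, batch,
                                          reference):
        profile = _normalized(GenotypeSpec.normal_male(), targets, params,
                              batch, reference, seed=1)
        auto = [profile.dosages[t.target_id] for t in targets
                if t.chrom not in ("chrX", "chrY")
                and t.target_id not in profile.masked]
        assert float(np.median(auto)) == pytest.approx(2.0, abs=1e-12)

    def test_klinefelter_dosages(self, targets, params, batch, reference):
        profile = _normalized(GenotypeSpec.aneuploid("47,XXY"), targets,
                              params, batch, reference, seed=2)
        x = np.median([profile.relative(t) for t in profile.targets_on("chrX")])
        y = np.median([profile.relative(t) for t in profile.targets_on("chrY")])
        assert x == pytest.approx(2.0, abs=0.15)
        assert y == pytest.approx(1.0, abs=0.15)

    def test_sample_equal_to_reference_median_is_exactly_baseline(
            self, targets):
        p = DepthParams(efficiency_sd=0.0, dispersion=0.0, seed=0)
        spec = GenotypeSpec.normal_male()
        mu = simcov.expected_depths(spec, p, targets)
        table = simcov.CoverageTable("exact", dict(mu))
        reference = [simcov.CoverageTable(f"r{i}", dict(mu))
                     for i in range(10)]
        profile = normalize(table, reference, targets)
        for t in targets:
            assert profile.dosages[t.target_id] == pytest.approx(
                t.baseline_copies, abs=1e-9)

    def test_reference_too_small_rejected(self, targets, params, batch):
        rng = np.random.default_rng(0)
        table = simulate_sample(GenotypeSpec.normal_male(), params, targets,
                                batch, rng)
        refs = simcov.simulate_reference_cohort(
            10, params, targets, batch, np.random.default_rng(1))
        with pytest.raises(ValueError, match="too small"):
            normalize(table, refs[:5], targets)

    def test_zero_median_target_masked(self, targets, params, batch,
                                       reference):
        rng = np.random.default_rng(3)
        table = simulate_sample(GenotypeSpec.normal_male(), params, targets,
                                batch, rng)
        dead = [simcov.CoverageTable(r.sample_id,
                                     {**r.depths, "SRY_01": 0.0})
                for r in reference]
        profile = normalize(table, dead, targets)
        assert "SRY_01" in profile.masked
        assert "SRY_01" not in profile.dosages


class TestGeneDosage:
    def test_complete_azfc_daz_zero_of_four(self, targets, params, batch,
                                            reference):
        profile = _normalized(GenotypeSpec.deletion(simcov.AZFC_DEL), targets,
                              params, batch, reference, seed=4)
        gd = gene_dosage(profile, "DAZ")
        assert gd.baseline == 4
        assert gd.estimate == pytest.approx(0.0, abs=0.3)

    def test_grgr_daz_two_of_four(self, targets, params, batch, reference):
        profile = _normalized(GenotypeSpec.deletion(simcov.GRGR_DEL), targets,
                              params, batch, reference, seed=5)
        assert gene_dosage(profile, "DAZ").estimate == pytest.approx(2.0, abs=0.5)
        assert gene_dosage(profile, "BPY2").estimate == pytest.approx(3.0, abs=0.5)

    def test_azfbc_duplication_doubles_family_dosage(self, targets, params,
                                                     batch, reference):
        profile = _normalized(GenotypeSpec.duplication(simcov.AZFBC_DUP),
                              targets, params, batch, reference, seed=6)
        assert gene_dosage(profile, "DAZ").estimate == pytest.approx(8.0, rel=0.1)
        assert gene_dosage(profile, "RBMY").estimate == pytest.approx(12.0, rel=0.1)

    def test_all_masked_gives_sentinel(self, targets, params, batch,
                                       reference):
        profile = _normalized(GenotypeSpec.normal_male(), targets, params,
                              batch, reference, seed=7)
        profile.masked.add("SRY_01")
        gd = gene_dosage(profile, "SRY")
        assert gd.n_targets == 0
        assert math.isnan(gd.estimate)


def _truth_segments(spec, targets):
    """Independent oracle: exhaustive scan of planted per-target copy states."""
    loci = simcov.build_gene_loci(targets)
    ytargets = sorted((t for t in targets if t.chrom == "chrY"),
                      key=lambda t: t.start)
    states = [spec.target_copies(t, loci) / t.baseline_copies
              for t in ytargets]
    runs = []
    i = 0
    while i < len(states):
        if states[i] == 1.0:
            i += 1
            continue
        j = i
        while j + 1 < len(states) and states[j + 1] == states[i]:
            j += 1
        runs.append((ytargets[i].start, ytargets[j].end, states[i],
                     j == len(states) - 1))
        i = j + 1
    return runs


VALIDATION_SPECS = [
    GenotypeSpec.normal_male(),
    GenotypeSpec.deletion(simcov.AZFA_DEL),
    GenotypeSpec.deletion(simcov.AZFB_DEL),
    GenotypeSpec.deletion(simcov.AZFBC_DEL),
    GenotypeSpec.deletion(simcov.AZFC_DEL),
    GenotypeSpec.idic_y(),
    GenotypeSpec.iso_yp(),
    GenotypeSpec.aneuploid("45,X"),
    GenotypeSpec.aneuploid("47,XYY"),
]


class TestSegmentY:
    @pytest.mark.parametrize("spec", VALIDATION_SPECS,
                             ids=lambda s: s.karyotype + str(s.events))
    def test_noiseless_segmentation_matches_truth_scan(self, spec, targets):
        profile = noiseless_profile(spec, targets)
        calls = segment_y(profile)
        truth = _truth_segments(spec, targets)
        assert len(calls) == len(truth)
        for call, (start, end, state, terminal) in zip(calls, truth):
            assert call.inner == (start, end)
            assert call.copy_state == pytest.approx(state)
            assert call.terminal == terminal

    def test_normal_profile_gives_no_calls(self, targets, params, batch,
                                           reference):
        profile = _normalized(GenotypeSpec.normal_male(), targets, params,
                              batch, reference, seed=8)
        assert segment_y(profile) == []

    def test_b2b4_single_loss_call_covers_daz_bpy2(self, targets, params,
                                                   batch, reference):
        profile = _normalized(GenotypeSpec.deletion(simcov.AZFC_DEL), targets,
                              params, batch, reference, seed=9)
        calls = segment_y(profile)
        assert len(calls) == 1
        call = calls[0]
        assert call.direction == "loss" and call.copy_state == 0.0
        for t in targets:
            if t.family_id in ("DAZ", "BPY2"):
                assert call.inner[0] <= t.start and t.end <= call.inner[1]
        assert call.inner == (25130409, 27198251)
        assert call.outer == (24564028, 58911806)

    def test_idic_profile_gain_plus_terminal_loss(self, targets, params,
                                                  batch, reference):
        profile = _normalized(GenotypeSpec.idic_y(), targets, params, batch,
                              reference, seed=10)
        calls = segment_y(profile)
        directions = [c.direction for c in calls]
        assert directions == ["gain", "loss"]
        assert calls[1].terminal

    def test_outer_contains_inner_invariant(self):
        with pytest.raises(ValueError):
            CnvCall("chrY", inner=(10, 20), outer=(12, 18), copy_state=0,
                    direction="loss")


class TestMosaicFraction:
    def test_thirty_percent_loss(self):
        est = estimate_mosaic_fraction(0.7, 1.0, "loss")
        assert est.fraction == pytest.approx(0.30)

    def test_baseline_dosage_gives_zero(self):
        assert estimate_mosaic_fraction(1.0, 1.0, "loss").fraction == 0.0

    def test_gain_closed_form(self):
        est = estimate_mosaic_fraction(1.5, 1.0, "gain", gain_copies=1)
        assert est.fraction == pytest.approx(0.5)

    def test_zero_baseline_errors(self):
        with pytest.raises(ValueError):
            estimate_mosaic_fraction(0.5, 0.0, "loss")

    @given(st.floats(0, 3, allow_nan=False), st.floats(0.5, 4),
           st.sampled_from(["loss", "gain"]))
    def test_fraction_always_clamped(self, dosage, baseline, direction):
        est = estimate_mosaic_fraction(dosage, baseline, direction)
        assert 0.0 <= est.fraction <= 1.0
        assert 0.0 <= est.interval[0] <= est.fraction <= est.interval[1] <= 1.0

    def test_interval_propagates_spread(self):
        tight = estimate_mosaic_fraction(0.7, 1.0, "loss", spread=0.01,
                                         n_targets=50)
        wide = estimate_mosaic_fraction(0.7, 1.0, "loss", spread=0.2,
                                        n_targets=5)
        assert (tight.interval[1] - tight.interval[0]) < \
            (wide.interval[1] - wide.interval[0])


class TestRoundTripRecovery:
    def test_integer_states_recovered_for_single_copy_genes(
            self, targets, params, batch, reference):
        """Called copy state equals truth for single-copy genes at 100x."""
        config = CallerConfig()
        specs = [GenotypeSpec.normal_male()] * 10 + \
            [GenotypeSpec.deletion(simcov.AZFC_DEL)] * 10 + \
            [GenotypeSpec.deletion(simcov.AZFB_DEL)] * 10
        loci = simcov.build_gene_loci(targets)
        rng = np.random.default_rng(11)
        wrong = 0
        checks = 0
        for spec in specs:
            table = simulate_sample(spec, params, targets, batch, rng)
            profile = normalize(table, reference, targets)
            for gene in ("USP9Y", "DDX3Y", "KDM5D", "EIF1AY", "RPS4Y2"):
                truth = spec.target_copies(
                    next(t for t in targets if t.gene == gene), loci)
                gd = gene_dosage(profile, gene)
                called = (0 if gd.estimate < config.absent_below
                          else 1 if gd.estimate >= config.present_at_least
                          else None)
                checks += 1
                wrong += called != truth
        assert wrong == 0, f"{wrong}/{checks} gene states miscalled"


class TestCallExport:
    def test_bed_and_json_export(self, targets, tmp_path):
        from exomy.depthcnv import write_calls_bed, write_calls_json
        import json

        profile = noiseless_profile(
            GenotypeSpec.deletion(simcov.AZFC_DEL), targets)
        calls = segment_y(profile)
        bed = tmp_path / "calls.bed"
        js = tmp_path / "calls.json"
        write_calls_bed(calls, bed)
        write_calls_json(calls, js)
        assert bed.read_text() == "chrY\t25130409\t27198251\tloss_x0\n"
        rec = json.loads(js.read_text())[0]
        assert rec["outer"] == [24564028, 58911806]
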