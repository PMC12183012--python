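"""Reporting-layer tests: statistics, categories, nomenclature, summaries."""

import itertools

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exomy.azf import AzfClass, AzfClassification
from exomy.cftr import CftrFindings
from exomy.depthcnv import CnvCall
from exomy.evalreport import (CATEGORIES, ConfusionMatrix, DiagnosticReport,
                              assign_category, confusion_stats,
                              filter_to_panel, format_iscn_like,
                              format_karyotype_iscn, karyotype_from_iscn,
                              parse_iscn_like, rule_of_three_bound,
                              summarize_cohort)
from exomy.sexkaryo import KaryotypeCall, SexDosages

KLINEFELTER = "seq(X)×2,(Y)×1 NC_000023.10:g.[pter_qter]sup"

# the six non-Klinefelter chromosomal-anomaly result strings of the
# evaluation cohort, as printed
ANOMALY_STRINGS = {
    "P55": ("seq[GRCh37] Ypterq11.221(2655082_15032390)×1∼2,"
            "Yq11.221qter(19880860_qter)×0 "
            "NC_000024.9:g.pter_(15032390_19880860)dup mos "
            "NC_000024.9:g.(15032390_19880860)_qterdel"),
    "P214": ("seq[GRCh37] Xp22.33q28(3544582×1,3559783_qter×2), "
             "Yp11.2q12(5605902×1,6114298_qter×0) "
             "NC_000023.10:g.(3544582_ 3559877)_qterdup "
             "NC_000024.9:g.(5605902_6114298)_qterdel"),
    "P241": ("seq[GRCh37] 4p11q12(48906608×2,48988393_52887490×1, "
             "52887882×2),4q12(54374394×2,54424011_55141218×1,55143475×2),"
             "4q12(55606853×2,55946107_57220377×1,57220849×2) "
             "NC_000004.11:g.[(48906608_48988393)_(52887490_52887882)del;"
             "(54374394_54424011)_(55141218_55143475)del;"
             "(55606853_55946107)_(57220377_57220849)del]"),
    "P254": ("seq[GRCh37] Xp22.33q28(3264653×1,3530228_qter×2), "
             "Yp11.2q12(5605902×1,6114298_qter×0) "
             "NC_000023.10:g.(3264653_3530228)_qterdup "
             "NC_000024.9:g.(5605902_6114298)_qterdel"),
    "P269": ("seq[GRCh37] Ypterq11.222(pter_19991724)×2,Yq11.222qter "
             "(20138043_qter)×0 NC_000024.9:g.pter_(19991724_20138043)dup "
             "NC_000024.9:g.(19991724_20138043)_qterdel"),
    "P292": ("seq[GRCh37] Xp22.33q28(2699968_qter×2),Yp11.2q12(2848037×1, "
             "3447310_qter×0) NC_000023.10:g.(pter_2699968)_qterdup "
             "NC_000024.9:g.(2848037_3447310)_qterdel"),
}

EXPECTED_CLASS = {
    "P55": "idic_or_iso_Y",
    "P214": "46,XX_SRY+",
    "P241": "46,XY",          # autosomal-only imbalance
    "P254": "46,XX_SRY+",
    "P269": "idic_or_iso_Y",
    "P292": "46,XX_SRY+",
}


class TestRuleOfThree:
    @pytest.mark.parametrize("n,expected", [
        (61, 95.1), (73, 95.9), (101, 97.0), (3, 0.0), (300, 99.0), (1, 0.0),
    ])
    def test_bounds(self, n, expected):
        assert rule_of_three_bound(n).bound_percent == expected

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            rule_of_three_bound(0)

    @given(st.integers(4, 100_000))
    def test_increasing_above_three(self, n):
        # the exact bound is strictly increasing; the one-decimal rendering
        # is monotone non-decreasing
        assert (1 - 3 / (n + 1)) > (1 - 3 / n)
        assert rule_of_three_bound(n + 1).bound_percent >= \
            rule_of_three_bound(n).bound_percent


class TestConfusionStats:
    def test_cftr_validation_worked_example(self):
        calls = [True] * 17 + [False] + [False] * 83
        truth = [True] * 18 + [False] * 83
        cm = confusion_stats(calls, truth)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (17, 1, 83, 0)
        assert cm.sensitivity_percent() == 94
        assert cm.specificity_percent() == 100

    def test_all_correct(self):
        cm = confusion_stats([True, False], [True, False])
        assert cm.sensitivity_percent() == 100
        assert cm.specificity_percent() == 100

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_stats([True], [True, False])

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1,
                    max_size=50))
    def test_matches_exhaustive_recount(self, pairs):
        calls = [c for c, _ in pairs]
        truth = [t for _, t in pairs]
        cm = confusion_stats(calls, truth)
        recount = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for c, t in pairs:
            key = ("t" if c == t else "f") + ("p" if c else "n")
            recount[key] += 1
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (
            recount["tp"], recount["fp"], recount["tn"], recount["fn"])
        assert cm.tp + cm.fp + cm.tn + cm.fn == len(pairs)


def _karyo(cls):
    d = SexDosages(1, 1, 1, 1, 1)
    return KaryotypeCall(cls, d, True)


def _azf(cls):
    if cls == AzfClass.NONE:
        return AzfClassification(cls)
    return AzfClassification(cls, evidence={"x": "lost"})


def _cftr(cls, std):
    return CftrFindings(classification=cls, standard_detectable=std,
                        pathogenic_alleles={"none": 0, "carrier": 1,
                                            "biallelic_CFTR_related": 2}[cls])


class TestAssignCategory:
    def test_klinefelter_is_standard_detectable(self):
        r = DiagnosticReport("s", karyotype=_karyo("47,XXY"))
        assert assign_category(r) == "standard_detectable"

    def test_panel_cnv_is_extra_yield(self):
        r = DiagnosticReport("s", panel_pathogenic=True)   # e.g. DPY19L2 loss
        assert assign_category(r) == "extra_yield"

    def test_single_cftr_allele_is_carrier_only(self):
        r = DiagnosticReport("s", cftr=_cftr("carrier", True))
        assert assign_category(r) == "cf_carrier_only"

    def test_nonkit_biallelic_cftr_is_extra_yield(self):
        r = DiagnosticReport("s", cftr=_cftr("biallelic_CFTR_related", False))
        assert assign_category(r) == "extra_yield"

    def test_total_and_deterministic_over_flag_space(self):
        karyos = [None, _karyo("46,XY"), _karyo("47,XXY")]
        azfs = [None, _azf(AzfClass.NONE), _azf(AzfClass.AZFC),
                _azf(AzfClass.PARTIAL)]
        cftrs = [None, _cftr("none", False), _cftr("carrier", True),
                 _cftr("biallelic_CFTR_related", True),
                 _cftr("biallelic_CFTR_related", False)]
        for k, a, c, pp, vus in itertools.product(
                karyos, azfs, cftrs, [False, True], [False, True]):
            r = DiagnosticReport("s", karyotype=k, azf=a, cftr=c,
                                 panel_pathogenic=pp, reportable_vus=vus)
            cat = assign_category(r)
            assert cat in CATEGORIES
            assert assign_category(r) == cat

    def test_vus_reportability_switch(self):
        r = DiagnosticReport("s", reportable_vus=True)
        assert assign_category(r, vus_reportable=True) == "extra_yield"
        assert assign_category(r, vus_reportable=False) == "none"


class TestPanelFilter:
    def test_panel_gene_retained_off_panel_removed(self):
        table = pd.DataFrame({
            "gene": ["DPY19L2", "NOTAGENE", "CFTR"],
            "variant": ["del", "snv", "snv"],
        })
        kept = filter_to_panel(table)
        assert list(kept["gene"]) == ["DPY19L2", "CFTR"]

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            filter_to_panel(pd.DataFrame({"gene": []}), gene_list=[])


class TestIscnFormatting:
    def test_azfc_call_formats_to_printed_string(self):
        call = CnvCall("chrY", inner=(25130409, 27198251),
                       outer=(24564028, 58911806), copy_state=0,
                       direction="loss")
        assert format_iscn_like(call) == (
            "seq[GRCh37] Yq11.223q11.23(25130410_27198251)×0 "
            "NC_000024.9:g.(24564028_25130410)_(27198251_58911807)del")

    def test_klinefelter_formats_to_ploidy_string(self):
        assert format_karyotype_iscn(_karyo("47,XXY")) == KLINEFELTER

    def test_structural_call_has_no_ploidy_string(self):
        with pytest.raises(ValueError):
            format_karyotype_iscn(_karyo("idic_or_iso_Y"))

    @pytest.mark.parametrize("call", [
        CnvCall("chrY", (25130409, 27198251), (24564028, 58911806), 0, "loss"),
        CnvCall("chrY", (20708556, 24564028), (15032390, 25130409), 0, "loss"),
        CnvCall("chrY", (2655081, 15032390), (0, 20708556), 2, "gain"),
        CnvCall("chrY", (20708556, 58912200), (15032390, 59373566), 0, "loss",
                terminal=True),
        CnvCall("chrY", (20708556, 58912200), (15032390, 59373566), 0.5,
                "loss", terminal=True),
    ])
    def test_format_parse_round_trip(self, call):
        parsed = parse_iscn_like(format_iscn_like(call))
        assert len(parsed.calls) == 1
        assert parsed.calls[0] == call


class TestPrintedResultParsing:
    def test_klinefelter_string_classifies_as_xxy(self, targets):
        assert karyotype_from_iscn(KLINEFELTER, targets).karyotype == "47,XXY"

    @pytest.mark.parametrize("patient", sorted(ANOMALY_STRINGS))
    def test_anomaly_strings_classify(self, targets, patient):
        call = karyotype_from_iscn(ANOMALY_STRINGS[patient], targets)
        assert call.karyotype == EXPECTED_CLASS[patient]

    def test_seventeen_profiles_give_eleven_klinefelters(self, targets):
        strings = [KLINEFELTER] * 11 + list(ANOMALY_STRINGS.values())
        classes = [karyotype_from_iscn(s, targets).karyotype for s in strings]
        assert classes.count("47,XXY") == 11

    def test_unparseable_string_rejected(self):
        with pytest.raises(ValueError):
            parse_iscn_like("karyotype 46,XY")


class TestCohortSummary:
    def test_evaluation_cohort_reconstruction(self):
        """Category counts rebuilt from the reported cohort composition:
        30 standard-detectable, 28 extra yield, 9 carriers of 292 -> 22.9%."""
        reports = []
        mk = DiagnosticReport
        # 17 chromosomal anomalies
        for i, cls in enumerate(["47,XXY"] * 11 + ["idic_or_iso_Y"] * 2 +
                                ["46,XX_SRY+"] * 3 + ["structural_Y_anomaly"]):
            reports.append(mk(f"k{i}", karyotype=_karyo(cls)))
        # 6 classical AZF deletions
        for i, cls in enumerate([AzfClass.AZFB] + [AzfClass.AZFC] * 5):
            reports.append(mk(f"a{i}", azf=_azf(cls)))
        # 10 biallelic CFTR: 7 fully in-kit, 3 with a non-kit variant
        for i in range(7):
            reports.append(mk(f"c{i}",
                              cftr=_cftr("biallelic_CFTR_related", True)))
        for i in range(3):
            reports.append(mk(f"n{i}",
                              cftr=_cftr("biallelic_CFTR_related", False)))
        # 10 monogenic panel findings, 15 reportable VUS
        for i in range(10):
            reports.append(mk(f"m{i}", panel_pathogenic=True))
        for i in range(15):
            reports.append(mk(f"v{i}", reportable_vus=True))
        # 9 CF carriers
        for i in range(9):
            reports.append(mk(f"r{i}", cftr=_cftr("carrier", True)))
        # negatives up to 292
        while len(reports) < 292:
            reports.append(mk(f"x{len(reports)}"))
        summary = summarize_cohort(reports)
        assert summary.n == 292
        assert summary.category_counts["standard_detectable"] == 30
        assert summary.category_counts["extra_yield"] == 28
        assert summary.category_counts["cf_carrier_only"] == 9
        assert summary.abnormal == 67
        assert summary.abnormal_percent == 22.9
        assert summary.percent("standard_detectable") == 10.3

    def test_all_none_cohort(self):
        reports = [DiagnosticReport(f"s{i}") for i in range(10)]
        summary = summarize_cohort(reports)
        assert summary.abnormal == 0
        assert summary.abnormal_percent == 0.0

    def test_totals_equal_category_sum(self):
        reports = [DiagnosticReport("a", panel_pathogenic=True),
                   DiagnosticReport("b"),
                   DiagnosticReport("c", cftr=_cftr("carrier", True))]
        summary = summarize_cohort(reports)
        assert sum(summary.category_counts.values()) == summary.n

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])
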