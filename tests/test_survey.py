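from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoscan.refmap import build_reference_map
from mitoscan.seqio import AA_ALPHABET, MultipleAlignment, SequenceRecord, translate
from mitoscan.simulate import make_barcode_panel
from mitoscan.survey import (
    FixationReport,
    classify_fixation,
    merge_reports,
    place_barcode,
    rank_substituted_clades,
    survey_position,
    write_fixation_tsv,
)


def random_protein(rng, n=120):
    return "".join(rng.choice(list(AA_ALPHABET), size=n))


class TestClassifyFixation:
    def test_derived_fixed(self):
        state = classify_fixation({"S": 110}, "A", threshold=1.0)
        assert (state.kind, state.residue, state.derived) == ("fixed", "S", True)

    def test_ancestral_fixed(self):
        state = classify_fixation({"A": 8}, "A", threshold=1.0)
        assert (state.kind, state.residue, state.derived) == ("fixed", "A", False)

    def test_unfixed(self):
        assert classify_fixation({"A": 8, "S": 5}, "A", 1.0).kind == "unfixed"

    def test_empty_absent(self):
        assert classify_fixation({}, "A").kind == "absent"

    def test_near_fixation_thresholds(self):
        spectrum = {"S": 914, "A": 1}
        assert classify_fixation(spectrum, "A", 1.0).kind == "unfixed"
        state = classify_fixation(spectrum, "A", 0.99)
        assert (state.kind, state.residue, state.derived) == ("fixed", "S", True)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            classify_fixation({"A": 1}, "A", threshold=0.5)

    @settings(max_examples=100, deadline=None)
    @given(
        st.dictionaries(
            st.sampled_from(list("ACDS")), st.integers(0, 50), min_size=1, max_size=4
        ),
        st.floats(0.51, 1.0),
        st.floats(0.51, 1.0),
    )
    def test_threshold_monotonicity(self, spectrum, t1, t2):
        # the set of fixed spectra shrinks as the threshold rises
        lo, hi = sorted((t1, t2))
        if classify_fixation(spectrum, "A", hi).kind == "fixed":
            assert classify_fixation(spectrum, "A", lo).kind == "fixed"


class TestPlaceBarcode:
    def test_exact_fragment_placement(self, rng):
        ref = random_protein(rng)
        fragment = ref[40:80]
        nt = "".join(_codon(aa) for aa in fragment)
        placed = place_barcode(nt, ref, code="vertebrate-mitochondrial")
        assert all(placed[p] == ref[p - 1] for p in range(41, 81))
        assert 40 not in placed and 81 not in placed

    def test_variant_residue_preserved(self, rng):
        ref = random_protein(rng)
        variant = ref[30:59] + "W" + ref[60:90]
        nt = "".join(_codon(aa) for aa in variant)
        placed = place_barcode(nt, ref)
        assert placed[60] == "W"


def _codon(aa):
    from mitoscan.seqio import get_code

    return get_code("vertebrate-mitochondrial").codons_for(aa)[0]


class TestSurveyAligned:
    @staticmethod
    def _setup():
        ref = SequenceRecord("ref", "MKVAL")
        rows = [
            ref,
            SequenceRecord("s1", "MKSAL"),
            SequenceRecord("s2", "MKSAL"),
            SequenceRecord("s3", "MKVAL"),
            SequenceRecord("s4", "MK-AL"),
        ]
        aln = MultipleAlignment(rows)
        refmap = build_reference_map(aln, "ref")
        ann = {"ref": "outgrp", "s1": "humm", "s2": "humm", "s3": "humm", "s4": "humm"}
        return rows, refmap, ann

    def test_counts_and_spectrum(self):
        rows, refmap, ann = self._setup()
        reports = survey_position(rows[1:], ann, 3, refmap=refmap, ancestral="V")
        rep = reports["humm"]
        assert (rep.n_total, rep.n_informative) == (4, 3)
        assert rep.spectrum == Counter({"S": 2, "V": 1})
        assert rep.fixation_state.kind == "unfixed"

    def test_unmapped_position_rejected(self):
        rows = [SequenceRecord("ref", "M-K"), SequenceRecord("s1", "MAK")]
        aln = MultipleAlignment(rows)
        refmap = build_reference_map(aln, "ref")
        with pytest.raises(KeyError):
            survey_position(rows[1:], {"s1": "c"}, 5, refmap=refmap)

    def test_unannotated_sample_rejected(self):
        rows, refmap, _ = self._setup()
        with pytest.raises(KeyError, match="no annotation"):
            survey_position(rows[1:], {"s1": "humm"}, 3, refmap=refmap)

    def test_exclusion_list(self):
        rows, refmap, ann = self._setup()
        reports = survey_position(
            rows[1:], ann, 3, refmap=refmap, exclude=["s3"]
        )
        assert reports["humm"].n_total == 3
        assert reports["humm"].spectrum == Counter({"S": 2})

    def test_clade_field_selection(self):
        rows, refmap, _ = self._setup()
        ann = {r.id: {"order": "Apodiformes", "family": "Trochilidae"} for r in rows}
        reports = survey_position(
            rows[1:], ann, 3, refmap=refmap, clade_field="family"
        )
        assert set(reports) == {"Trochilidae"}
        with pytest.raises(ValueError, match="clade_field"):
            survey_position(rows[1:], ann, 3, refmap=refmap)


class TestSurveyBarcodes:
    def test_near_fixation_panel(self, rng):
        # {S:914, A:1} hummingbirds + {A:110} swifts, full coverage
        ref = random_protein(rng, 160)
        focal = 83
        base = ref[:focal - 1] + "A" + ref[focal:]
        records, ann, _, truth = make_barcode_panel(
            {"humm": base, "swift": base},
            {"humm": {"S": 914, "A": 1}, "swift": {"A": 110}},
            focal_ref_position=focal,
            coverage=1.0,
            seed=42,
        )
        reports = survey_position(
            records, ann, focal, reference_protein=base, ancestral="A",
            threshold=1.0,
        )
        assert reports["humm"].spectrum == Counter({"S": 914, "A": 1})
        assert reports["humm"].n_informative == 915
        assert reports["humm"].fixation_state.kind == "unfixed"
        assert reports["swift"].spectrum == Counter({"A": 110})
        assert reports["swift"].fixation_state.residue == "A"
        relaxed = survey_position(
            records, ann, focal, reference_protein=base, ancestral="A",
            threshold=0.99,
        )
        assert relaxed["humm"].fixation_state.residue == "S"
        assert relaxed["humm"].fixation_state.derived is True

    def test_zero_coverage_absent(self, rng):
        ref = random_protein(rng, 100)
        records, ann, _, _ = make_barcode_panel(
            {"c1": ref}, {"c1": {"S": 12}}, focal_ref_position=50,
            coverage=0.0, seed=1,
        )
        reports = survey_position(records, ann, 50, reference_protein=ref)
        rep = reports["c1"]
        assert (rep.n_total, rep.n_informative) == (12, 0)
        assert rep.fixation_state.kind == "absent"

    def test_partial_coverage_counts(self, rng):
        ref = random_protein(rng, 100)
        records, ann, _, truth = make_barcode_panel(
            {"c1": ref}, {"c1": {"S": 10, "T": 10}}, focal_ref_position=60,
            coverage=0.5, seed=3,
        )
        reports = survey_position(records, ann, 60, reference_protein=ref)
        rep = reports["c1"]
        assert rep.n_total == 20
        assert rep.n_informative == truth["coverage"]["c1"] == 10
        assert rep.spectrum == Counter(truth["spectra"]["c1"])


class TestMergeAndRank:
    def test_merge_additivity(self):
        a = FixationReport(5, "x", 10, 8, Counter({"A": 8}))
        b = FixationReport(5, "x", 4, 3, Counter({"A": 2, "S": 1}))
        merged = merge_reports(a, b, ancestral="A")
        assert merged.n_total == 14
        assert merged.n_informative == 11
        assert merged.spectrum == Counter({"A": 10, "S": 1})

    def test_rank_empty(self):
        reports = {"c": FixationReport(5, "c", 3, 3, Counter({"A": 3}))}
        df, overall = rank_substituted_clades(reports, "A")
        assert df.empty
        assert overall == {"divergent": 0, "informative": 3, "fraction": 0.0}

    def test_rank_rare_divergence_ratio(self):
        # 15 divergent of 36,636 informative bird samples
        reports = {
            "birds": FixationReport(
                153, "birds", 36_700, 36_636, Counter({"A": 36_621, "S": 15})
            )
        }
        df, overall = rank_substituted_clades(reports, "A")
        assert overall["divergent"] == 15
        assert overall["informative"] == 36_636
        assert overall["fraction"] == pytest.approx(15 / 36_636)
        assert overall["fraction"] < 0.001  # rendered "< 0.1%"
        assert df.iloc[0]["n_derived"] == 15

    def test_rank_order_invariant_to_sample_shuffle(self, rng):
        ref = random_protein(rng, 80)
        records, ann, _, _ = make_barcode_panel(
            {"c1": ref, "c2": ref},
            {"c1": {"A": 5, "S": 3}, "c2": {"A": 6, "S": 1}},
            focal_ref_position=40, coverage=1.0, seed=5,
        )
        order = list(records)
        rng.shuffle(order)
        r1 = survey_position(records, ann, 40, reference_protein=ref)
        r2 = survey_position(order, ann, 40, reference_protein=ref)
        d1, o1 = rank_substituted_clades(r1, "A")
        d2, o2 = rank_substituted_clades(r2, "A")
        assert o1 == o2
        assert d1.equals(d2)


def test_fixation_tsv(tmp_path):
    reports = {
        "humm": FixationReport(153, "humm", 915, 915, Counter({"S": 914, "A": 1})),
    }
    reports["humm"].fixation_state = classify_fixation(
        reports["humm"].spectrum, "A", 0.99
    )
    out = tmp_path / "fix.tsv"
    write_fixation_tsv(reports, out)
    body = out.read_text().splitlines()[1]
    assert body == "humm\t153\t915\t915\tA:1,S:914\tderived-fixed(S)"


def test_report_invariants():
    with pytest.raises(ValueError):
        FixationReport(1, "c", 3, 5, Counter({"A": 5}))
    with pytest.raises(ValueError):
        FixationReport(1, "c", 5, 3, Counter({"A": 5}))
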