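"""Correction chains, collagen QC, zone classification, KS comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from punapipe.evidence import ModelExpectation, expectations
from punapipe.isotopes import (CorrectionStep, DEFAULT_D18O_CHAIN, apply_chain,
                               classify_zone, collagen_qc,
                               evaluate_isotope_hypothesis, ks_two_sample)
from punapipe.samples import IsotopeSample

finite_permil = st.floats(min_value=-45, max_value=45)


class TestApplyChain:
    @pytest.mark.parametrize("raw, chain, expected", [
        (-10.0, [], -10.0),
        (-10.0, [CorrectionStep("Suess", 1.0, 1.5)], -8.5),
        (0.0, [CorrectionStep("VPDB->VSMOW", 1.03091, 30.91)], 30.91),
    ])
    def test_examples(self, raw, chain, expected):
        assert apply_chain(raw, chain) == pytest.approx(expected)

    def test_default_d18o_chain_composes_three_steps(self):
        # hand-folded: VPDB->VSMOW, -8.5 offset, phosphate-water inversion
        v = 1.03091 * (-10.0) + 30.91
        v = v - 8.5
        v = (v - 22.7) / 0.78
        assert apply_chain(-10.0, DEFAULT_D18O_CHAIN) == pytest.approx(v)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            apply_chain(float("nan"), [])

    @settings(derandomize=True, max_examples=50)
    @given(v=finite_permil,
           params=st.lists(st.tuples(st.floats(0.5, 2.0), st.floats(-10, 10)),
                           max_size=6))
    def test_chains_compose_associatively(self, v, params):
        chain = [CorrectionStep(f"s{i}", a, b) for i, (a, b) in enumerate(params)]
        for cut in range(len(chain) + 1):
            split = apply_chain(apply_chain(v, chain[:cut]), chain[cut:])
            assert split == pytest.approx(apply_chain(v, chain), rel=1e-12, abs=1e-12)


class TestCollagenQC:
    def test_published_check_values_pass(self):
        qc = collagen_qc(44, 16)
        assert qc.atomic_cn_ratio == pytest.approx(3.2, abs=0.05)
        assert qc.passes

    def test_equal_mole_counts_give_unit_ratio(self):
        qc = collagen_qc(12.011, 14.007)
        assert qc.atomic_cn_ratio == pytest.approx(1.0)
        assert not qc.passes

    def test_boundary_mass_fractions_fail_on_ratio(self):
        # (35/12.011)/(11/14.007) = 3.711 > 3.6
        qc = collagen_qc(35, 11)
        assert qc.atomic_cn_ratio == pytest.approx(3.711, abs=0.001)
        assert not qc.passes

    @settings(derandomize=True, max_examples=200)
    @given(c=st.floats(1, 100), n=st.floats(1, 100))
    def test_passes_exactly_the_stated_rectangle(self, c, n):
        qc = collagen_qc(c, n)
        expected = (c >= 35 and 11 <= n <= 16 and 2.9 <= qc.atomic_cn_ratio <= 3.6)
        assert qc.passes == expected

    def test_boundaries_inclusive(self):
        # C:N of exactly 2.9 / 3.6 with in-range mass fractions passes
        n = 15.0
        for ratio in (2.9, 3.6):
            c = ratio * n * 12.011 / 14.007
            assert collagen_qc(c, n).passes

    def test_zero_nitrogen_rejected(self):
        with pytest.raises(ValueError):
            collagen_qc(44, 0)


class TestClassifyZone:
    @pytest.mark.parametrize("value, zone", [
        (-13.46, "highland"),   # lowest-numbered packaged burial
        (-8.0, "lowland"),      # boundary: strict inequality
        (-5.0, "lowland"),      # typical low-elevation surface water
    ])
    def test_examples(self, value, zone):
        assert classify_zone(value) == zone

    @settings(derandomize=True, max_examples=100)
    @given(v=finite_permil, delta=st.floats(0.001, 10))
    def test_monotone_lowering_never_unflips_highland(self, v, delta):
        if classify_zone(v) == "highland":
            assert classify_zone(v - delta) == "highland"


def _ks_oracle(a, b):
    """Brute-force sup-distance between the two ECDFs."""
    a, b = np.sort(a), np.sort(b)
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


class TestKSTwoSample:
    def test_identical_samples_give_zero(self):
        d, p = ks_two_sample([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert d == 0.0

    def test_disjoint_supports_give_one(self):
        d, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_interleaved_half(self):
        d, _ = ks_two_sample([1, 2], [1.5, 2.5])
        assert d == pytest.approx(0.5)

    def test_agrees_with_bruteforce_ecdf_oracle(self, rng):
        for _ in range(50):
            na, nb = rng.integers(1, 21, 2)
            a = rng.normal(0, 1, na)
            b = rng.normal(rng.uniform(-1, 1), 1, nb)
            d, p = ks_two_sample(a, b)
            assert d == pytest.approx(_ks_oracle(a, b), abs=1e-12)
            assert 0.0 <= d <= 1.0 and 0.0 <= p <= 1.0

    def test_symmetric_in_arguments(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 2, 13)
        assert ks_two_sample(a, b) == pytest.approx(ks_two_sample(b, a))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestEvaluateIsotopeHypothesis:
    def test_burials_inside_permanent_window(self, burials):
        rec = evaluate_isotope_hypothesis(burials, expectations("table2"), "d18O")
        assert rec.per_model["permanent"] is True
        assert rec.detail["fraction_inside"]["permanent"] == 1.0
        assert rec.detail["n"] == 16

    def test_burials_outside_logistical_window(self, burials):
        rec = evaluate_isotope_hypothesis(burials, expectations("table2"), "d18O")
        assert rec.per_model["logistical"] is False
        assert rec.detail["fraction_inside"]["logistical"] == 0.0

    def test_window_excluding_all_samples_unsupported(self, burials):
        m = ModelExpectation("permanent", (40.0, 41.0), (40.0, 41.0),
                             "full_spectrum", None, "absent")
        rec = evaluate_isotope_hypothesis(burials, [m], "d18O")
        assert rec.per_model["permanent"] is False

    def test_missing_values_listed_not_dropped(self):
        samples = [IsotopeSample("a", d18O_mw_vsmow=-15.0),
                   IsotopeSample("b")]
        rec = evaluate_isotope_hypothesis(samples, expectations(), "d18O")
        assert rec.detail["missing"] == ["b"]
        assert rec.detail["n"] == 1

    def test_no_values_is_indeterminate(self):
        rec = evaluate_isotope_hypothesis([IsotopeSample("a")], expectations(), "d13C")
        assert all(v is None for v in rec.per_model.values())
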