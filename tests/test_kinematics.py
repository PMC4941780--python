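"""Frequency allometries: prediction, OLS/PIC fitting, calibration."""

import math

import dendropy
import numpy as np
import pytest

import protowing as pw
from protowing.kinematics import (
    FrequencyModel,
    InsufficientDataError,
    invert_frequency,
)
from protowing.synthetic import GeneratorSpec, generate_frequency_dataset


def brute_force_contrasts(newick: str, values: dict[str, tuple[float, float]]):
    """Independent-contrasts oracle: explicit postorder recursion."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    contrasts = []

    def visit(node):
        # returns (x, y, extra_branch_length)
        if node.is_leaf():
            x, y = values[node.taxon.label]
            return x, y, node.edge.length or 0.0
        (x1, y1, v1), (x2, y2, v2) = [visit(c) for c in node.child_nodes()]
        sd = math.sqrt(v1 + v2)
        contrasts.append(((x1 - x2) / sd, (y1 - y2) / sd))
        x = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
        y = (y1 / v1 + y2 / v2) / (1 / v1 + 1 / v2)
        extra = v1 * v2 / (v1 + v2)
        return x, y, (node.edge.length or 0.0) + extra

    visit(tree.seed_node)
    return contrasts


class TestPredictFrequency:
    def test_zero_slope_is_constant(self):
        m = FrequencyModel("c", intercept=1.0, slope=0.0)
        assert pw.predict_frequency(m, 0.01) == pw.predict_frequency(m, 100) == 10.0

    def test_log_linearity(self):
        m = FrequencyModel("m", intercept=1.0, slope=-1 / 3)
        ratio = pw.predict_frequency(m, 5.0) / pw.predict_frequency(m, 0.5)
        assert ratio == pytest.approx(10 ** (-1 / 3))

    def test_nonpositive_mass_rejected(self):
        m = FrequencyModel("m", intercept=1.0, slope=-0.3)
        with pytest.raises(ValueError):
            pw.predict_frequency(m, 0.0)

    def test_positive_slope_warns(self):
        with pytest.warns(UserWarning, match="positive mass slope"):
            FrequencyModel("w", intercept=1.0, slope=0.2)


class TestFitFrequencyOLS:
    def test_exact_recovery_on_noise_free_line(self):
        masses = np.logspace(-2, 1, 20)
        data = [(m, 10 ** (0.8 - 0.31 * math.log10(m))) for m in masses]
        fit = pw.fit_frequency_ols(data)
        assert fit.slope == pytest.approx(-0.31, abs=1e-10)
        assert fit.intercept == pytest.approx(0.8, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_idempotence_of_predict_then_fit(self):
        m0 = FrequencyModel("m", intercept=0.9, slope=-0.25)
        masses = np.logspace(-1.5, 1, 15)
        refit = pw.fit_frequency_ols([(m, pw.predict_frequency(m0, m)) for m in masses])
        assert refit.slope == pytest.approx(m0.slope, abs=1e-12)
        assert refit.intercept == pytest.approx(m0.intercept, abs=1e-12)

    def test_duplicate_masses_still_well_posed(self):
        fit = pw.fit_frequency_ols([(1.0, 9.0), (1.0, 11.0), (2.0, 8.0), (4.0, 6.0)])
        assert math.isfinite(fit.slope)
        assert fit.r_squared < 1.0

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            pw.fit_frequency_ols([(1.0, 10.0), (2.0, 8.0)])

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            pw.fit_frequency_ols([(1.0, 10.0), (2.0, -8.0), (3.0, 7.0)])


class TestFitFrequencyPIC:
    def test_two_tip_closed_form(self):
        # a single contrast: slope = (y1-y2)/(x1-x2), branch lengths cancel
        tree = dendropy.Tree.get(data="(A:1.0,B:2.0);", schema="newick")
        data = [("A", 0.1, 12.0), ("B", 1.0, 8.0)]
        fit = pw.fit_frequency_pic(data, tree)
        expect = (math.log10(12) - math.log10(8)) / (math.log10(0.1) - math.log10(1.0))
        assert fit.slope == pytest.approx(expect, rel=1e-9)

    def test_star_tree_equals_centered_origin_ols(self):
        # equal-branch star: contrasts-based slope equals origin regression of
        # centered tip values (computed with the brute-force oracle)
        rng = np.random.default_rng(7)
        n = 6
        masses = 10 ** rng.uniform(-1, 1, n)
        freqs = 10 ** (1.0 - 0.3 * np.log10(masses) + rng.normal(0, 0.05, n))
        # dendropy requires bifurcating trees for PIC; use the oracle on a
        # caterpillar with tiny internal branches approximating a star
        labels = [f"s{i}" for i in range(n)]
        eps = 1e-9
        newick = f"({labels[0]}:1,{labels[1]}:1)"
        for lab in labels[2:]:
            newick = f"({newick}:{eps},{lab}:1)"
        newick += ";"
        values = {
            lab: (math.log10(m), math.log10(f))
            for lab, m, f in zip(labels, masses, freqs)
        }
        contrasts = brute_force_contrasts(newick, values)
        x = np.array([c[0] for c in contrasts])
        y = np.array([c[1] for c in contrasts])
        slope_pic = float(np.sum(x * y) / np.sum(x * x))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        fit = pw.fit_frequency_pic(
            [(lab, m, f) for lab, m, f in zip(labels, masses, freqs)], tree
        )
        assert fit.slope == pytest.approx(slope_pic, rel=1e-6)
        # Helmert-transform identity: contrasts on a star reduce to the
        # origin regression of centered tip values
        xc = np.log10(masses) - np.log10(masses).mean()
        yc = np.log10(freqs) - np.log10(freqs).mean()
        slope_centered = float(np.sum(xc * yc) / np.sum(xc * xc))
        assert fit.slope == pytest.approx(slope_centered, rel=1e-4)

    def test_matches_brute_force_oracle_on_random_tree(self):
        spec = GeneratorSpec(seed=11, n_tips=12, noise_sd=0.08)
        tree, rows = generate_frequency_dataset(spec)
        newick = tree.as_string(schema="newick")
        values = {t: (math.log10(m), math.log10(f)) for t, m, f in rows}
        contrasts = brute_force_contrasts(newick, values)
        x = np.array([c[0] for c in contrasts])
        y = np.array([c[1] for c in contrasts])
        # contrast signs are orientation-dependent; compare origin-slopes
        expect = float(np.sum(x * y) / np.sum(x * x))
        fit = pw.fit_frequency_pic(rows, tree)
        assert fit.slope == pytest.approx(expect, rel=1e-6)

    def test_noise_free_line_recovered_exactly(self):
        tree, rows = generate_frequency_dataset(
            GeneratorSpec(seed=3, n_tips=16, noise_sd=0.0, true_slope=-0.3, true_intercept=1.0)
        )
        fit = pw.fit_frequency_pic(rows, tree)
        assert fit.slope == pytest.approx(-0.3, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)

    def test_missing_tip_lists_names(self):
        tree, rows = generate_frequency_dataset(GeneratorSpec(seed=3, n_tips=8))
        rows = rows + [("ghost", 1.0, 10.0)]
        with pytest.raises(ValueError, match="ghost"):
            pw.fit_frequency_pic(rows, tree)


class TestEffectiveAirspeed:
    def test_no_flapping_gives_body_speed(self):
        assert pw.effective_airspeed(0.0, 1.5708, 0.24, 1.5) == 1.5

    def test_hand_check(self):
        assert pw.effective_airspeed(12.3, 1.5708, 0.24, 1.5) == pytest.approx(6.137, abs=2e-3)

    def test_linearity_in_each_argument(self):
        base = pw.effective_airspeed(10, 1.0, 0.3, 1.0)
        assert pw.effective_airspeed(20, 1.0, 0.3, 1.0) - 1.0 == pytest.approx(2 * (base - 1.0))
        assert pw.effective_airspeed(10, 2.0, 0.3, 1.0) - 1.0 == pytest.approx(2 * (base - 1.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pw.effective_airspeed(-1.0, 1.0, 0.3, 1.0)


class TestCalibration:
    def test_mod_frequency_at_microraptor_mass(self, calibrated_models):
        # inversion of the PH881 reference cell implies ~12.3 Hz at 0.17 kg
        f = pw.predict_frequency(calibrated_models["MOD"], 0.17)
        assert f == pytest.approx(12.3, abs=0.5)

    def test_implied_frequency_inversion_example(self, microraptor_ph881):
        r = microraptor_ph881
        f = invert_frequency(0.50, r.mass_kg, r.best_area_m2, r.wing_length_m,
                             math.pi / 2, 1.5)
        assert f == pytest.approx(12.28, abs=0.05)

    def test_all_slopes_negative(self, calibrated_models):
        assert all(m.slope < 0 for m in calibrated_models.values())

    def test_provenance_and_labels(self, calibrated_models):
        assert set(calibrated_models) == {"ALL", "GF", "MOD"}
        assert all(m.provenance == "calibrated" for m in calibrated_models.values())

    def test_zero_cells_excluded(self, specimens, reference_bw, calibrated_models):
        n_cells = (reference_bw.df[list(reference_bw.BW_COLUMNS)] > 0).sum().sum()
        fitted = sum(m.n_points for m in calibrated_models.values())
        assert fitted < n_cells  # zero bw cells and flagged rows dropped

    def test_calibration_needs_enough_cells(self, specimens, reference_bw):
        tiny = reference_bw.df.head(2).copy()
        with pytest.raises(InsufficientDataError):
            pw.calibrate_from_reference(specimens, pw.ReferenceBWTable(tiny))
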