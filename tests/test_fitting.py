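"""Parameter estimation: MM fits, fold changes, cascade fits, NNK sizing."""

import numpy as np
import pytest

import apkpath as ap


# ---------------------------------------------------------------------
# Michaelis-Menten initial-rate fits
# ---------------------------------------------------------------------

def test_noiseless_mm_fit_recovers_truth_exactly():
    assay = ap.gen_mm_assay(true_kcat=15.0, true_km=0.1, noise=ap.NO_NOISE)
    fit = ap.fit_michaelis_menten(assay)
    assert fit.converged and not fit.unreliable
    assert fit.kcat == pytest.approx(15.0, rel=1e-6)
    assert fit.km == pytest.approx(0.1, rel=1e-6)


def test_mm_fit_accuracy_across_one_hundred_noise_seeds():
    # Km chosen inside the assay grid so both parameters are identifiable
    errs_kcat, errs_km = [], []
    for seed in range(100):
        assay = ap.gen_mm_assay(
            true_kcat=15.0,
            true_km=5.0,
            noise=ap.NoiseModel(kind="multiplicative_gaussian", cv=0.05, seed=seed),
        )
        fit = ap.fit_michaelis_menten(assay)
        assert fit.converged
        errs_kcat.append(abs(fit.kcat / 15.0 - 1.0))
        errs_km.append(abs(fit.km / 5.0 - 1.0))
    assert np.median(errs_kcat) <= 0.15
    assert np.median(errs_km) <= 0.15


def test_mm_fit_flags_too_few_distinct_concentrations():
    assay = ap.gen_mm_assay(
        true_kcat=15.0, true_km=0.1, grid=[1.0, 5.0, 25.0], noise=ap.NO_NOISE
    )
    fit = ap.fit_michaelis_menten(assay)
    assert fit.unreliable
    assert any("distinct" in r for r in fit.reasons)


def test_mm_fit_flags_km_beyond_the_assay_range():
    # true Km 10x above the highest concentration: extrapolated, flagged
    assay = ap.gen_mm_assay(true_kcat=15.0, true_km=5000.0, noise=ap.NO_NOISE)
    fit = ap.fit_michaelis_menten(assay)
    assert fit.unreliable
    assert any("range" in r.lower() or "km" in r.lower() for r in fit.reasons)


def test_mm_fit_flags_all_zero_rates():
    assay = ap.gen_mm_assay(true_kcat=0.0, true_km=1.0, noise=ap.NO_NOISE)
    fit = ap.fit_michaelis_menten(assay)
    assert fit.unreliable


def test_mm_fit_confidence_intervals_bracket_truth_without_noise():
    assay = ap.gen_mm_assay(true_kcat=8.0, true_km=2.0, noise=ap.NO_NOISE)
    fit = ap.fit_michaelis_menten(assay)
    lo, hi = fit.kcat_ci
    assert lo <= 8.0 * (1 + 1e-9) and hi >= 8.0 * (1 - 1e-9)
    lo, hi = fit.km_ci
    assert lo <= 2.0 * (1 + 1e-9) and hi >= 2.0 * (1 - 1e-9)


# ---------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------

def test_efficiency_fold_change_simple_values():
    a = ap.gen_mm_assay(true_kcat=10.0, true_km=1.0, noise=ap.NO_NOISE)
    b = ap.gen_mm_assay(true_kcat=23.0, true_km=1.0, noise=ap.NO_NOISE)
    fold = ap.efficiency_fold_change(
        ap.fit_michaelis_menten(b), ap.fit_michaelis_menten(a)
    )
    assert float(fold) == pytest.approx(2.3, rel=1e-5)


def test_efficiency_fold_change_invariant_to_shared_scaling():
    # doubling kcat and Km together leaves kcat/Km unchanged
    a = ap.gen_mm_assay(true_kcat=10.0, true_km=1.0, noise=ap.NO_NOISE)
    b = ap.gen_mm_assay(true_kcat=20.0, true_km=2.0, noise=ap.NO_NOISE)
    fold = ap.efficiency_fold_change(
        ap.fit_michaelis_menten(b), ap.fit_michaelis_menten(a)
    )
    assert float(fold) == pytest.approx(1.0, rel=1e-5)


def test_fold_change_carries_unreliability_forward():
    good = ap.fit_michaelis_menten(
        ap.gen_mm_assay(true_kcat=10.0, true_km=1.0, noise=ap.NO_NOISE)
    )
    bad = ap.fit_michaelis_menten(
        ap.gen_mm_assay(true_kcat=10.0, true_km=5000.0, noise=ap.NO_NOISE)
    )
    fold = ap.efficiency_fold_change(bad, good)
    assert not fold.reliable


# ---------------------------------------------------------------------
# Cascade fits
# ---------------------------------------------------------------------

def test_cascade_fit_recovers_kcats_from_noiseless_timecourse(f6p_design, params):
    truth = params
    start = truth.with_constants(
        "BbPK", "GALD", kcat=truth.get("BbPK", "GALD").kcat * 3.0
    ).with_constants("BbPK", "D-EUS", kcat=truth.get("BbPK", "D-EUS").kcat / 3.0)
    ds = ap.simulate(f6p_design, truth, {"F6P": 10.0})
    result = ap.fit_cascade(
        f6p_design,
        start,
        [ds],
        [("BbPK", "GALD", "kcat"), ("BbPK", "D-EUS", "kcat")],
        n_starts=3,
    )
    assert result.converged
    fitted = result.params
    for enzyme, substrate in (("BbPK", "GALD"), ("BbPK", "D-EUS")):
        assert fitted.get(enzyme, substrate).kcat == pytest.approx(
            truth.get(enzyme, substrate).kcat, rel=1e-2
        )


def test_cascade_fit_tolerates_measurement_noise(f6p_design, params):
    ds = ap.gen_timecourse(
        f6p_design,
        params,
        {"F6P": 10.0},
        noise=ap.NoiseModel(kind="multiplicative_gaussian", cv=0.05, seed=11),
    )
    result = ap.fit_cascade(
        f6p_design,
        params.with_constants(
            "BbPK", "GALD", kcat=params.get("BbPK", "GALD").kcat * 2.0
        ),
        [ds],
        [("BbPK", "GALD", "kcat")],
        n_starts=3,
    )
    assert result.converged
    assert result.params.get("BbPK", "GALD").kcat == pytest.approx(
        params.get("BbPK", "GALD").kcat, rel=0.25
    )


def test_cascade_fit_flags_parameter_the_data_cannot_constrain(f6p_design, params):
    # L-EUS never appears on the F6P route, so its kcat is unidentifiable
    ds = ap.simulate(f6p_design, params, {"F6P": 10.0})
    result = ap.fit_cascade(
        f6p_design,
        params,
        [ds],
        [("BbPK", "L-EUS", "kcat")],
        n_starts=2,
    )
    assert ("BbPK", "L-EUS", "kcat") in result.nonidentifiable


def test_cascade_fit_with_no_free_parameters_is_trivial(f6p_design, params):
    ds = ap.simulate(f6p_design, params, {"F6P": 10.0})
    result = ap.fit_cascade(f6p_design, params, [ds], [])
    assert result.converged and result.cost == 0.0 and result.estimates == {}


# ---------------------------------------------------------------------
# NNK library sizing
# ---------------------------------------------------------------------

def test_nnk_screen_size_worked_example():
    size = ap.nnk_screen_size(sites=34, coverage=0.95)
    assert size.raw_clones == 95
    assert size.clones_per_library == 96
    assert size.total_clones == 3264


def test_nnk_screen_size_other_example():
    assert ap.nnk_screen_size(sites=40, coverage=0.95).total_clones == 3840


def test_nnk_residue_mode_uses_twenty_outcomes():
    codon = ap.nnk_screen_size(sites=1, coverage=0.95, mode="codon")
    residue = ap.nnk_screen_size(sites=1, coverage=0.95, mode="residue")
    # 32 codons cover 20 residues, so codon-level coverage needs more clones
    assert residue.raw_clones < codon.raw_clones


def test_nnk_clone_count_monotone_in_coverage():
    sizes = [ap.nnk_screen_size(34, c).raw_clones for c in (0.5, 0.9, 0.95, 0.99)]
    assert sizes == sorted(sizes) and len(set(sizes)) == 4


def test_nnk_totals_scale_linearly_with_sites():
    one = ap.nnk_screen_size(1, 0.95)
    ten = ap.nnk_screen_size(10, 0.95)
    assert ten.total_clones == 10 * one.clones_per_library


def test_nnk_rejects_invalid_inputs():
    with pytest.raises(ValueError):
        ap.nnk_screen_size(0, 0.95)
    with pytest.raises(ValueError):
        ap.nnk_screen_size(34, 1.0)
    with pytest.raises(ValueError):
        ap.nnk_screen_size(34, -0.1)
    with pytest.raises(ValueError):
        ap.nnk_screen_size(34, 0.95, mode="protein")
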