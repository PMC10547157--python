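"""Cascade ODE simulation: rate laws, conservation, convergence to stoichiometry."""

import numpy as np
import pytest

import apkpath as ap
from apkpath.kinetics import EnzymeLoad, RateConstants

BUNDLED_SOURCES = {
    "F6P": {"F6P": 10.0},
    "Xu5P": {"Xu5P": 10.0},
    "DHA": {"DHA": 10.0},
    "D-EUS": {"D-EUS": 5.0},
    "GALD": {"GALD": 10.0},
    "HCHO": {"HCHO": 20.0},
}


def total_carbon(dataset, registry):
    w = np.array([registry.n_carbons(s) for s in dataset.species], float)
    return w @ dataset.conc


# ---------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------

def test_single_substrate_rate_saturates_at_kcat_e(params, f6p_design):
    vmax = params.vmax("BbPK", "F6P")  # kcat * E * 3600, in mM/h
    rates = ap.rate_vector(f6p_design, params, {"F6P": 1e7})
    assert rates["BbPK:F6P"] == pytest.approx(vmax, rel=1e-5)


def test_all_rates_vanish_at_zero_concentration(params, xu5p_design):
    rates = ap.rate_vector(xu5p_design, params, {})
    assert all(v == 0.0 for v in rates.values())


def test_competing_substrates_at_equal_conc_and_km_split_by_kcat(params, f6p_design):
    # give D-EUS and GALD a common Km so the shared-site law splits the
    # enzyme exactly by kcat
    p = params.with_constants("BbPK", "D-EUS", km=20.0).with_constants(
        "BbPK", "GALD", km=20.0
    )
    rates = ap.rate_vector(f6p_design, p, {"D-EUS": 8.0, "GALD": 8.0})
    kcat_ratio = p.get("BbPK", "D-EUS").kcat / p.get("BbPK", "GALD").kcat
    assert rates["BbPK:D-EUS"] / rates["BbPK:GALD"] == pytest.approx(kcat_ratio)


def test_competitive_law_approaches_independent_first_order(params, f6p_design):
    # Km -> inf at fixed kcat/Km: competition vanishes
    y = {"F6P": 3.0, "D-EUS": 5.0, "GALD": 7.0}
    scale = 1e6
    p = params
    for sub in ("F6P", "D-EUS", "GALD"):
        rc = params.get("BbPK", sub)
        p = p.with_constants("BbPK", sub, km=rc.km * scale, kcat=rc.kcat * scale)
    competitive = ap.rate_vector(f6p_design, p, y)
    independent = ap.rate_vector(
        f6p_design,
        type(p)(p.enzymes, p.constants, rate_law="independent"),
        y,
    )
    for rid in ("BbPK:F6P", "BbPK:D-EUS", "BbPK:GALD"):
        assert competitive[rid] == pytest.approx(independent[rid], rel=1e-5)


def test_reversible_isomerase_rests_at_equilibrium(params, f6p_design):
    rc = params.get("Ps-LRhI", "D-ETS")
    # at [ketose]/[aldose] = Keq the net rate is zero
    rates = ap.rate_vector(f6p_design, params, {"D-ETS": 1.0, "D-EUS": rc.keq})
    assert rates["Ps-LRhI:D-ETS"] == pytest.approx(0.0, abs=1e-12)


def test_missing_parameter_error_names_the_pair(f6p_design, params):
    broken = ap.KineticParameterSet(
        enzymes=params.enzymes,
        constants={k: v for k, v in params.constants.items() if k != ("BbPK", "GALD")},
    )
    with pytest.raises(ap.MissingParameterError, match="GALD"):
        ap.make_rate_function(f6p_design, broken)


def test_parameter_invariants():
    with pytest.raises(ValueError):
        RateConstants(km=-1.0, kcat=1.0)
    with pytest.raises(ValueError):
        RateConstants(km=1.0)  # no parameterization chosen
    with pytest.raises(ValueError):
        RateConstants(km=1.0, kcat=1.0, specific_activity=1.0)  # both modes
    with pytest.raises(ValueError):
        EnzymeLoad(loading=1.0, molar_mass=-5.0)


def test_specific_activity_parameterization_matches_kcat():
    # 1 umol/min/mg at 2 mg/mL = 2 mM/min = 120 mM/h saturating rate
    p = ap.KineticParameterSet(
        enzymes={"E": EnzymeLoad(2.0)},
        constants={("E", "S"): RateConstants(km=1.0, specific_activity=1.0)},
    )
    assert p.vmax("E", "S") == pytest.approx(120.0)


# ---------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------

def test_zero_enzyme_loadings_freeze_the_state(f6p_design, params):
    p = params
    for enzyme in p.enzymes:
        p = p.with_loading(enzyme, 0.0)
    ds = ap.simulate(f6p_design, p, {"F6P": 10.0})
    assert np.allclose(ds["F6P"], 10.0)
    assert np.allclose(ds["AcP"], 0.0)


@pytest.mark.parametrize("source", sorted(BUNDLED_SOURCES))
def test_carbon_conservation_over_ten_hours(registry, params, source):
    design = ap.generate(source, "fls")
    ds = ap.simulate(design, params, BUNDLED_SOURCES[source])
    tot = total_carbon(ds, registry)
    assert np.max(np.abs(tot / tot[0] - 1.0)) < 1e-6


@pytest.mark.parametrize("source", sorted(BUNDLED_SOURCES))
def test_ac_pool_is_monotone_nondecreasing(params, source):
    design = ap.generate(source, "fls")
    ds = ap.simulate(design, params, BUNDLED_SOURCES[source])
    assert np.all(np.diff(ds["AcP"]) >= -1e-9)


@pytest.mark.parametrize("source", sorted(BUNDLED_SOURCES))
def test_long_horizon_yield_matches_stoichiometry(params, source):
    design = ap.generate(source, "fls")
    ds = ap.simulate(
        design, params, BUNDLED_SOURCES[source], horizon=200.0, grid=[0.0, 100.0, 200.0]
    )
    theory = float(ap.theoretical_yield(source, "fls"))
    assert ap.final_yield(ds) == pytest.approx(theory, abs=1e-3)


def test_formaldehyde_stays_well_below_feed_scale(xu5p_timecourse):
    # the condensation keeps free HCHO far below the 10 mM feed
    assert xu5p_timecourse["HCHO"].max() < 1.0


def test_default_grid_is_two_hour_sampling(f6p_timecourse):
    assert np.allclose(f6p_timecourse.time, [0, 2, 4, 6, 8, 10])


def test_simulate_rejects_bad_initial_conditions(f6p_design, params):
    with pytest.raises(ValueError, match="outside design"):
        ap.simulate(f6p_design, params, {"Xu5P": 10.0})
    with pytest.raises(ValueError, match="nonnegative"):
        ap.simulate(f6p_design, params, {"F6P": -1.0})


def test_timecourse_dataset_invariants():
    with pytest.raises(ValueError, match="strictly increasing"):
        ap.TimecourseDataset(
            time=[0.0, 0.0], species=("A",), conc=[[1.0, 1.0]]
        )
    with pytest.raises(ValueError, match="nonnegative"):
        ap.TimecourseDataset(
            time=[0.0, 1.0], species=("A",), conc=[[1.0, -1.0]]
        )


# ---------------------------------------------------------------------
# Pools and carbon abundance
# ---------------------------------------------------------------------

def test_default_pools_group_by_carbon_count(f6p_design, xu5p_design):
    pools = ap.default_pools(f6p_design).pools
    assert pools["F6P"] == {"F6P"}
    assert pools["Ac"] == {"AcP"}
    assert pools["C4"] == {"E4P", "D-ETS", "D-EUS"}
    assert pools["C2"] == {"GALD"}
    xpools = ap.default_pools(xu5p_design).pools
    assert xpools["C3"] == {"G3P", "DHAP", "DHA"}
    assert xpools["C1"] == {"HCHO"}


def test_initial_abundance_sits_entirely_in_the_source_pool(f6p_timecourse, f6p_design):
    frame = ap.carbon_abundance(f6p_timecourse, ap.default_pools(f6p_design))
    assert frame.loc["F6P"].iloc[0] == pytest.approx(1.0)
    assert frame.drop("F6P").iloc[:, 0].abs().max() == 0.0


def test_pool_fractions_sum_to_one_throughout(f6p_timecourse, f6p_design):
    frame = ap.carbon_abundance(f6p_timecourse, ap.default_pools(f6p_design))
    assert np.allclose(frame.sum(axis=0), 1.0, atol=1e-6)


def test_final_ac_fraction_equals_final_yield(f6p_timecourse, f6p_design):
    frame = ap.carbon_abundance(f6p_timecourse, ap.default_pools(f6p_design))
    assert frame.loc["Ac"].iloc[-1] == pytest.approx(ap.final_yield(f6p_timecourse))


def test_overlapping_pools_rejected():
    with pytest.raises(ValueError, match="overlaps"):
        ap.PoolGrouping({"a": {"X"}, "b": {"X", "Y"}})


def test_pool_with_unknown_species_rejected(f6p_timecourse):
    with pytest.raises(ValueError, match="unknown species"):
        ap.carbon_abundance(
            f6p_timecourse, ap.PoolGrouping({"Ac": {"AcP", "pyruvate"}})
        )


# ---------------------------------------------------------------------
# Mutant parameter sets
# ---------------------------------------------------------------------

@pytest.mark.parametrize(
    "mutant,substrate,fold",
    [("E520I", "DHA", 2.3), ("Q321A", "DHA", 5.0), ("H142N", "GALD", 8.5),
     ("H142N", "D-EUS", 3.6)],
)
def test_mutant_sets_encode_reported_efficiency_folds(params, mutant, substrate, fold):
    mut = ap.mutant_parameters(mutant)
    wt_eff = params.get("BbPK", substrate).kcat / params.get("BbPK", substrate).km
    mut_eff = mut.get("BbPK", substrate).kcat / mut.get("BbPK", substrate).km
    assert mut_eff / wt_eff == pytest.approx(fold)


def test_default_parameters_bind_dha_tighter_than_gald(params):
    assert params.get("BbPK", "DHA").km < params.get("BbPK", "GALD").km
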