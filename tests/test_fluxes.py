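import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from factoromics.fluxes import (
    FluxSamples,
    MetabolicModel,
    apply_condition_constraints,
    calibrate_ngam,
    flux_zscores,
    gpr_genes,
    regulation_scores,
    resolve_gpr,
    sample_fluxes,
)


def _rxn(rid, stoich, lb=0.0, ub=1000.0, **kw):
    return {"id": rid, "metabolites": stoich, "lower_bound": lb, "upper_bound": ub, **kw}


def _chain_model(conv_ub=1000.0):
    """glucose (fixed uptake 1) -> ATP -> NGAM, 1:1 yields."""
    return MetabolicModel(
        metabolites=["glc", "atp"],
        reactions=[
            _rxn("EX_glc", {"glc": -1}, lb=-1.0, ub=-1.0, exchange=True, direction="uptake"),
            _rxn("CONV", {"glc": -1, "atp": 1}, ub=conv_ub),
            _rxn("NGAM", {"atp": -1}),
        ],
        biomass="CONV",
        ngam="NGAM",
    )


def _interval_model(lo=0.0, hi=1.0):
    """Single pass-through metabolite: flux uniform on [lo, hi]."""
    return MetabolicModel(
        metabolites=["A"],
        reactions=[
            _rxn("R_in", {"A": 1}, lb=lo, ub=hi),
            _rxn("R_out", {"A": -1}, lb=lo, ub=hi),
        ],
        biomass="R_out",
        ngam="R_out",
    )


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


def test_model_invariants_enforced():
    with pytest.raises(ValueError, match="unknown metabolites"):
        MetabolicModel(["a"], [_rxn("r", {"b": 1})], biomass="r", ngam="r")
    with pytest.raises(ValueError, match="lower bound exceeds"):
        MetabolicModel(["a"], [_rxn("r", {"a": 1}, lb=2, ub=1)], biomass="r", ngam="r")
    with pytest.raises(ValueError, match="invalid gene ID"):
        MetabolicModel(["a"], [_rxn("r", {"a": 1}, gpr="1bad gene")], biomass="r", ngam="r")


def test_model_json_round_trip(bundle, tmp_path):
    path = tmp_path / "model.json"
    bundle.model.to_json(path)
    back = MetabolicModel.from_json(path)
    assert back.reactions == bundle.model.reactions
    assert back.metabolites == bundle.model.metabolites
    assert np.array_equal(back.stoichiometric_matrix(), bundle.model.stoichiometric_matrix())


def test_gpr_parsing_and_resolution():
    assert gpr_genes("(ga or gb) and gc") == ["ga", "gb", "gc"]
    z = {"ga": 1.0, "gb": 5.0, "gc": 3.0}
    # OR picks the strongest isoenzyme, AND the weakest complex member
    assert resolve_gpr("ga or gb", z) == "gb"
    assert resolve_gpr("ga and gb", z) == "ga"
    assert resolve_gpr("(ga or gb) and gc", z) == "gc"
    assert resolve_gpr("gmissing", z) is None


# ---------------------------------------------------------------------------
# condition constraints
# ---------------------------------------------------------------------------


def test_measured_exchanges_bounded_with_uptake_sign(bundle):
    phys = bundle.physiology.copy()
    phys.loc["WT-C", ["r_glc", "r_glc_sd"]] = [0.65, 0.01]
    model = apply_condition_constraints(bundle.model, phys, "WT-C")
    rxn = model.reaction("EX_glc")
    assert rxn["lower_bound"] == pytest.approx(-0.66)
    assert rxn["upper_bound"] == pytest.approx(-0.64)


def test_zero_sd_pins_exchanges(bundle):
    phys = bundle.physiology.copy()
    for col in phys.columns:
        if col.endswith("_sd"):
            phys[col] = 0.0
    model = apply_condition_constraints(bundle.model, phys, "WT-N")
    for ex in ("EX_glc", "EX_o2", "EX_co2", "EX_ipm"):
        rxn = model.reaction(ex)
        assert rxn["lower_bound"] == rxn["upper_bound"]


def test_biomass_composition_recomposed_per_condition(bundle):
    model = apply_condition_constraints(bundle.model, bundle.physiology, "DGA1-N")
    biomass = model.reaction("BIOMASS")
    assert biomass["metabolites"]["lipid"] == pytest.approx(-2.2)
    assert biomass["metabolites"]["prot"] == pytest.approx(-1.2)


def test_widening_sd_multiplier_relaxes_the_polytope(bundle):
    def probe_range(mult):
        model = apply_condition_constraints(bundle.model, bundle.physiology, "WT-N", mult)
        S = model.stoichiometric_matrix()
        lb, ub = model.bounds()
        j = model.reaction_ids.index("TCA")
        out = []
        for sense in (1.0, -1.0):
            c = np.zeros(len(lb))
            c[j] = sense
            res = optimize.linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)), method="highs")
            out.append(res.x[j])
        return out[0], out[1]  # (min, max)

    lo1, hi1 = probe_range(1.0)
    lo2, hi2 = probe_range(2.0)
    assert lo2 <= lo1 and hi2 >= hi1
    assert (hi2 - lo2) > (hi1 - lo1)


def test_infeasible_constraints_name_a_culprit(bundle):
    phys = bundle.physiology.copy()
    phys.loc["WT-N", ["r_glc", "r_glc_sd"]] = [0.01, 0.0]  # starves the network
    with pytest.raises(ValueError, match="infeasible"):
        apply_condition_constraints(bundle.model, phys, "WT-N")


# ---------------------------------------------------------------------------
# NGAM calibration
# ---------------------------------------------------------------------------


def test_ngam_bounds_from_hand_solvable_chain():
    out = calibrate_ngam(_chain_model())
    rxn = out.reaction("NGAM")
    assert rxn["upper_bound"] == pytest.approx(1.0, abs=1e-9)
    assert rxn["lower_bound"] == pytest.approx(0.95, abs=1e-9)


def test_ngam_maximum_matches_independent_lp_oracle():
    model = MetabolicModel(
        metabolites=["glc", "atp"],
        reactions=[
            _rxn("EX_glc", {"glc": -1}, lb=-1.0, ub=-1.0, exchange=True, direction="uptake"),
            _rxn("LOW", {"glc": -1, "atp": 1}),
            _rxn("HIGH", {"glc": -1, "atp": 2}, ub=0.4),
            _rxn("NGAM", {"atp": -1}),
        ],
        biomass="LOW",
        ngam="NGAM",
    )
    out = calibrate_ngam(model)
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    c = np.zeros(4)
    c[3] = -1.0
    oracle = optimize.linprog(c, A_eq=S, b_eq=np.zeros(2), bounds=list(zip(lb, ub)), method="highs")
    assert out.reaction("NGAM")["upper_bound"] == pytest.approx(-oracle.fun, abs=1e-9)
    assert -oracle.fun == pytest.approx(1.4, abs=1e-9)


def test_infeasible_model_raises_before_sampling():
    with pytest.raises(ValueError, match="infeasible"):
        calibrate_ngam(_chain_model(conv_ub=0.5))


# ---------------------------------------------------------------------------
# ACHR sampling
# ---------------------------------------------------------------------------


def test_uniform_interval_moments():
    samples = sample_fluxes(_interval_model(), n_draws=5000, seed=1, thinning=1)
    flux = samples.draws.loc["R_in"].to_numpy()
    assert abs(flux.mean() - 0.5) < 0.02
    assert abs(flux.var(ddof=1) - 1.0 / 12.0) < 0.005


def test_point_polytope_has_zero_spread():
    model = _interval_model()
    model.reaction("R_in")["lower_bound"] = 0.7
    model.reaction("R_in")["upper_bound"] = 0.7
    samples = sample_fluxes(model, n_draws=50, seed=2)
    assert np.allclose(samples.sd, 0.0)
    assert np.allclose(samples.mean, 0.7)


def test_draws_satisfy_mass_balance_and_bounds(bundle):
    model = calibrate_ngam(
        apply_condition_constraints(bundle.model, bundle.physiology, "WT-N")
    )
    samples = sample_fluxes(model, n_draws=1000, seed=3)
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    D = samples.draws.to_numpy()
    assert np.abs(S @ D).max() < 1e-9
    assert (D >= lb[:, None]).all() and (D <= ub[:, None]).all()


def test_sampling_is_deterministic(bundle):
    model = calibrate_ngam(
        apply_condition_constraints(bundle.model, bundle.physiology, "WT-C")
    )
    a = sample_fluxes(model, n_draws=200, seed=5)
    b = sample_fluxes(model, n_draws=200, seed=5)
    pd.testing.assert_frame_equal(a.draws, b.draws)


# ---------------------------------------------------------------------------
# flux Z-scores
# ---------------------------------------------------------------------------


def _samples_from(draws: np.ndarray, names) -> FluxSamples:
    return FluxSamples(pd.DataFrame(draws, index=names))


def test_identical_samples_give_zero_z(bundle):
    model = calibrate_ngam(
        apply_condition_constraints(bundle.model, bundle.physiology, "WT-C")
    )
    a = sample_fluxes(model, n_draws=200, seed=7)
    b = sample_fluxes(model, n_draws=200, seed=7)
    assert np.allclose(flux_zscores(a, b), 0.0)


def test_z_antisymmetry_exact():
    rng = np.random.default_rng(8)
    a = _samples_from(rng.normal(1.0, 0.1, (3, 500)), ["r1", "r2", "r3"])
    b = _samples_from(rng.normal(0.4, 0.1, (3, 500)), ["r1", "r2", "r3"])
    zab = flux_zscores(a, b)
    zba = flux_zscores(b, a)
    assert (zab == -zba).all()


def test_doubling_sds_halves_z():
    rng = np.random.default_rng(9)
    base = rng.normal(0.0, 0.05, (1, 2000))
    a = _samples_from(1.0 + base, ["r"])
    b = _samples_from(0.2 + base[:, ::-1], ["r"])
    wide_a = _samples_from(1.0 + 2 * base, ["r"])
    wide_b = _samples_from(0.2 + 2 * base[:, ::-1], ["r"])
    z = flux_zscores(a, b)["r"]
    z_wide = flux_zscores(wide_a, wide_b)["r"]
    assert z_wide == pytest.approx(z / 2.0, rel=1e-9)


def test_forced_branch_shift_produces_large_z():
    # branch flux forced from about 1.0 +/- 0.05 to 0.2 +/- 0.05
    rng = np.random.default_rng(10)
    a = _samples_from(rng.normal(1.0, 0.05, (1, 4000)), ["branch"])
    b = _samples_from(rng.normal(0.2, 0.05, (1, 4000)), ["branch"])
    z = flux_zscores(a, b)["branch"]
    assert z == pytest.approx(0.8 / np.sqrt(0.005), rel=0.1)
    assert z > 2


def test_reaction_mismatch_rejected():
    a = _samples_from(np.ones((1, 10)), ["r1"])
    b = _samples_from(np.ones((1, 10)), ["r2"])
    with pytest.raises(ValueError, match="reaction sets"):
        flux_zscores(a, b)


# ---------------------------------------------------------------------------
# regulation scores
# ---------------------------------------------------------------------------


def _pair_model(gpr="gene1"):
    return MetabolicModel(
        metabolites=["a"],
        reactions=[
            _rxn("R_in", {"a": 1}),
            _rxn("R", {"a": -1}, gpr=gpr),
        ],
        biomass="R",
        ngam="R",
    )


def test_concordant_down_pair_scores_the_weakest_level():
    model = _pair_model()
    table = regulation_scores(
        pd.Series({"R": -3.0, "R_in": 0.0}),
        pd.Series({"gene1": -4.0}),
        pd.Series({"gene1": -2.5}),
        model,
    )
    row = table.set_index(["reaction", "gene"]).loc[("R", "gene1")]
    assert row["score"] == pytest.approx(-2.5)
    assert bool(row["regulated"])


def test_sign_discordance_scores_zero():
    model = _pair_model()
    table = regulation_scores(
        pd.Series({"R": 3.0, "R_in": 0.0}),
        pd.Series({"gene1": -3.0}),
        pd.Series({"gene1": -3.0}),
        model,
    )
    row = table.set_index(["reaction", "gene"]).loc[("R", "gene1")]
    assert row["score"] == 0.0 and not row["regulated"]


def test_missing_gene_pairs_are_skipped():
    model = _pair_model(gpr="gene1 or gene2")
    table = regulation_scores(
        pd.Series({"R": -3.0, "R_in": 0.0}),
        pd.Series({"gene1": -4.0}),  # gene2 unscored
        pd.Series({"gene1": -2.0}),
        model,
    )
    assert set(table["gene"]) == {"gene1"}


def test_scores_equivariant_under_relabeling():
    model = _pair_model(gpr="gene1")
    flux_z = pd.Series({"R": -3.0, "R_in": 0.0})
    rna = pd.Series({"gene1": -4.0})
    prot = pd.Series({"gene1": -2.5})
    base = regulation_scores(flux_z, rna, prot, model)

    renamed = _pair_model(gpr="geneX")
    renamed.reactions[1]["id"] = "RX"
    table = regulation_scores(
        pd.Series({"RX": -3.0, "R_in": 0.0}),
        pd.Series({"geneX": -4.0}),
        pd.Series({"geneX": -2.5}),
        renamed,
    )
    assert table["score"].tolist() == base["score"].tolist()
    assert table["regulated"].tolist() == base["regulated"].tolist()


def test_gpr_representative_flags(bundle):
    model = _pair_model(gpr="ga and gb")
    table = regulation_scores(
        pd.Series({"R": -3.0, "R_in": 0.0}),
        pd.Series({"ga": -4.0, "gb": -1.0}),
        pd.Series({"ga": -3.0, "gb": -1.5}),
        model,
    ).set_index("gene")
    # AND complex: the weakest member (gb) represents the reaction
    assert bool(table.loc["gb", "gpr_representative"])
    assert not bool(table.loc["ga", "gpr_representative"])
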