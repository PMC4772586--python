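"""Path system: validation, enumeration, product effects, delta SEs, bootstrap."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dtmediate as dm
from dtmediate.path_mediation import CoefficientTable, Equation, OutcomeSpec

OUT = OutcomeSpec(name="hazard", J_max=6, baseline="constant")


def make_spec(equations, exposure="x"):
    return dm.PathModelSpec(exposure=exposure, equations=tuple(equations), outcome=OUT)


def test_validate_colon_system(colon_spec):
    assert dm.validate_spec(colon_spec) is colon_spec
    assert colon_spec.mediators == ("emergency", "caseload")
    assert set(colon_spec.exogenous()) >= {"affluence", "age10"}


@pytest.mark.parametrize(
    "equations,match",
    [
        ([Equation("m", ("x", "hazard")), Equation("hazard", ("x", "m"),
          "discrete_time_logit")], "outcome"),
        ([Equation("m", ("x", "m")), Equation("hazard", ("m",),
          "discrete_time_logit")], "self-loop"),
        ([Equation("a", ("b",)), Equation("b", ("a",)),
          Equation("hazard", ("a",), "discrete_time_logit")], "ordering|cyclic"),
        ([Equation("m", ("x",))], "discrete_time_logit"),
    ],
)
def test_validate_rejects_malformed_systems(equations, match):
    with pytest.raises(dm.SpecError, match=match):
        dm.validate_spec(make_spec(equations))


def test_spec_yaml_round_trip(tmp_path, colon_spec):
    import yaml

    cfg = {
        "exposure": "affluence",
        "outcome": {"time": "time", "event": "event", "J_max": 24,
                    "baseline": "constant", "proportional": True},
        "equations": [
            {"dependent": eq.dependent, "regressors": list(eq.regressors),
             "link": eq.link}
            for eq in colon_spec.equations
        ],
    }
    path = tmp_path / "model.yaml"
    path.write_text(yaml.safe_dump(cfg))
    spec = dm.spec_from_yaml(path)
    assert spec.equations == colon_spec.equations
    assert spec.exposure == "affluence"


def test_enumerate_paths_colon(colon_spec):
    paths = dm.enumerate_paths(colon_spec)
    assert paths == [
        ("affluence", "caseload", "hazard"),
        ("affluence", "emergency", "hazard"),
        ("affluence", "emergency", "caseload", "hazard"),
    ]


def test_enumerate_paths_edge_cases():
    single = make_spec(
        [Equation("m", ("x",)), Equation("hazard", ("x", "m"), "discrete_time_logit")]
    )
    assert dm.enumerate_paths(single) == [("x", "m", "hazard")]
    no_med = make_spec(
        [Equation("m", ("w",)), Equation("hazard", ("x", "m"), "discrete_time_logit")]
    )
    assert dm.enumerate_paths(no_med) == []


def test_path_count_matches_dfs_on_random_dags():
    """Enumeration equals a brute-force DFS count on random recursive systems."""
    rng = np.random.default_rng(77)
    for _ in range(25):
        k = rng.integers(2, 7)  # mediators m0..m{k-1}, plus exposure + outcome
        nodes = ["x"] + [f"m{i}" for i in range(k)]
        equations = []
        for i, dep in enumerate(nodes[1:], start=1):
            parents = [nodes[j] for j in range(i) if rng.random() < 0.5]
            equations.append(Equation(dep, tuple(parents) or ("x",)))
        hazard_parents = tuple(
            n for n in nodes if n == "x" or rng.random() < 0.6
        )
        equations.append(Equation("hazard", hazard_parents, "discrete_time_logit"))
        spec = make_spec(equations)
        got = dm.enumerate_paths(spec)

        g = spec.graph()

        def dfs(node, target, seen):
            if node == target:
                return [[node]]
            out = []
            for nxt in g.successors(node):
                if nxt not in seen:
                    out.extend(
                        [[node] + p for p in dfs(nxt, target, seen | {nxt})]
                    )
            return out

        brute = [tuple(p) for p in dfs("x", "hazard", {"x"}) if len(p) >= 3]
        assert sorted(got) == sorted(brute)
        assert got == sorted(got, key=lambda p: (len(p), p))


def coef_table(rows):
    return CoefficientTable(
        pd.DataFrame(rows, columns=["equation", "regressor", "estimate", "se"])
    )


def test_indirect_effect_products(colon_coefficients):
    two = dm.indirect_effect(
        ("affluence", "emergency", "hazard"), colon_coefficients
    )
    assert two == pytest.approx(-0.302 * 0.411, abs=1e-12)
    three = dm.indirect_effect(
        ("affluence", "emergency", "caseload", "hazard"), colon_coefficients
    )
    assert three == pytest.approx(-0.302 * -0.063 * -0.173, abs=1e-12)
    tab = coef_table(
        [("m", "x", 0.0, 0.1), ("hazard", "m", 0.7, 0.1), ("hazard", "x", 0.2, 0.1)]
    )
    assert dm.indirect_effect(("x", "m", "hazard"), tab) == 0.0
    with pytest.raises(KeyError, match="absent"):
        dm.indirect_effect(("x", "absent", "hazard"), colon_coefficients)


def test_delta_se_closed_form(colon_coefficients):
    """Two-edge delta SE equals sqrt(b^2 SEa^2 + a^2 SEb^2); matches the
    published worked-example SEs to 3 decimals."""
    se1 = dm.delta_se(("affluence", "emergency", "hazard"), colon_coefficients)
    assert se1 == pytest.approx(
        np.sqrt(0.411**2 * 0.062**2 + 0.302**2 * 0.084**2), abs=1e-12
    )
    assert se1 == pytest.approx(0.036, abs=0.002)
    se2 = dm.delta_se(("affluence", "caseload", "hazard"), colon_coefficients)
    assert se2 == pytest.approx(0.043, abs=0.002)
    zero = coef_table([("m", "x", 0.4, 0.0), ("hazard", "m", 0.7, 0.0)])
    assert dm.delta_se(("x", "m", "hazard"), zero) == 0.0


@given(
    st.lists(
        st.floats(-2, 2, allow_nan=False).map(lambda v: round(v, 3)),
        min_size=5, max_size=5,
    )
)
def test_decomposition_additivity(vals):
    """direct + sum of path products = total, exactly, for any coefficients."""
    a1, a2, b1, b2, c = vals
    tab = coef_table(
        [
            ("emergency", "affluence", a1, 0.05),
            ("caseload", "affluence", a2, 0.05),
            ("caseload", "emergency", c, 0.05),
            ("hazard", "emergency", b1, 0.05),
            ("hazard", "caseload", b2, 0.05),
            ("hazard", "affluence", 0.3, 0.05),
        ]
    )
    spec = make_spec(
        [
            Equation("emergency", ("affluence",)),
            Equation("caseload", ("affluence", "emergency")),
            Equation("hazard", ("affluence", "emergency", "caseload"),
                     "discrete_time_logit"),
        ],
        exposure="affluence",
    )
    dec = dm.decompose(tab, spec=spec)
    total_paths = sum(p.estimate for p in dec.paths)
    assert dec.total_indirect.estimate == pytest.approx(total_paths, abs=1e-12)
    assert dec.total.estimate == pytest.approx(
        dec.direct.estimate + dec.total_indirect.estimate, abs=1e-12
    )


def test_decompose_reproduces_published_table(colon_coefficients, colon_spec):
    dec = dm.decompose(colon_coefficients, spec=colon_spec)
    by_chain = {p.chain: p for p in dec.paths}
    assert by_chain[("affluence", "emergency", "hazard")].estimate == pytest.approx(
        -0.124, abs=0.002
    )
    assert by_chain[("affluence", "caseload", "hazard")].estimate == pytest.approx(
        -0.099, abs=0.002
    )
    assert by_chain[
        ("affluence", "emergency", "caseload", "hazard")
    ].estimate == pytest.approx(-0.003, abs=0.002)
    assert dec.total_indirect.estimate == pytest.approx(-0.227, abs=0.002)
    assert dec.total.estimate == pytest.approx(-0.823, abs=0.002)
    assert dec.proportion_mediated == pytest.approx(0.276, abs=0.002)
    assert not dec.inconsistent


def test_decompose_no_mediators():
    tab = coef_table([("hazard", "x", 0.5, 0.1)])
    spec = make_spec([Equation("hazard", ("x",), "discrete_time_logit")])
    dec = dm.decompose(tab, spec=spec)
    assert dec.total.estimate == dec.direct.estimate == 0.5
    assert dec.total_indirect.estimate == 0.0
    assert dec.proportion_mediated == 0.0


def test_inconsistent_mediation_flagged():
    tab = coef_table(
        [("m", "x", 0.5, 0.1), ("hazard", "m", 0.8, 0.1), ("hazard", "x", -0.3, 0.1)]
    )
    spec = make_spec(
        [Equation("m", ("x",)), Equation("hazard", ("x", "m"), "discrete_time_logit")]
    )
    dec = dm.decompose(tab, spec=spec)
    assert dec.inconsistent
    assert not 0.0 <= dec.proportion_mediated <= 1.0


def test_ols_matches_normal_equations_and_statsmodels():
    """Linear equations agree with the closed-form normal equations on a toy
    4-point problem, and with statsmodels HC1 robust SEs on random data."""
    import statsmodels.api as sm

    x = np.array([0.0, 1.0, 2.0, 3.0])
    y = np.array([1.0, 2.0, 2.0, 4.0])
    data = pd.DataFrame({"x": x, "m": y, "time": [1] * 4, "event": [1, 0, 1, 0]})
    spec = make_spec(
        [Equation("m", ("x",)), Equation("hazard", ("x",), "discrete_time_logit")]
    )
    fit = dm.fit_path_system(data, spec, J_max=1)
    X = np.column_stack([np.ones(4), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert fit.coef("m", "intercept") == pytest.approx(beta[0], abs=1e-10)
    assert fit.coef("m", "x") == pytest.approx(beta[1], abs=1e-10)

    rng = np.random.default_rng(12)
    n = 400
    df = pd.DataFrame({"x": rng.normal(size=n)})
    df["m"] = (rng.random(n) < np.clip(0.4 + 0.2 * df["x"], 0, 1)).astype(float)
    df["time"] = rng.integers(1, 5, n)
    df["event"] = rng.integers(0, 2, n)
    fit = dm.fit_path_system(df, spec, J_max=4)
    sm_res = sm.OLS(df["m"], sm.add_constant(df["x"])).fit(cov_type="HC1")
    assert fit.coef("m", "x") == pytest.approx(sm_res.params["x"], abs=1e-8)
    assert fit.se("m", "x") == pytest.approx(sm_res.bse["x"], abs=1e-8)


def test_empty_mediator_system_matches_plain_dtsm(colon_cohort):
    """A spec with no mediator equations reduces to fit_dtsm alone."""
    _, frame, _ = colon_cohort
    spec = make_spec(
        [Equation("hazard", ("affluence", "age10"), "discrete_time_logit")],
        exposure="affluence",
    )
    spec = dm.PathModelSpec(
        exposure="affluence", equations=spec.equations,
        outcome=OutcomeSpec(name="hazard", J_max=24, baseline="constant"),
    )
    fit = dm.fit_path_system(frame, spec)
    from dtmediate.person_period import frame_to_records

    table = dm.expand_person_period(
        frame_to_records(frame, covariates=["affluence", "age10"]), 24
    )
    direct = dm.fit_dtsm(
        table,
        dm.HazardSpec(covariates=("affluence", "age10"), baseline="constant"),
    )
    pd.testing.assert_series_equal(fit.hazard_fit.params, direct.params)
    assert fit.hazard_fit.loglik == direct.loglik


def test_total_effect_matches_mediator_free_refit():
    """In a generative system with modest mediator effects the decomposition's
    total effect is close to the exposure coefficient of a refit that omits
    the mediators (the two coincide in the linear limit)."""
    cfg = dm.SyntheticConfig(
        n=20000,
        J=8,
        hazard_coef={"affluence": 0.4, "m1": 0.25},
        mediator_coefs={"m1": {"intercept": 0.35, "affluence": 0.3}},
        exposure_dist="uniform",
        target_cum_event=0.4,
        seed=314,
    )
    frame, _ = dm.simulate_frame(cfg)
    dec = dm.decompose(dm.fit_path_system(frame, cfg.model_spec()))
    reduced_spec = dm.PathModelSpec(
        exposure="affluence",
        equations=(Equation("hazard", ("affluence",), "discrete_time_logit"),),
        outcome=OutcomeSpec(name="hazard", J_max=8, baseline="constant"),
    )
    reduced = dm.fit_path_system(frame, reduced_spec)
    assert dec.total.estimate == pytest.approx(
        reduced.coef("hazard", "affluence"), abs=0.08
    )


def test_standardize_latent(colon_cohort):
    cfg, frame, _ = colon_cohort
    fit = dm.fit_path_system(frame, cfg.model_spec())
    raw = dm.standardize_latent(fit, "raw")
    assert (raw["standardized"] == raw["raw"]).all()
    ystar = dm.standardize_latent(fit, "ystar")
    denom = np.sqrt(fit.hazard_fit.linpred_var + np.pi**2 / 3)
    np.testing.assert_allclose(ystar["standardized"], ystar["raw"] / denom)
    with pytest.raises(ValueError):
        dm.standardize_latent(fit, "zscore")


def test_standardization_scale_equivariance(colon_cohort):
    """Scaling a covariate by c divides its per-unit coefficient by c and
    leaves the per-SD (ystar-standardized per SD) effect unchanged."""
    cfg, frame, _ = colon_cohort
    fit = dm.fit_path_system(frame, cfg.model_spec())
    scaled = frame.assign(age10=frame["age10"] * 2.0)
    fit2 = dm.fit_path_system(scaled, cfg.model_spec())
    assert fit2.coef("hazard", "age10") == pytest.approx(
        fit.coef("hazard", "age10") / 2.0, rel=1e-6
    )
    # per-SD effect: coefficient times covariate SD, on the ystar scale
    s1 = dm.standardize_latent(fit, "ystar")["standardized"]["age10"]
    s2 = dm.standardize_latent(fit2, "ystar")["standardized"]["age10"]
    assert s1 * frame["age10"].std() == pytest.approx(
        s2 * scaled["age10"].std(), rel=1e-6
    )


def test_bootstrap_validation_and_determinism():
    cfg = dm.SyntheticConfig(n=250, J=6, seed=5)
    frame, _ = dm.simulate_frame(cfg)
    spec = cfg.model_spec()
    with pytest.raises(ValueError, match="B >= 100"):
        dm.bootstrap_indirect(frame, spec, B=0)
    b1 = dm.bootstrap_indirect(frame, spec, B=100, seed=8)
    b2 = dm.bootstrap_indirect(frame, spec, B=100, seed=8)
    pd.testing.assert_frame_equal(b1.ci, b2.ci)


def test_bootstrap_se_agrees_with_delta_method():
    """Bootstrap SEs of single-path indirect effects are within 25% of the
    delta-method SEs on a simulated cohort."""
    cfg = dm.SyntheticConfig(n=2000, J=12, seed=41)
    frame, _ = dm.simulate_frame(cfg)
    spec = cfg.model_spec()
    dec = dm.decompose(dm.fit_path_system(frame, spec))
    boot = dm.bootstrap_indirect(frame, spec, B=400, seed=42)
    for p in dec.paths:
        ratio = boot.ci.loc[p.label, "se"] / p.se
        assert 0.75 < ratio < 1.25, (p.label, ratio)
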