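"""Published worked-example inputs: an Irish colon-cancer cohort (2004-2008).

These are the printed direct-effect estimates from a registry study of 5178
colon-cancer patients followed quarterly for up to 24 periods after diagnosis.
The structural system has a continuous affluence/deprivation exposure on a 0-1
metric, two binary mediators (emergency admission and treatment at a
high-caseload hospital, each modelled by a linear probability equation) and a
discrete-time logistic hazard of cancer death. The raw registry data are not
public; these coefficient tables serve as fixed inputs for the
effect-decomposition worked example and as generative truth for simulation
studies.
"""

from __future__ import annotations

import pandas as pd

from .path_mediation import Equation, OutcomeSpec, PathModelSpec

COHORT_N = 5178
N_PERIODS = 24

#: hazard-of-death equation (logit-latent metric), estimate and robust SE
COLON_HAZARD_COEF = {
    "age10": 0.299,
    "affluence": -0.596,
    "emergency": 0.411,
    "stage2": 0.639,
    "stage3": 1.306,
    "stage4": 3.193,
    "treatment": -0.766,
    "caseload": -0.173,
}
COLON_HAZARD_SE = {
    "age10": 0.036,
    "affluence": 0.271,
    "emergency": 0.084,
    "stage2": 0.213,
    "stage3": 0.210,
    "stage4": 0.207,
    "treatment": 0.106,
    "caseload": 0.071,
}

#: emergency-admission linear probability equation
COLON_EMERGENCY_COEF = {"intercept": 0.241, "age10": 0.023, "affluence": -0.302}
COLON_EMERGENCY_SE = {"intercept": 0.061, "age10": 0.007, "affluence": 0.062}
COLON_EMERGENCY_RESID_VAR = 0.170

#: high-caseload-hospital linear probability equation
COLON_CASELOAD_COEF = {
    "intercept": 0.192,
    "age10": -0.009,
    "affluence": 0.576,
    "emergency": -0.063,
}
COLON_CASELOAD_SE = {
    "intercept": 0.074,
    "age10": 0.008,
    "affluence": 0.077,
    "emergency": 0.023,
}
COLON_CASELOAD_RESID_VAR = 0.241

#: baseline covariate distribution of the cohort
COLON_STAGE_PROBS = (0.108, 0.350, 0.324, 0.218)  # stage I..IV
COLON_TREATMENT_P = 0.808
COLON_AFFLUENCE_MEAN = 0.58
COLON_AFFLUENCE_SD = 0.13


def colon_coefficient_table() -> pd.DataFrame:
    """All direct effects as a tidy (equation, regressor, estimate, se) frame.

    This is the format `dtmediate decompose` consumes, enabling the effect
    decomposition without access to the raw cohort.
    """
    rows = []
    for reg, est in COLON_HAZARD_COEF.items():
        rows.append(("hazard", reg, est, COLON_HAZARD_SE[reg]))
    for reg, est in COLON_EMERGENCY_COEF.items():
        rows.append(("emergency", reg, est, COLON_EMERGENCY_SE[reg]))
    for reg, est in COLON_CASELOAD_COEF.items():
        rows.append(("caseload", reg, est, COLON_CASELOAD_SE[reg]))
    return pd.DataFrame(rows, columns=["equation", "regressor", "estimate", "se"])


def colon_model_spec(J_max: int = N_PERIODS, baseline: str = "constant") -> PathModelSpec:
    """The colon-cancer recursive system: affluence and age drive emergency
    admission; affluence, age and admission route drive hospital caseload;
    everything plus stage and treatment enters the hazard of death."""
    return PathModelSpec(
        exposure="affluence",
        equations=(
            Equation("emergency", ("affluence", "age10"), "linear"),
            Equation("caseload", ("affluence", "age10", "emergency"), "linear"),
            Equation(
                "hazard",
                (
                    "affluence",
                    "age10",
                    "emergency",
                    "caseload",
                    "stage2",
                    "stage3",
                    "stage4",
                    "treatment",
                ),
                "discrete_time_logit",
            ),
        ),
        outcome=OutcomeSpec(
            name="hazard",
            time="time",
            event="event",
            J_max=J_max,
            baseline=baseline,
            proportional=True,
        ),
    )
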