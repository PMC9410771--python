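"""Published group-mean pulse-spread measurements used as worked-example inputs.

These are the reported group-average relative fluxes (percent of the initial
central-window fluorescence per minute) for mouse tibial nerve at 2, 4, 8 and
16 weeks of age and sciatic nerve at 8 weeks, from the photoactivation
pulse-spread study of neurofilament transport this package models, with the
corresponding infinite-window ("model") values from the window-size
extrapolation. They serve as inputs to the estimator arithmetic: applying the
velocity and directionality formulas to the flux columns must reproduce the
published velocity (mm/d) and percent-anterograde columns.
"""

from __future__ import annotations

import pandas as pd

# group -> (S_d measured, S_p measured, S_d model, S_p model), % of F_c(0) per min
REPORTED_GROUP_FLUXES: dict[str, dict[str, float]] = {
    "tibial_2wk": dict(S_d_pct=0.299, S_p_pct=0.195, S_d_model_pct=0.415, S_p_model_pct=0.231),
    "tibial_4wk": dict(S_d_pct=0.178, S_p_pct=0.135, S_d_model_pct=0.218, S_p_model_pct=0.184),
    "tibial_8wk": dict(S_d_pct=0.154, S_p_pct=0.122, S_d_model_pct=0.152, S_p_model_pct=0.113),
    "tibial_16wk": dict(S_d_pct=0.096, S_p_pct=0.068, S_d_model_pct=0.091, S_p_model_pct=0.060),
    "sciatic_8wk": dict(S_d_pct=0.202, S_p_pct=0.125, S_d_model_pct=0.202, S_p_model_pct=0.130),
}

# published derived values for the same groups (velocity mm/d, % anterograde)
REPORTED_DERIVED: dict[str, dict[str, float]] = {
    "tibial_2wk": dict(velocity=0.060, pct_antero=60.5, velocity_model=0.106, pct_antero_model=64.2),
    "tibial_4wk": dict(velocity=0.025, pct_antero=56.9, velocity_model=0.020, pct_antero_model=54.2),
    "tibial_8wk": dict(velocity=0.018, pct_antero=55.8, velocity_model=0.022, pct_antero_model=57.3),
    "tibial_16wk": dict(velocity=0.016, pct_antero=58.7, velocity_model=0.018, pct_antero_model=60.5),
    "sciatic_8wk": dict(velocity=0.044, pct_antero=61.8, velocity_model=0.041, pct_antero_model=60.8),
}

ACTIVATION_WINDOW_UM = 40.0


def reported_fluxes_frame() -> pd.DataFrame:
    df = pd.DataFrame(REPORTED_GROUP_FLUXES).T
    df.index.name = "group"
    return df.reset_index()
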