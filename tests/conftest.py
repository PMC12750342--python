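import numpy as np
import pandas as pd
import pytest

from paddythresh import reference, simulate
from paddythresh.core import OXIDE_FRACTIONS


@pytest.fixture(scope="session")
def tiny_dataset():
    return simulate.make_fixture("tiny", seed=11)


@pytest.fixture(scope="session")
def study_dataset():
    return simulate.make_fixture("study_like", seed=7)


@pytest.fixture(scope="session")
def reference_models():
    return reference.reference_transfer_models()


def build_quadrant_frame(counts, soil_threshold, grain_limit, ph=7.8):
    """Minimal paired frame realising exact quadrant counts.

    Quadrant membership depends only on which side of the threshold/limit
    each value falls, so sites are placed at 2x (exceeding) or 0.5x (safe).
    """
    placements = {
        "I": (2.0, 2.0),
        "II": (0.5, 2.0),
        "III": (0.5, 0.5),
        "IV": (2.0, 0.5),
    }
    rows = []
    k = 0
    for quadrant, n in counts.items():
        s_mult, r_mult = placements[quadrant]
        for _ in range(n):
            k += 1
            rows.append(
                {
                    "site_id": f"Q{k:04d}",
                    "pH": ph,
                    "S_T_Cd": s_mult * soil_threshold,
                    "Rice_Cd": r_mult * grain_limit,
                    "S_T_As": s_mult * soil_threshold,
                    "Rice_As": r_mult * grain_limit,
                }
            )
    return pd.DataFrame(rows)


def make_regression_frame(n, rng, rice_from=None, noise_sd=0.0):
    """Small paired frame with lognormal covariates for regression tests.

    ``rice_from`` is a callable mapping the frame to lg(rice); defaults to
    the regional Cd model's linear predictor.
    """
    from paddythresh.regression import linear_predictor

    frame = pd.DataFrame(
        {
            "site_id": [f"R{i:04d}" for i in range(n)],
            "pH": rng.uniform(6.6, 8.2, n),
            "SOM": rng.uniform(10, 70, n),
            "S_T_Cd": rng.lognormal(np.log(2.0), 1.0, n),
            "A_Cd": np.nan,
            "S_T_As": rng.lognormal(np.log(60.0), 1.0, n),
            "A_As": np.nan,
            **{
                frac: rng.lognormal(np.log(mean), 0.4, n)
                for frac, mean in reference.COVARIATE_MEANS.oxides.items()
            },
        }
    )
    frame["A_Cd"] = 0.45 * frame["S_T_Cd"] * rng.lognormal(0, 0.1, n)
    frame["A_As"] = np.maximum(0.721 * frame["S_T_As"] - 0.263, 0.001)
    if rice_from is None:
        rice_from = lambda f: linear_predictor(reference.CD_TRANSFER_MODEL, f)
    lg_rice = np.asarray(rice_from(frame), dtype=float)
    if noise_sd:
        lg_rice = lg_rice + rng.normal(0, noise_sd, n)
    frame["Rice_Cd"] = 10.0 ** lg_rice
    frame["Rice_As"] = 10.0 ** np.asarray(
        linear_predictor(reference.AS_TRANSFER_MODEL, frame), dtype=float
    )
    return frame
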