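"""Published constants of the Gejiu–Mengzi (Yunnan) paddy-soil survey.

These values — the regional transfer-model coefficients, study-wide
covariate means, 95th-percentile reciprocal bioconcentration factors, and
the four-quadrant counts of the screening-value evaluation — are the
inputs that calibrate this package's defaults and anchor its worked
examples. The underlying 125-sample field data are not public; the
synthetic generator in :mod:`paddythresh.simulate` emulates their
structure from these constants.
"""

from __future__ import annotations

from .regression import Term, TransferModel
from .safety import AuxiliaryRelation, CovariateMeans

#: Regional log10 transfer model for grain Cd (fitted on 116 survey sites).
CD_TRANSFER_MODEL = TransferModel(
    element="Cd",
    intercept=1.481,
    terms=(
        Term("pH", -0.096, "raw"),
        Term("SOM", -0.003, "raw"),
        Term("S_T_Cd", 0.852, "log10"),
        Term("C_Fe", -0.25, "log10"),
        Term("F_Fe", -0.32, "log10"),
        Term("Am_Fe", 0.217, "log10"),
        Term("C_Mn", 0.238, "log10"),
        Term("Am_Mn", -0.381, "log10"),
    ),
    n_fit=116,
    r=0.861,
    r2=0.742,
    adj_r2=0.724,
)

#: Regional log10 transfer model for grain As (fitted on 116 survey sites).
AS_TRANSFER_MODEL = TransferModel(
    element="As",
    intercept=-2.077,
    terms=(
        Term("pH", -0.006, "raw"),
        Term("SOM", -0.000125, "raw"),
        Term("S_T_As", 0.975, "log10"),
        Term("A_As", -0.003, "log10"),
        Term("C_Fe", -0.001, "log10"),
        Term("F_Fe", -0.017, "log10"),
        Term("Am_Fe", -0.006, "log10"),
        Term("C_Mn", -0.002, "log10"),
    ),
    n_fit=116,
    r=0.999,
    r2=0.998,
    adj_r2=0.997,
)


def reference_transfer_models() -> dict[str, TransferModel]:
    """Fresh copies of the regional Cd/As transfer models."""
    return {
        "Cd": TransferModel.from_dict(CD_TRANSFER_MODEL.to_dict()),
        "As": TransferModel.from_dict(AS_TRANSFER_MODEL.to_dict()),
    }


#: Study-wide covariate means used when inverting the models (mg·kg⁻¹; SOM g·kg⁻¹).
COVARIATE_MEANS = CovariateMeans(
    som=34.55,
    oxides={
        "C_Fe": 390.0,
        "C_Mn": 80.0,
        "F_Fe": 34450.0,
        "F_Mn": 1080.0,
        "Am_Fe": 4190.0,
        "Am_Mn": 970.0,
    },
)

#: Linear tie of available As to total As (linear scale), used in ST inversion.
AAS_RELATION = AuxiliaryRelation(response="A_As", slope=0.721, intercept=-0.263, r2=0.55)

#: Survey descriptive anchors: soil-total means (mg·kg⁻¹) and pH structure.
SOIL_TOTAL_MEANS = {"Cd": 2.16, "As": 60.18}
PH_RANGE = (6.56, 8.25)
ALKALINE_FRACTION = 0.744  # share of samples with pH > 7.5
SOM_MEAN, SOM_RANGE = 34.55, (9.53, 70.30)

#: Fitted 95th-percentile reciprocal BCF per (element, pH bin), dimensionless.
HC95_INV_BCF = {
    ("Cd", "neutral"): 48.29,
    ("Cd", "alkaline"): 50.6,
    ("As", "neutral"): 194.3,
    ("As", "alkaline"): 193.8,
}

#: Published regional thresholds (mg·kg⁻¹) per (element, pH bin).
PUBLISHED_ST = {
    ("Cd", "neutral"): 4.54,
    ("Cd", "alkaline"): 7.12,
    ("As", "neutral"): 91.43,
    ("As", "alkaline"): 92.30,
}
PUBLISHED_HT = {
    ("Cd", "neutral"): 9.66,
    ("Cd", "alkaline"): 10.12,
    ("As", "neutral"): 97.15,
    ("As", "alkaline"): 96.9,
}

#: Four-quadrant counts of the screening-value evaluation over 125 sites
#: (I true positive, II false negative, III true negative, IV false positive).
QUADRANT_COUNTS = {
    "Cd": {"I": 18, "II": 0, "III": 24, "IV": 83},
    "As": {"I": 22, "II": 0, "III": 38, "IV": 65},
}
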