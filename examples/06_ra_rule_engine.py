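"""The eight-predictor RA rule engine on individual patient records.

Predictors: QOF RA codes, the derived intensity class (1 sero-positive ..
4 sero-negative, 9 no history), psoriatic-arthritis and alternative-
arthropathy exclusions, and the prednisolone/methotrexate/sulphasalazine/
leflunomide medication groups.  The shipped code lists are synthetic
placeholders; deployments load their own terminology via configuration.
"""

from codephen import PatientRecord, classify_ra, default_predictors
from codephen.ra import feature_vector

predictors = default_predictors()

patients = {
    "QOF code + methotrexate": {"N0400": 1, "h3311": 2},
    "sero-positive + prednisolone": {"N0411": 1, "bd3z1": 1},
    "diagnosis code only (no medication)": {"N0400": 3},
    "psoriatic arthritis exclusion": {"N0452": 1, "N0400": 2, "h3311": 1},
    "no relevant codes": {"Z0004": 5},
}
for desc, codes in patients.items():
    rec = PatientRecord("P", codes)
    vec = feature_vector(rec, predictors)
    print(f"{desc:38s} intensity={vec['INTENSITY_RA']} -> {classify_ra(rec, predictors)}")
# Exclusions dominate: a single psoriatic-arthritis code forces notRA even
# with diagnostic and medication evidence present.
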