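"""Semi-quantify a compound via its retention-time-nearest internal standard.

The calibration is a straight line fitted by weighted least squares
with weights 1/x, which keeps low concentration levels from being
swamped by the high ones.  Results are semi-quantified estimates, not
validated concentrations.
"""

import pandas as pd

import dielscreen as ds

compounds = pd.DataFrame({"rt": [5.2, 8.9]}, index=["bezafibrate", "caffeine"])
standards = pd.DataFrame({"rt": [3.0, 5.0, 9.1]}, index=["IS_a", "IS_b", "IS_c"])
pairing = ds.match_internal_standards(compounds, standards)
print("IS pairing:", pairing.to_dict())

# calibration levels in ng/L with analyte/IS response ratios
points = [(50, 0.11), (100, 0.24), (200, 0.45), (500, 1.18), (1000, 2.31)]
model = ds.fit_calibration(points, compound_id="bezafibrate", is_id=pairing["bezafibrate"])
print(f"calibration: response = {model.slope:.5f} x conc + {model.intercept:.5f} "
      f"({model.weighting}-weighted)")

for response in (0.35, 0.80, 2.00):
    q = ds.quantify(response, model)
    print(f"response {response:.2f} -> {q.concentration:7.1f} ng/L ({q.label})")
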