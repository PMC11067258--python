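"""End-to-end right-heart-catheterization (RHC) analysis pipeline.

Pass the path of the public RHC CSV as the first argument to analyse the
real study (black vs white patients, outcome = receipt of RHC, SES =
education >= high school and income >= $25K, 27 dummy-encoded health-status
covariates).  Without an argument, a SYNTHETIC column-compatible stand-in
is generated so the pipeline can be demonstrated offline; its numbers are
structural only.
"""

import sys

import deweight as dw

if len(sys.argv) > 1:
    data = dw.rhc_preprocess(sys.argv[1])
    source = sys.argv[1]
else:
    data = dw.rhc_preprocess(dw.synthetic_rhc_raw(n=4000, seed=4))
    source = "synthetic stand-in (structural demo only)"

print(f"source: {source}")
print(f"N = {data.n_subjects} ({data.n_minority} black, "
      f"{data.n_majority} white), {data.X_h.shape[1]} health-status columns")
print(data.subgroup_catalog().to_string(index=False), "\n")

table = dw.four_method_comparison(data)
print(table.round(2).to_string(index=False))

w = dw.build_weights(data, "att", "deweighting")
chars = dw.weighted_characteristics(data, w)
print(f"\nATT deweighting: weighted white N = {chars.n0_weighted:.2f} "
      f"(raw {chars.n0}); SES rows of the weighted white sample equal the "
      "raw white SES distribution by construction.")
print(chars.table.loc[["educ_hs", "income_25k"]].round(4).to_string())
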