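"""Isotropic vs orthotropic vs zoned-orthotropic peri-implant comparison.

Runs the full pipeline on the mandible proxy under a 150 N vertical bite-like
load on the implant platform, with both tube ends fully restrained, and
prints the maximum stress/strain statistics over the cortical and cancellous
bands surrounding the implant, with percent changes against the effectively
isotropic baseline.
"""

import pandas as pd

import orthobone as ob

pd.set_option("display.width", 160)

cfg = ob.RunConfig()           # default proxy geometry, three variants
res = ob.run_comparison(cfg, write_outputs=False)

df = res.comparison
cols = ["region", "quantity", "statistic", "isotropic", "orthotropic",
        "pct_change_orthotropic", "zoned:4", "pct_change_zoned:4"]
print(df[df.statistic == "max"][cols].round(4).to_string(index=False))

print("""
Reading the table: stresses are MPa (signed; compressive maxima are the most
negative values), strains dimensionless.  The cancellous band reacts far more
strongly to orthotropy than the cortical band - its peak stresses grow by
hundreds of percent - while the zoned comparator scatters values above and
below both other models (its single frame per zone misaligns the stiff axis).
Frame deviation from the centerline tangent: orthotropic %.2f deg, zoned %.2f deg.
""" % (res.variants["orthotropic"].frame_deviation_mean,
       res.variants["zoned:4"].frame_deviation_mean))
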