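"""Filter candidate variants down to confident somatic SNVs.

Six constructed candidates each trip one rule of the cascade (known
germline panel; intergenic; variant evidence in normal spots; insufficient
normal depth to exclude germline; weak tumor signal); exactly one
survives.  Normal spots are those with tumor proportion < 0.5.
"""

import numpy as np
import pandas as pd

from spatialcna import VariantTable, filter_somatic

sites = pd.DataFrame({
    "chrom": ["chr1"] * 6,
    "pos": [101, 102, 103, 104, 105, 106],
    "ref": list("AACGTA"),
    "alt": list("TTTAAC"),
    "known_germline": [True, False, False, False, False, False],
    "genic": [True, False, True, True, True, True],
})
# spots 0-1 are normal (theta < 0.5); 2-4 are tumor
alt = np.array([
    [0, 0, 9, 9, 9],   # in the germline panel
    [0, 0, 9, 9, 9],   # intergenic
    [1, 0, 9, 9, 9],   # one alt read in a normal spot
    [0, 0, 9, 9, 9],   # normal depth 10 < 15: cannot exclude germline
    [0, 0, 1, 1, 1],   # tumor alt count 3 < 5
    [0, 0, 9, 9, 9],   # survives: alt 27, VAF 0.45
])
tot = np.array([
    [10, 10, 20, 20, 20], [10, 10, 20, 20, 20], [10, 10, 20, 20, 20],
    [5, 5, 20, 20, 20], [10, 10, 20, 20, 20], [10, 10, 20, 20, 20],
])
theta = np.array([0.1, 0.2, 0.9, 0.8, 0.7])

vt = VariantTable(sites=sites, alt_counts=alt, total_counts=tot)
somatic, annotated = filter_somatic(vt, theta)  # defaults: alt >= 5, VAF > 0.3, depth 15
print(f"{len(annotated)} candidates -> {len(somatic)} somatic call(s)")
print(somatic[["chrom", "pos", "tumor_alt", "tumor_total", "tumor_vaf"]].to_string(index=False))
print("per-rule failures:",
      {r: int((~annotated[r]).sum())
       for r in ("pass_panel", "pass_genic", "pass_normal", "pass_signal")})
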