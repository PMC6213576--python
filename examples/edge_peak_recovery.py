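"""Recovering reflections truncated by detector edges.

For a peak partially off a panel, summing the observed voxels loses the
truncated fraction, while the profile fit — evaluated over the full
reciprocal-space box but fitted only on detector-accessible voxels —
extrapolates the missing part.  The model scale A approaches the
untruncated truth.
"""

import numpy as np

from tofprofile import IntegrationConfig, integrate_peaks, standard_suites

cfg = IntegrationConfig()
suites = standard_suites(seed=11, n_peaks={"strong": 40, "edge": 8})

strong = suites["strong"]
run_s = integrate_peaks(strong.events,
                        list(zip(strong.truth.h, strong.truth.k, strong.truth.l)),
                        strong.ub, strong.geom, strong.table, cfg)

edge = suites["edge"]
run_e = integrate_peaks(edge.events,
                        list(zip(edge.truth.h, edge.truth.k, edge.truth.l)),
                        edge.ub, edge.geom, edge.table, cfg,
                        library=run_s.library)
truth = edge.truth.set_index(["h", "k", "l"])
print("  hkl        edge_px  truncated   A/truth   masked-sum/truth")
for r in run_e.results:
    t = truth.loc[r.peak]
    print(f"({r.peak[0]:3d}{r.peak[1]:3d}{r.peak[2]:3d})  {r.edge_px:6d} "
          f"{t.trunc_frac:9.0%} {r.A / t.n_in_box:9.2f} {r.I_masked / t.n_in_box:13.2f}")
print("\nthe masked summation is biased low by roughly the truncated fraction,")
print("while the fitted scale A recovers the untruncated intensity.")
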