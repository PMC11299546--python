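"""TFCE permutation statistics on a cohort with planted atrophy.

Generates two groups of phantoms, group B with 20% thinner gray matter,
and tests for the group difference with threshold-free cluster
enhancement and max-statistic permutation correction.
"""
import numpy as np
import t1morph as tm
from t1morph import stats as st
from t1morph.volume_io import smooth_fwhm

base = tm.PhantomSpec(grid_shape=(40, 40, 40), wm_radius=9.0,
                      gm_thickness=3.5, noise_percent=3.0, seed=0)
cohort = tm.generate_cohort(n_per_group=10, atrophy_percent=20.0,
                            base_spec=base, seed=123)

Y, tiv = [], []
for vol, truth, group, t in cohort:
    Y.append(smooth_fwhm(truth.fractions["gm"], 6.0).data.ravel())
    tiv.append(t)
Y = st.global_scaling_tiv(np.stack(Y), np.array(tiv))

design = st.Design.two_group(10, 10)           # one-tailed A > B
p, enh, null_max = st.permutation_fwe(Y, design, st.TfceParams(),
                                      n_perm=199, seed=7,
                                      shape=(40, 40, 40))
sig = p <= 0.05
ribbon = cohort[0][1].fractions["gm"].data > 0.5
print(f"significant voxels at FWE p<=0.05: {sig.sum()}")
print(f"overlap with the planted GM ribbon: "
      f"{(sig & ribbon).sum()}/{ribbon.sum()}")
print(f"null max-TFCE distribution: median {np.median(null_max):.1f}, "
      f"95th pct {np.quantile(null_max, 0.95):.1f}")
# The planted 20% thickness loss shows up as a contiguous significant
# cluster covering most of the gray-matter shell.
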