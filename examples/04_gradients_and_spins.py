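"""Connectivity gradients and spin-corrected map correlations.

The group-mean cortical FC matrix is thresholded to its top 10% per row,
turned into a cosine affinity and embedded with diffusion maps (alpha=0.5,
t=0).  Loading maps are compared with the principal gradient under a
spin-permutation null that preserves spatial autocorrelation.
"""

import numpy as np

from bbpls import SynthConfig, generate_cohort
from bbpls.gradients import (
    GradientConfig, cosine_affinity, diffusion_embedding, group_mean_fc,
    row_threshold,
)
from bbpls.spatial import build_spin_null, fc_loading_parcel_profiles, spin_correlation
from bbpls.pipeline import fit_sample

data = generate_cohort(SynthConfig(n_participants=300, n_cortical_parcels=60, seed=0))
parc = data.parcellation

mean_fc = group_mean_fc(data.modalities["rest_fc"], parc)
affinity = cosine_affinity(row_threshold(mean_fc, row_density=0.10))
grad = diffusion_embedding(affinity, GradientConfig(), parcel_ids=list(mean_fc.index))
print("gradient variance explained (first 3):",
      np.round(100 * grad.variance_explained[:3], 1), "%")

fit = fit_sample(data, n_components=1)
within, between = fc_loading_parcel_profiles(
    fit["loadings"]["rest_fc"]["lc1"].to_numpy(), parc
)
null = build_spin_null(parc, n_spins=199, rng=np.random.default_rng(3))
g1 = grad.embedding.iloc[:, 0].to_numpy()
for name, prof in (("between-network", between), ("within-network", within)):
    r, p = spin_correlation(prof.to_numpy(), g1, null)
    print(f"LC1 {name} FC loadings vs principal gradient: "
          f"r={r:.2f}, p_spin={p:.3f}")
# The planted LC1 edge pattern follows the cohort's network axis, so the
# between-network loading profile tracks the principal gradient; the spin
# p-value accounts for the spatial smoothness of both maps.
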