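"""Quantify filament bundling from TIRF line profiles.

Generates Gaussian line profiles across single filaments (the control)
and across bundles averaging ~3.4 filaments, fits each profile, and
normalizes the background-corrected peak intensities to the control
mean — the bundle-thickness readout.
"""

import numpy as np

from syncap import (
    TirfFieldSpec,
    fit_gaussian,
    generate_tirf_profiles,
    mann_whitney,
    normalize_to_control,
)

spec = TirfFieldSpec(seed=5)  # 40 singles + 40 bundles, 143 nm pixels
singles, bundles = [], []
for profile, count in generate_tirf_profiles(spec):
    amplitude = fit_gaussian(profile).amplitude
    (singles if count == 1 else bundles).append(amplitude)

normalized = normalize_to_control(bundles, singles)
comparison = mann_whitney(bundles, singles, alternative="two_sided")

print(f"control profiles (1 filament): {len(singles)}")
print(f"bundle profiles              : {len(bundles)}")
print(f"mean normalized bundle intensity: {normalized.mean():.2f}")
print(f"Mann-Whitney U = {comparison.u_statistic:.0f}, p = {comparison.p_value:.2e}")
# The normalized mean approximates the mean filaments-per-bundle;
# fluorescence adds linearly within a diffraction-limited bundle.
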