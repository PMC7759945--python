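"""Temporal overlap between a diurnal and a nocturnal forager.

Computes the overlap coefficient Dhat (area under the minimum of the two
activity densities) with its estimator-selection rule, a smoothed-bootstrap
confidence interval, the overlap-strength band, and two tests of whether
the samples share one distribution.
"""

import numpy as np

from dielcam.overlap import (
    classify_strength,
    estimate_overlap,
    overlap_ci,
    same_distribution_test,
    select_estimator,
    watson_two_sample,
)
from dielcam.simulate import sample_mixture

rng = np.random.default_rng(7)
diurnal = sample_mixture(((7.5, 5.0, 0.55), (16.5, 5.0, 0.45)), 300, rng)
nocturnal = sample_mixture(((20.0, 4.0, 0.5), (3.0, 3.0, 0.5)), 120, rng)
similar = sample_mixture(((8.0, 5.0, 0.5), (16.0, 4.0, 0.5)), 90, rng)

for name, other in [("nocturnal", nocturnal), ("similar diurnal", similar)]:
    est = select_estimator(diurnal.size, other.size)
    delta, _ = estimate_overlap(diurnal, other)
    lo, hi = overlap_ci(diurnal, other, n_boot=500, seed=1)
    p = same_distribution_test(diurnal, other, n_boot=999, seed=2)
    w = watson_two_sample(diurnal, other)
    print(f"diurnal vs {name:15s} ({est}, n={diurnal.size}/{other.size}):")
    print(f"  Dhat = {delta:.3f}  CI [{lo:.3f}, {hi:.3f}]  strength = {classify_strength(delta)}")
    print(f"  same-distribution permutation p = {p:.3f}; Watson U2 = {w.u2:.3f} ({w.band})")
print()
print("Dhat near 0 = disjoint schedules, near 1 = identical; the estimator")
print("switches from the grid integral (Dhat1) to the density-ratio form")
print("(Dhat4) once both samples reach 75 observations.")
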