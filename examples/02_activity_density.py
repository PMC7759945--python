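"""Circular activity analysis of one simulated diel schedule.

Draws a bimodal (dawn/dusk) von Mises mixture — the typical duiker
pattern — and runs the single-species toolkit: kernel density,
trigonometric-sum cross-check, Hermans-Rasson uniformity test, circular
median, and the Rowcliffe activity level.
"""

import numpy as np

from dielcam.density import (
    activity_level,
    circular_median_hour,
    hermans_rasson_test,
    total_variation_distance,
    trig_sum_density,
    vm_kernel_density,
)
from dielcam.simulate import sample_mixture

rng = np.random.default_rng(42)
schedule = ((7.0, 5.0, 0.5), (17.0, 4.0, 0.3), (12.0, 1.5, 0.2))
times = sample_mixture(schedule, 400, rng)

kde = vm_kernel_density(times)
trig = trig_sum_density(times, order=3)
unif = hermans_rasson_test(times, n_boot=1000, seed=1)
act = activity_level(times, n_boot=1000, seed=2)

print(f"n = {times.size} events from a dawn/dusk bimodal schedule")
print(f"kernel mode           : {kde.mode_hour:.2f} h (kappa = {kde.params['kappa']:.2f})")
print(f"circular median       : {circular_median_hour(times):.2f} h")
print(f"Hermans-Rasson p      : {unif.p_value:.4f}  (p < 0.01 -> non-uniform schedule)")
print(f"kernel vs trig-sum TV : {total_variation_distance(kde, trig):.3f}  (agreement between methods)")
print(f"activity level        : {act.estimate:.3f}  CI [{act.ci_low:.3f}, {act.ci_high:.3f}]")
print()
print("The activity level is the fraction of the 24-h cycle spent active")
print("(mean detection rate over peak rate); ~0.5 here because the animal")
print("concentrates activity into two broad peaks.")
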