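"""Probabilistic spatial co-occurrence on a simulated station grid.

Simulates occupancy for three species — one pair sharing habitat (odds
ratio 5), one species independent — then tests every pair with the exact
hypergeometric model: p_lt (fewer shared stations than expected), p_gt
(more), standardised effect size, and the random/positive/negative call.
"""

import numpy as np

from dielcam.cooccur import pairwise_cooccurrence
from dielcam.simulate import SimulationConfig, SpeciesProfile, simulate_occupancy

species = (
    SpeciesProfile("red duiker", ((7.0, 4.0, 1.0),), 0.2, 0.45),
    SpeciesProfile("blue duiker", ((8.0, 4.0, 1.0),), 0.3, 0.55),
    SpeciesProfile("yellow-backed", ((20.0, 3.0, 1.0),), 0.1, 0.30),
)
association = np.array([
    [1.0, 5.0, 1.0],   # red and blue share habitat
    [5.0, 1.0, 1.0],
    [1.0, 1.0, 1.0],   # yellow-backed settles independently
])
cfg = SimulationConfig(
    n_sites=9, stations_per_site=35, days_per_station=40,
    species=species, association=association, seed=21,
)
presence = simulate_occupancy(cfg)
matrix = presence.drop(columns="site")

print(f"{matrix.shape[0]} stations; stations occupied per species:")
print(matrix.sum().to_string())
print()
table = pairwise_cooccurrence(matrix, alpha=0.05)
print(table.round(4).to_string(index=False))
print()
print("p_gt < 0.05 flags positive association (shared habitat preference);")
print("the red-blue pair recovers the induced odds ratio, the others are")
print("classified random. The effect size is (observed - expected shared")
print("stations) / N, comparable across studies.")
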