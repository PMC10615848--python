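"""Pairwise spike-train synchrony with the binned coefficient k(tau).

Generates spike-train pairs with a controlled shared fraction (the same
construction used to analyze dual cell-attached interneuron recordings)
and shows that k increases with the shared fraction.
"""

from gabawave.observables import sync_coefficient
from gabawave.synthetic import gen_spike_pairs

for shared in (0.0, 0.25, 0.5, 0.75, 1.0):
    raster = gen_spike_pairs(
        n_trains=2, rate=10.0, shared_fraction=shared, jitter_ms=1.0, seed=4
    )
    k = sync_coefficient(raster, tau=5.0)
    print(f"shared fraction {shared:4.2f} -> k = {k:.3f}")
print("-> k(tau) tracks the underlying common-input fraction; identical")
print("   trains give k = 1, independent trains sit near chance level.")
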