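"""Calibrate the fluorescent GABA sensor and invert a measured transient.

Builds a synthetic concentration-response titration from the published
sensor model (E_max = 0.175, K_d = 1.26 uM, n = 2) with 5% noise, fits the
Hill equation to it, and then converts a peak dF/F0 of 0.074 - the signal
observed during interictal events - into a GABA concentration.
"""

from gabawave.ephys import hill_fit, hill_inverse
from gabawave.synthetic import SENSOR_FIT, GeneratorSpec, gen_calibration_curve

conc, resp = gen_calibration_curve(GeneratorSpec(seed=1), noise_frac=0.05)
fit = hill_fit(conc, resp)
print(f"fitted sensor model: E_max={fit.e_max:.3f}, K_d={fit.k_d:.2f} uM, n={fit.n:.2f}")
print(f"(generator truth:    E_max={SENSOR_FIT.e_max}, K_d={SENSOR_FIT.k_d} uM, n={SENSOR_FIT.n:g})")

delta = hill_inverse(0.074, SENSOR_FIT)
print(f"a peak dF/F0 of 0.074 corresponds to a [GABA]e increase of {delta:.2f} uM")
print("-> the extracellular GABA wave preceding an interictal event is ~1.1 uM.")
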