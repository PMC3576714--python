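"""Invert a plant model: desired outputs -> stimulation amplitudes.

At each event the model output is a quadratic in the present amplitude, so
the required stimulation is a closed-form root, solved recursively through
the train (each solved amplitude feeds the next event's history).  The
round trip forward-predict -> invert recovers the original amplitudes.
"""

import numpy as np

import lvcontrol as lv

basis = lv.build_basis()
gt = lv.make_ground_truth_model("mixed", basis, noise_sd=0.05)
rng = np.random.default_rng(3)

# Fit a plant model from noisy RARIT data (as an experiment would).
spec = lv.TrainSpec(amplitude_mode="gaussian", amplitude_params=(150.0, 45.0),
                    seed=3)
trains = [lv.simulate_plant(gt, t, rng) for t in lv.generate_rarit(spec, rng)]
plant = lv.fit_trains(basis, trains).coefficients

# Round trip: forward-predict a fresh RARIT, invert the predictions.
probe = lv.generate_rarit(lv.TrainSpec(n_trains=1, amplitude_mode="gaussian",
                                       amplitude_params=(150.0, 45.0),
                                       seed=4), rng)[0]
desired = lv.predict_output(plant, basis, probe)
res = lv.invert_sequence(plant, basis, probe.times, desired)
rel = np.abs(res.amplitudes - probe.amplitudes) / probe.amplitudes
print(f"round trip over {probe.n_events} events: max relative amplitude "
      f"error {rel.max():.2e}, flags {res.flag_counts()}")

# Saturation: a target above the plant's reachable maximum is answered with
# the vertex amplitude and flagged, not an error.
sat = lv.invert_sequence(plant, basis, [0.0], [5.0])
print(f"unreachable target 5.0 mV -> amplitude {sat.amplitudes[0]:.1f} uA, "
      f"flag {sat.flags[0]}, achieved {sat.achieved_outputs[0]:.3f} mV")
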