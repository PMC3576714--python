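"""Full synthetic modeling-control protocol, controlled vs fixed stimulation.

Fits a trajectory model (upstream population-spike -> downstream response)
and a plant model (stimulation -> downstream response), then derives the
stimulation amplitudes (a DARIT) that make the stimulated pathway reproduce
the reference pathway's responses.  A fixed-amplitude arm at the same mean
intensity shows what is lost without the model.
"""

import lvcontrol as lv

for noise_sd in (0.0, 0.05):
    res = lv.run_endtoend(preset="mixed", noise_sd=noise_sd, seed=1)
    s = res.summary()
    print(f"noise_sd={noise_sd}:")
    print(f"  trajectory model mean train VAF {100*s['trajectory_mean_train_vaf']:.2f}%, "
          f"plant model {100*s['plant_mean_train_vaf']:.2f}%")
    print(f"  controlled NMSE {s['controlled_nmse_pct']:.3f}%  vs  "
          f"fixed-amplitude NMSE {s['fixed_nmse_pct']:.3f}%  "
          f"(mean DARIT amplitude {s['mean_darit_amplitude']:.1f} uA)")
    print(f"  solver flags: {s['flag_counts']}")
# Controlled NMSE ~0 without noise (the inverse is exact where feasible) and
# well below the fixed-amplitude NMSE with noise: the model-derived
# stimulation reproduces the reference dynamics, a constant cannot.
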