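"""Turn one EEG channel into a train of message departures.

Builds a 20 s synthetic channel (10 Hz bursts over 1/f background),
computes its complex-Morlet scalogram at 5-30 Hz, finds the prominent
power troughs at each frequency, and prints the departure counts and
mean inter-departure times.  Departures should be denser at higher
analysis frequencies.
"""

import numpy as np

import neurotraffic as nt

spec = nt.SynthSpec(n_subjects=1, n_channels=1, epochs_per_condition=1,
                    epoch_duration=20.0, seed=1)
rec = nt.generate_subject(spec, 0)
scg = nt.morlet_scalogram(rec.data[0, 0], rec.sample_interval)

print("frequency_hz  n_departures  mean_tau_samples  mean_tau_ms")
for si, freq in enumerate(scg.pseudo_frequencies):
    train = nt.detect_departures(
        scg.power[0, si], threshold_ratio=0.05,
        coi_halfwidth=int(scg.coi_halfwidth[si]),
    )
    tau = nt.inter_departure_times(train, rec.sample_interval)
    print(f"{freq:10.0f} {tau.n + 1:12d} {tau.intervals.mean():17.1f}"
          f" {tau.to_ms().mean():12.1f}")

print("\nEach row is one wavelet scale; tau is the time between successive")
print("scalogram troughs ('message departures') in digitization intervals.")
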