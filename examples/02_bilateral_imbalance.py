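"""Bilateral MF imbalance: segmental ratios and the global scores.

Commands the right-side electrodes to run 10% above the left at every
lumbar level, then checks that the segmental imbalance reads ~+10% and
that the global scores combine the levels as magnitude (uncompensated)
and signed mean (compensated).
"""

from emgfatigue import (EMGGenSpec, bandpass_filter, compute_imbalance,
                        detect_artifacts, generate_emg, mf_series)
from emgfatigue.simulate import ChannelSpec

overrides = {f"{lvl}_right": ChannelSpec(imf0=110.0, slope=-0.22)
             for lvl in ("L1", "L2", "L5")}
rec = generate_emg(EMGGenSpec(imf0=100.0, slope=-0.20, seed=17,
                              channel_overrides=overrides))
filt = bandpass_filter(rec)
series = mf_series(filt, mask=detect_artifacts(filt))
res = compute_imbalance(series)

for lvl in ("L1", "L2", "L5"):
    print(f"segmental {lvl}: {res.segmental[lvl]:+6.2f} %  "
          f"(n = {res.n_ratio_samples[lvl]} epoch ratios)")
print(f"uncompensated (magnitude): {res.uncompensated:6.2f} %")
print(f"compensated   (signed):    {res.compensated:+6.2f} %")
print(f"transform: {res.transform}")
print("\nAll three levels were commanded 10% right-dominant, so each segmental")
print("score is ~+10%, and with no cancellation across levels the compensated")
print("score equals the uncompensated one. Opposite-signed level imbalances")
print("would shrink the compensated score but leave the uncompensated intact.")
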