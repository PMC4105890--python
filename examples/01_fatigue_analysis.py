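"""Single-recording fatigue analysis: from raw EMG to IMF and MF slope.

Simulates a 30 s sustained-contraction recording whose median frequency
declines at a known rate, runs the full analysis chain (band-pass,
artefact screen, MF series, linear regression), and prints the fatigue
descriptors next to the generator's ground truth.
"""

from emgfatigue import EMGGenSpec, analyze_recording, generate_emg

rec = generate_emg(EMGGenSpec(imf0=100.0, slope=-0.30, seed=7))
result, series, imbalance = analyze_recording(rec, metadata={"subject": "demo", "day": 1})

print(f"MF series: {len(series.times)} values per channel at "
      f"{1 / (series.times[1] - series.times[0]):g} Hz over "
      f"[{series.times[0] - 0.25:g}, {series.times[-1] + 0.25:g}] s")
print(f"{'channel':<10} {'IMF (Hz)':>9} {'slope (Hz/s)':>13} {'norm (%/s)':>11} {'R^2':>6}")
for ch in series.channels:
    fit = result.channels[ch]
    print(f"{ch:<10} {fit.imf:9.2f} {fit.slope:13.3f} {fit.slope_norm:11.3f} "
          f"{fit.r_squared:6.3f}")
print(f"{'all (mean)':<10} {result.overall['imf']:9.2f} "
      f"{result.overall['slope_hzs']:13.3f} {result.overall['slope_norm']:11.3f}")
print(f"most negative electrode: {result.most_negative.channel} "
      f"({result.most_negative.slope:.3f} Hz/s)")
print("\nGround truth was IMF = 100 Hz, slope = -0.30 Hz/s on every channel: the")
print("estimated IMF should sit within a fraction of a Hz and the slope within a")
print("few thousandths of a Hz/s. A slope of -0.30 Hz/s means the spectral center")
print("of the signal drops 0.3 Hz every second - the electromyographic signature")
print("of accumulating muscle fatigue under load.")
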