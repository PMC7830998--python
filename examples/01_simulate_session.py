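"""Generate one synthetic study session and look at its ground truth.

A session is three 15-min trials (baseline, simulated autonomous drive,
recovery); the drive splits into a calm part A, a 1-min transition and a
dynamic part B.  Here one nausea episode (amplitude gain 2.5) is injected
into part B, with button presses leading it by about a minute.
"""

from eggms import EpisodeSpec, SimConfig, generate_session

episode = EpisodeSpec(start_s=1440.0, end_s=1740.0, amp_gain=2.5,
                      freq_shift_cpm=0.5, press_rate_per_min=3.0)
config = SimConfig(seed=42, episodes=(episode,), noise_sd_uv=15.0)
bundle = generate_session(config)

print("segments:", {k: v for k, v in bundle.segments.named().items()})
print(f"EGG: {bundle.egg.n_channels} channels x {bundle.egg.n_samples} samples "
      f"at {bundle.egg.acq.fs} Hz")
print(f"button presses: {len(bundle.buttons)} "
      f"(first at {bundle.buttons.timestamps[0]:.0f} s; the episode starts at "
      f"{episode.start_s:.0f} s, so the first report leads it)")
g1 = bundle.gsr.segment_stats(*bundle.segments.trial1)[0]
g3 = bundle.gsr.segment_stats(*bundle.segments.trial3)[0]
print(f"GSR mean rises {g1:.2f} -> {g3:.2f} uS across trials (arousal trend)")
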