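"""Enhance a night and detect its acoustic events.

Runs adaptive spectral subtraction and the histogram-threshold event
segmenter on a synthetic night, then compares the detections against the
generator's ground truth.  Intensities and SNRs are on the calibrated dB
scale; at these study conditions nearly every planted event is recovered
with boundaries within a few tens of milliseconds.
"""

from snoredetect import NightSpec, SnoreBlock, NoiseEventSpec, PipelineConfig, generate_night
from snoredetect.pipeline import detect_events, enhance_signal

config = PipelineConfig()
spec = NightSpec(
    duration_s=300.0,
    snore_blocks=[SnoreBlock(count=50, period_mean_s=4.0, intensity_range_db=(55, 65))],
    noise_events=[NoiseEventSpec("cough", 5, (55, 62))],
    seed=11,
)
signal, truth = generate_night(spec)

clean = enhance_signal(signal, config)
events, track = detect_events(clean, config)

print(f"planted {len(truth)} events, detected {len(events)}")
matched = 0
for t in truth:
    overlaps = [ev for ev in events if min(ev.end_s, t.offset_s) - max(ev.start_s, t.onset_s) > 0]
    matched += bool(overlaps)
print(f"{matched}/{len(truth)} planted events overlapped by a detection")
print("first five detections (onset, offset, intensity, SNR):")
for ev in events[:5]:
    print(f"  {ev.start_s:7.2f}-{ev.end_s:7.2f} s  {ev.intensity_db:5.1f} dB  SNR {ev.snr_db:5.1f} dB")
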