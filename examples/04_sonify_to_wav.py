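"""Render one sit-to-stand pattern to an 8 s stimulus clip.

The full model (combo SJPF) maps CoM speed to flute blowing pressure,
distance-from-stand to an ascending A-major scale (A4..A5), shank jerk
to a 1-10x pitch multiplier and each movement stoppage to a bell strike,
then writes a 48 kHz / 24-bit stereo WAV.
"""

from pathlib import Path

from sts_sonify import PipelineConfig, default_pattern_specs, run_pipeline

out = Path("scratch/example_clips")
cfg = PipelineConfig.default()
spec = default_pattern_specs(seed=0)["P6"]

for combo in ("SP", "SJPF"):
    res = run_pipeline(spec, cfg, out_dir=out / combo, combo=combo, seed=0)
    print(f"combo {combo}: wrote {res.wav_path} "
          f"({res.manifest['n_freezes']} bell strikes, "
          f"{res.manifest['n_jerk_crossings']} jerk crossings)")

# SP (the fixed model component) carries only the melody and loudness;
# SJPF additionally glitches the pitch post-rise and rings the bell on
# stopping - listen to both to hear why SJPF disambiguates P4/P5/P6.
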