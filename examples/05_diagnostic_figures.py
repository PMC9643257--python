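"""Render the diagnostic figures for a small synthetic dataset.

Writes a waveform plot, a per-frame PSD with the 26 SSC frequencies marked,
and the per-band mean-SSC class-comparison plot under examples_output/.
"""

import os

from sscswallow import (Dataset, FeatureConfig, GeneratorConfig,
                        extract_features, generate_dataset)
from sscswallow.report import plot_band_sscs, plot_frame_psd, plot_waveform

out = "examples_output"
os.makedirs(out, exist_ok=True)

ds = generate_dataset(20, 8, GeneratorConfig(seed=0))
clip = ds.clips[-1]  # an aspirating clip
plot_waveform(clip, f"{out}/waveform.png")
centroids = plot_frame_psd(clip, frame_index=5, config=FeatureConfig(),
                           path=f"{out}/psd_with_sscs.png")
print(f"frame 5 of {clip.clip_id}: {len(centroids)} SSC markers, "
      f"top centroid {centroids[-1]:.0f} Hz")

feats = Dataset.from_feature_vectors(
    [extract_features(c, FeatureConfig()) for c in ds.clips])
data = plot_band_sscs(feats.to_frame(), f"{out}/band_sscs.png")
print(f"band plot: {data[0].shape[0]} normal vs {data[1].shape[0]} aspirating "
      "clips across 26 bands; the top band separates the classes")
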