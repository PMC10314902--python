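"""Preprocess a radiograph-like image and encode it into patch tokens.

The 64 x 64 grayscale input is resized/replicated/normalised with
ImageNet statistics and passed through a tiny randomly initialised
vision transformer: 16 patches of 16 x 16 pixels become 16 latent tokens.
"""

import numpy as np

from icufusion import BackboneConfig, ImageSpec, VisionBackbone, preprocess_image, zero_image

rng = np.random.default_rng(0)
spec = ImageSpec(height=64, width=64, patch_size=16)

raw = rng.random((128, 128))  # any grayscale input; resized to spec
img = preprocess_image(raw, spec)
print(f"preprocessed image: {img.shape} (3-channel, ImageNet-normalised)")

backbone = VisionBackbone(spec, BackboneConfig(depth=2, dim=64, heads=4), rng)
block = backbone.encode_image(img)
print(f"token block: {block.count} tokens of width {block.D} "
      f"(N = (64/16)^2 = {spec.n_tokens}), modality={block.modality!r}")

# 'image absent' is the canonical zero tensor in normalised space:
absent = backbone.encode_image(zero_image(img))
print("zero-image tokens identical for any input shape:",
      np.array_equal(absent.tokens.data,
                     backbone.encode_image(zero_image(preprocess_image(rng.random((64, 64)), spec))).tokens.data))
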