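"""Dataset-size ladder: how segmentation quality grows with training images.

Trains one model from scratch per training-set size on prefixes of a fixed
synthetic pool and evaluates each on one fixed domain-shifted held-out set —
the structure of a dataset-size scaling table.  Expect the fruit-class DSC
rows to increase with n (small runs are noisy).
"""

import numpy as np

import strawseg as ss
from strawseg.dataset import SamplePair, mask_to_indices


def to_pairs(samples):
    return [SamplePair(image=s.image, target=mask_to_indices(s.mask), id=str(i))
            for i, s in enumerate(samples)]


size = (64, 64)
ranges = ss.RandomizationRanges()
shift = ss.DomainShiftParams()
pool = to_pairs(ss.generate_samples(320, ranges, seed=11, size=size))
eval_pairs = to_pairs(ss.generate_samples(30, ranges, seed=12, size=size,
                                          shift=shift))
target_pool = ss.generate_samples(30, ranges, seed=13, size=size, shift=shift)
target_images = np.stack([s.image for s in target_pool]).astype(np.float32) / 255.0

config = ss.TrainConfig(epochs=12, batch_size=8, seed=0, eval_every=0)
result = ss.scaling_experiment([80, 320], ss.tiny_config(size), pool,
                               eval_pairs, ss.LossWeights(), config,
                               target_images=target_images, progress=True)
print("\n" + result.to_table())
print("\nEach row is an independently trained model; DSC is micro-averaged")
print("over the same fixed shifted evaluation set.")
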