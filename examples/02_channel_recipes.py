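"""The four channel-recipe strategies.

Each ensemble member views the multiband pattern through its own ordered
list of source-band positions; diversity of these views is what the
ensemble feeds on.
"""

import numpy as np

from bandfuse import (make_grayset_recipes, sample_bagged_multichannel,
                      sample_random_one_rgb, sample_random_triplet)

n_bands = 13           # a Sentinel-2-style band count
rgb = [3, 2, 1]        # positions of the red/green/blue bands

gray = make_grayset_recipes(n_bands)
print(f"grayset: {len(gray)} deterministic views, e.g. {gray[0].indices}, "
      f"{gray[12].indices}")

r = sample_random_triplet(n_bands, 1)
print(f"random triplet (seed 1): {r.indices}")

r1 = sample_random_one_rgb(n_bands, rgb, 1)
print(f"random-one-RGB (seed 1): {r1.indices}  "
      f"(guaranteed >=1 index from {rgb})")

bag = sample_bagged_multichannel(n_bands, 13, 1, first_rgb=rgb)
print(f"bagged 13-channel (seed 1): {bag.indices}")
print("repeats are allowed by design: draws are with replacement, and an")
print("all-red triplet is as legal as any other view.")
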