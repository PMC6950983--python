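"""Shared test helpers."""
import numpy as np


def random_instance_mask(rng, shape=(64, 64), n_cells=(2, 6), radius=(4, 9)):
    """Disjoint random blobs labelled 1..K (for metric tests)."""
    from skimage.draw import disk

    h, w = shape
    mask = np.zeros(shape, dtype=np.int32)
    n = int(rng.integers(*n_cells))
    lab = 0
    for _ in range(40):
        if lab >= n:
            break
        r = rng.uniform(*radius)
        cy, cx = rng.uniform(r, h - r), rng.uniform(r, w - r)
        rr, cc = disk((cy, cx), r, shape=shape)
        if (mask[rr, cc] != 0).any():
            continue
        lab += 1
        mask[rr, cc] = lab
    return mask
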