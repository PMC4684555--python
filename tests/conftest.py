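import numpy as np
import pytest

from ctbrain import extract_brain, generate_phantom, small_params, small_spec


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 128x128 phantom (seed 1)."""
    return generate_phantom(small_spec(), seed=1)


@pytest.fixture(scope="session")
def small_extraction(small_phantom):
    """Pipeline output on the small phantom, shared across tests."""
    return extract_brain(small_phantom.volume, small_params())


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; no calls into ctbrain internals)

DIRS = {
    "up": (-1, 0), "left_up": (-1, -1), "left": (0, -1),
    "left_down": (1, -1), "down": (1, 0), "right_down": (1, 1),
    "right": (0, 1), "right_up": (-1, 1),
}


def walk_ray(skull, r, c, direction):
    """Step-by-step ray walk; None when the ray exits the image."""
    dr, dc = DIRS[direction]
    if skull[r, c]:
        return 0
    nr, nc = skull.shape
    steps = 0
    while True:
        r, c = r + dr, c + dc
        if not (0 <= r < nr and 0 <= c < nc):
            return None
        steps += 1
        if skull[r, c]:
            return steps


def naive_dmap(skull, policy="any"):
    """Per-pixel 8-ray walker; quadratic and obviously correct."""
    nr, nc = skull.shape
    out = np.zeros((nr, nc), dtype=int)
    for r in range(nr):
        for c in range(nc):
            if skull[r, c]:
                continue
            dists = [walk_ray(skull, r, c, d) for d in DIRS]
            if policy == "any":
                if any(d is None for d in dists):
                    continue
                out[r, c] = sum(dists)
            else:
                measurable = [d for d in dists if d is not None]
                out[r, c] = sum(measurable) if measurable else 0
    return out


def brute_morph(mask, op, iterations):
    """Erosion/dilation as per-pixel min/max over the 3x3 neighbourhood,
    with outside-image pixels treated as background."""
    mask = np.asarray(mask, dtype=bool)
    for _ in range(iterations):
        padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
        padded[1:-1, 1:-1] = mask
        out = np.empty_like(mask)
        for r in range(mask.shape[0]):
            for c in range(mask.shape[1]):
                neigh = padded[r:r + 3, c:c + 3]
                out[r, c] = neigh.all() if op == "erode" else neigh.any()
        mask = out
    return mask


@pytest.fixture(scope="session")
def oracle():
    class Oracle:
        walk_ray = staticmethod(walk_ray)
        naive_dmap = staticmethod(naive_dmap)
        brute_morph = staticmethod(brute_morph)
    return Oracle
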