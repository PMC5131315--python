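"""Independent brute-force oracles for pair counting under periodic
boundaries.

Distances are computed by explicit enumeration of all 27 periodic images
(a genuinely different algorithm from the production round-to-nearest
minimum-image code), so agreement is a meaningful cross-check.
"""

import itertools

import numpy as np

_SHIFTS = np.array(list(itertools.product((-1.0, 0.0, 1.0), repeat=3)))


def brute_min_image_dist(pos_a: np.ndarray, pos_b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """(len(a), len(b)) minimum distances over all 27 periodic images.

    Coordinates are first wrapped into the primary cell so that one image
    shell suffices regardless of how far outside the box they sit.
    """
    box = np.asarray(box, float)
    pos_a = np.mod(pos_a, box)
    pos_b = np.mod(pos_b, box)
    best = np.full((len(pos_a), len(pos_b)), np.inf)
    for shift in _SHIFTS:
        delta = pos_a[:, None, :] - (pos_b[None, :, :] + shift * box)
        d = np.sqrt((delta**2).sum(axis=2))
        best = np.minimum(best, d)
    return best


def brute_count_within(pos_a, pos_b, box, cutoff) -> np.ndarray:
    """Per A atom, number of B atoms within cutoff (min-image)."""
    return (brute_min_image_dist(pos_a, pos_b, box) <= cutoff).sum(axis=1)


def brute_group_counts(pos, groups, probe_idx, box, cutoff) -> np.ndarray:
    """Per group, number of probe atoms whose min distance to any group
    atom is within the cutoff (probe counted once per group)."""
    out = np.empty(len(groups), dtype=int)
    for gi, g in enumerate(groups):
        d = brute_min_image_dist(pos[g], pos[probe_idx], box)
        out[gi] = int((d.min(axis=0) <= cutoff).sum())
    return out
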