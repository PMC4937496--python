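"""The 13 unique 3D texture directions.

The 26-neighborhood of a voxel contains 13 direction pairs (each offset and
its negation describe the same undirected direction); texture matrices are
built per direction and their statistics averaged over all 13.
"""

from __future__ import annotations

import itertools


def texture_directions() -> tuple[tuple[int, int, int], ...]:
    """All offsets in {-1,0,1}^3 \\ {0} modulo sign: first nonzero component positive."""
    dirs = []
    for off in itertools.product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        first = next(c for c in off if c != 0)
        if first > 0:
            dirs.append(off)
    return tuple(dirs)


TEXTURE_DIRECTIONS = texture_directions()
assert len(TEXTURE_DIRECTIONS) == 13


def paired_slices(offset: tuple[int, int, int], shape: tuple[int, int, int]):
    """Slices (s1, s2) such that arr[s1] and arr[s2] are voxel pairs at `offset`."""
    s1, s2 = [], []
    for o, n in zip(offset, shape):
        o = int(o)
        if o >= 0:
            s1.append(slice(0, n - o))
            s2.append(slice(o, n))
        else:
            s1.append(slice(-o, n))
            s2.append(slice(0, n + o))
    return tuple(s1), tuple(s2)
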