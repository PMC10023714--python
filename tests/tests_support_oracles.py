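"""Independent brute-force oracles used by the end-to-end checks."""

import numpy as np

import retinamosaic as rm


def brute_pair_counts(points: np.ndarray, r_max: float, bw: float) -> np.ndarray:
    """Ordered-pair annulus tallies from the full O(n^2) distance matrix."""
    n_bins = int(round(r_max / bw))
    counts = np.zeros(n_bins, dtype=int)
    n = len(points)
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    iu = ~np.eye(n, dtype=bool)
    for dist in d[iu]:
        if dist < r_max:
            counts[int(dist // bw)] += 1
    return counts


def sampled_circle_crossings(morph: rm.Morphology, r: float,
                             samples_per_edge: int = 400) -> int:
    """Sign changes of (radial distance - r) along densely sampled edges."""
    soma = morph.soma_xy
    total = 0
    for pi, ci in morph.edges():
        p0 = morph.xyz[pi, :2] - soma
        p1 = morph.xyz[ci, :2] - soma
        t = np.linspace(0.0, 1.0, samples_per_edge)
        pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        d = np.hypot(pts[:, 0], pts[:, 1]) - r
        total += int(np.sum(np.diff(np.sign(d)) != 0))
    return total
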