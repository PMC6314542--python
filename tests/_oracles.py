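"""Independent brute-force oracles used to cross-check the implementation."""

import heapq

import numpy as np


def brute_force_watershed(values: np.ndarray, seeds, mask: np.ndarray) -> np.ndarray:
    """Meyer flooding by explicit priority queue (ascending value, then age).

    Independent of the library watershed; on images with unique pixel
    values the catchment decomposition is unambiguous.
    """
    labels = np.zeros(values.shape, dtype=int)
    heap = []
    age = 0
    for i, (r, c) in enumerate(seeds, start=1):
        heapq.heappush(heap, (values[r, c], age, r, c, i))
        age += 1
    while heap:
        _, _, r, c, lab = heapq.heappop(heap)
        if labels[r, c]:
            continue
        labels[r, c] = lab
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if (
                    0 <= rr < values.shape[0]
                    and 0 <= cc < values.shape[1]
                    and mask[rr, cc]
                    and not labels[rr, cc]
                ):
                    heapq.heappush(heap, (values[rr, cc], age, rr, cc, lab))
                    age += 1
    return labels


def covariance_eigenvalues_2x2(coords: np.ndarray) -> tuple[float, float]:
    """Eigenvalues of the population covariance via the quadratic formula."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    a = float((centered[:, 0] ** 2).mean())
    b = float((centered[:, 0] * centered[:, 1]).mean())
    c = float((centered[:, 1] ** 2).mean())
    disc = np.sqrt(((a - c) / 2) ** 2 + b**2)
    return (a + c) / 2 + disc, (a + c) / 2 - disc
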