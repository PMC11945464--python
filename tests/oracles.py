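"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths under test: the OLS oracle solves
the normal equations voxel by voxel, and the cluster oracle is a plain BFS
flood fill over an explicit neighbor list.
"""

from collections import deque

import numpy as np


def ols_normal_equations(X: np.ndarray, y: np.ndarray):
    """Closed-form OLS for one voxel: beta = (X'X)^-1 X'y, plus residual SS."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _neighbor_offsets(connectivity: int):
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    return offsets


def flood_fill_components(binary: np.ndarray, connectivity: int):
    """Connected components of a 3D binary field as a list of voxel-index sets."""
    shape = binary.shape
    offsets = _neighbor_offsets(connectivity)
    seen = np.zeros(shape, dtype=bool)
    components = []
    for start in np.argwhere(binary):
        start = tuple(start)
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        component = set()
        while queue:
            vox = queue.popleft()
            component.add(vox)
            for off in offsets:
                nb = tuple(v + o for v, o in zip(vox, off))
                if any(c < 0 or c >= s for c, s in zip(nb, shape)):
                    continue
                if binary[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        components.append(frozenset(component))
    return components
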