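"""Independent reference implementations used only by the test suite.

The Bellman-Ford relaxation below shares nothing with the package's
Dijkstra machinery beyond the move-cost model it is checking: it loops
naively over cells until no update occurs, which is exact on any graph
with non-negative edge weights.
"""

import numpy as np

from demicwave.terrain import DIRECTIONS, ToblerParams, _move_times


def bellman_ford_times(dem, origin_rc, params=ToblerParams()):
    """Exhaustive shortest-time search by repeated relaxation."""
    dists, times = _move_times(dem, params)
    nr, nc = dem.shape
    t = np.full((nr, nc), np.inf)
    t[origin_rc] = 0.0
    changed = True
    while changed:
        changed = False
        for r in range(nr):
            for c in range(nc):
                if not np.isfinite(t[r, c]):
                    continue
                for d, (dr, dc) in enumerate(DIRECTIONS):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < nr and 0 <= cc < nc):
                        continue
                    mt = times[d][r, c]
                    if not np.isfinite(mt):
                        continue
                    nt = t[r, c] + mt
                    if nt < t[rr, cc] - 1e-15:
                        t[rr, cc] = nt
                        changed = True
    return t, dists, times


def oracle_backlinks_and_lengths(dem, origin_rc, params=ToblerParams()):
    """Times by Bellman-Ford plus backlink/length by the canonical rule.

    The canonical predecessor of a cell is the first direction in the
    fixed order whose neighbour attains the optimal time within 1e-9
    relative tolerance; lengths follow the backlink chain. Implemented
    with plain loops, independently of the package's vectorised pass.
    """
    t, dists, times = bellman_ford_times(dem, origin_rc, params)
    nr, nc = dem.shape
    opposite = (5, 6, 7, 8, 1, 2, 3, 4)
    backlink = np.zeros((nr, nc), dtype=int)
    for r in range(nr):
        for c in range(nc):
            if (r, c) == tuple(origin_rc) or not np.isfinite(t[r, c]):
                continue
            best, best_code = np.inf, 0
            for code in range(1, 9):
                dr, dc = DIRECTIONS[code - 1]
                pr, pc = r + dr, c + dc
                if not (0 <= pr < nr and 0 <= pc < nc):
                    continue
                mt = times[opposite[code - 1] - 1][pr, pc]
                if not np.isfinite(mt) or not np.isfinite(t[pr, pc]):
                    continue
                cand = t[pr, pc] + mt
                if best == np.inf or cand < best - 1e-9 * max(1.0, best):
                    best, best_code = cand, code
            backlink[r, c] = best_code
    length = np.full((nr, nc), np.nan)
    length[tuple(origin_rc)] = 0.0
    for idx in np.argsort(t, axis=None):
        r, c = divmod(int(idx), nc)
        code = backlink[r, c]
        if code == 0 or not np.isfinite(t[r, c]):
            continue
        dr, dc = DIRECTIONS[code - 1]
        pr, pc = r + dr, c + dc
        length[r, c] = length[pr, pc] + dists[opposite[code - 1] - 1][pr, pc]
    return t, backlink, length
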