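"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def brute_force_crossing(conc, resp, threshold, direction, scale,
                         n_grid=100_001):
    """Dense-grid scan of the piecewise-linear interpolant: first grid segment
    that meets the threshold in the requested direction."""
    x = np.log10(conc) if scale == "log" else np.asarray(conc, dtype=float)
    # include the knots so no dense cell straddles a kink of the interpolant
    grid = np.unique(np.concatenate([np.linspace(x[0], x[-1], n_grid), x]))
    vals = np.interp(grid, x, np.asarray(resp, dtype=float))
    if vals[0] == threshold:
        hit = grid[0]
    else:
        if direction == "up":
            idx = np.where((vals[:-1] < threshold) & (vals[1:] >= threshold))[0]
        else:
            idx = np.where((vals[:-1] > threshold) & (vals[1:] <= threshold))[0]
        if idx.size == 0:
            return None
        i = idx[0]
        t = (threshold - vals[i]) / (vals[i + 1] - vals[i])
        hit = grid[i] + t * (grid[i + 1] - grid[i])
    return 10 ** hit if scale == "log" else hit
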