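"""Brute-force dispersion-threshold oracle for cross-checking fixation parsing.

Independent of the package implementation: for each candidate start index it
recomputes the window dispersion from scratch over the full window (no
incremental min/max bookkeeping) and grows until the dispersion breaks.
Because dispersion is monotone under window growth, a maximal window under
the threshold that also covers the minimum duration is a fixation.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-9


def idt_bruteforce(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    min_duration_s: float,
    max_dispersion: float,
) -> list[tuple[int, int]]:
    """Return fixations as (start_index, end_index) inclusive pairs."""
    n = len(t)
    fixations: list[tuple[int, int]] = []
    i = 0
    while i < n:
        best = None
        for j in range(i, n):
            disp = (np.max(x[i:j + 1]) - np.min(x[i:j + 1])) + (
                np.max(y[i:j + 1]) - np.min(y[i:j + 1])
            )
            if disp > max_dispersion + _EPS:
                break
            best = j
        if best is not None and t[best] - t[i] >= min_duration_s - _EPS:
            fixations.append((i, best))
            i = best + 1
        else:
            i += 1
    return fixations
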