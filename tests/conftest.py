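"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive, literal transcriptions of the
method definitions (explicit slicing, double loops) kept independent of
the package's vectorised implementations.
"""

from __future__ import annotations

import numpy as np
import pytest


def discriminant_oracle(window, gap_width: int, th1: float, th2: float) -> bool:
    """Literal transcription of the two-condition particle discriminant.

    Core and periphery blocks are sliced directly from the window layout:
    a 3x3 core at the centre and eight blocks in the outermost 2-px band.
    """
    win = np.asarray(window, dtype=float)
    g = gap_width
    side = 7 + 2 * g
    assert win.shape == (side, side)
    half = 3 + g
    core = win[g + 2 : g + 5, g + 2 : g + 5].mean()
    blocks = [
        win[0:2, 0:2],                                  # top-left corner
        win[0:2, half - 1 : half + 2],                  # top edge
        win[0:2, side - 2 : side],                      # top-right corner
        win[half - 1 : half + 2, side - 2 : side],      # right edge
        win[side - 2 : side, side - 2 : side],          # bottom-right corner
        win[side - 2 : side, half - 1 : half + 2],      # bottom edge
        win[side - 2 : side, 0:2],                      # bottom-left corner
        win[half - 1 : half + 2, 0:2],                  # left edge
    ]
    if not core > th1:
        return False
    return all(core - b.mean() > th2 for b in blocks)


def similarity_oracle(image, template_pixels, row: int, col: int) -> float:
    """Double-loop transcription of the normalized L1 template similarity."""
    tpl = np.asarray(template_pixels)
    s = tpl.shape[0]
    total = 0.0
    for i in range(s):
        for j in range(s):
            total += abs(float(image[row + i, col + j]) - float(tpl[i, j]))
    return 1.0 - total / (255.0 * s * s)


@pytest.fixture(scope="session")
def pattern_g2():
    from fppl.pattern import build_pattern

    return build_pattern(2)


@pytest.fixture(scope="session")
def dot_panel():
    from fppl.synth import make_dot_panel

    return make_dot_panel()


@pytest.fixture(scope="session")
def gradient_fixture():
    from fppl.synth import make_gradient_band_image

    return make_gradient_band_image()
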