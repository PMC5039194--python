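import numpy as np
import pytest

from phenorosette.synthetic import Treatment, generate_design


def disk_mask(radius: int, pad: int = 5) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def ellipse_mask(a: int, b: int, pad: int = 5) -> np.ndarray:
    """Axis-aligned filled ellipse with semi-axes a (x) and b (y)."""
    ny, nx = 2 * (b + pad) + 1, 2 * (a + pad) + 1
    yy, xx = np.mgrid[:ny, :nx]
    return ((xx - (a + pad)) / a) ** 2 + ((yy - (b + pad)) / b) ** 2 <= 1.0


@pytest.fixture()
def small_design():
    return generate_design(
        ["Col-0", "C24"],
        [Treatment("control", 0), Treatment("salt", 100)],
        3,
        list(range(8)),
        seed=1,
    )
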