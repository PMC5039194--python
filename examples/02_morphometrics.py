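"""Shape traits on analytic masks with known geometry.

A rasterised disk should be maximally round, compact and rotationally
symmetric; a 4:1 ellipse should show slenderness ~4 and eccentricity
sqrt(15)/4 ~ 0.968.
"""

import numpy as np

from phenorosette.morpho import compute_morphometrics


def disk(r, pad=5):
    n = 2 * (r + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    return (yy - r - pad) ** 2 + (xx - r - pad) ** 2 <= r**2


def ellipse(a, b, pad=5):
    ny, nx = 2 * (b + pad) + 1, 2 * (a + pad) + 1
    yy, xx = np.mgrid[:ny, :nx]
    return ((xx - a - pad) / a) ** 2 + ((yy - b - pad) / b) ** 2 <= 1.0


for name, mask in [("disk r=60", disk(60)), ("ellipse 120x30", ellipse(120, 30))]:
    t = compute_morphometrics(mask)
    print(f"{name}: area={t.area_px} perimeter={t.perimeter_px:.1f} "
          f"roundness={t.roundness:.3f} compactness={t.compactness:.3f} "
          f"rms={t.rms:.3f} ecc={t.eccentricity:.3f} slenderness={t.slenderness:.3f}")

# roundness = 4*pi*area/perimeter^2 (1 = circle); compactness = solidity;
# rms = rotational mass symmetry over 36 angular sectors (1 = isotropic);
# slenderness = moment-ellipse axis ratio. The ellipse's eccentricity matches
# the closed form sqrt(1 - (30/120)^2) = 0.968.
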