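"""Tabulated X-ray atomic form factors (Cromer-Mann 4-Gaussian fits).

f(s) = sum_k a_k exp(-b_k s^2) + c with s = sin(theta)/lambda = |q| / 4 pi.

Coefficients for the handful of elements common in protein models; the
pseudo-element ``X`` has a constant unit form factor and is intended for
toy-model tests where a flat scatterer makes closed forms exact.
"""

from __future__ import annotations

import numpy as np

# element -> (a1..a4, b1..b4, c)
CROMER_MANN: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = {
    "H": ((0.489918, 0.262003, 0.196767, 0.049879),
          (20.6593, 7.74039, 49.5519, 2.20159), 0.001305),
    "C": ((2.31000, 1.02000, 1.58860, 0.865000),
          (20.8439, 10.2075, 0.568700, 51.6512), 0.215600),
    "N": ((12.2126, 3.13220, 2.01250, 1.16630),
          (0.005700, 9.89330, 28.9975, 0.582600), -11.5290),
    "O": ((3.04850, 2.28680, 1.54630, 0.867000),
          (13.2771, 5.70110, 0.323900, 32.9089), 0.250800),
    "P": ((6.43450, 4.17910, 1.78000, 1.49080),
          (1.90670, 27.1570, 0.526000, 68.1645), 1.11490),
    "S": ((6.90530, 5.20340, 1.43790, 1.58630),
          (1.46790, 22.2151, 0.253600, 56.1720), 0.866900),
    "FE": ((11.7695, 7.35730, 3.52220, 2.30450),
           (4.76110, 0.307200, 15.3535, 76.8805), 1.03690),
    "ZN": ((14.0743, 7.03180, 5.16520, 2.41000),
           (3.26550, 0.233300, 10.3163, 58.7097), 1.30410),
}


def form_factor(element: str, q_norm: np.ndarray) -> np.ndarray:
    """Atomic form factor evaluated at |q| (in 1/Angstrom, q = 2 pi / d).

    Raises KeyError-like ValueError naming the element if it is unknown.
    """
    q_norm = np.asarray(q_norm, dtype=float)
    key = element.strip().upper()
    if key == "X":
        return np.ones_like(q_norm)
    try:
        a, b, c = CROMER_MANN[key]
    except KeyError:
        raise ValueError(f"no form-factor coefficients for element {element!r}") from None
    s2 = (q_norm / (4.0 * np.pi)) ** 2
    f = np.full_like(q_norm, c)
    for ak, bk in zip(a, b):
        f += ak * np.exp(-bk * s2)
    return f
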