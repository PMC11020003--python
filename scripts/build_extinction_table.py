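"""Regenerate the bundled synthetic haemoglobin absorption table.

Writes ``src/drsmargin/data/hemoglobin_extinction_synthetic.csv``: absorption
coefficients (mm^-1) of fully oxygenated / fully deoxygenated whole blood on a
1 nm grid over 440-1010 nm. The curves are a synthetic, physically motivated
approximation built by monotone-cubic interpolation through anchor points at
the known band positions (oxy Q-bands at 542/577 nm, deoxy band at 555 nm,
the deoxy 760 nm bump, the ~800 nm isosbestic crossing); they reproduce the
qualitative spectral contrast the generator needs, not any published table.

Run from the repository root:  python scripts/build_extinction_table.py
"""

from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

# wavelength (nm), mu_a oxy blood (mm^-1), mu_a deoxy blood (mm^-1)
ANCHORS = [
    (440, 10.0, 16.0),
    (450, 6.8, 10.4),
    (460, 4.0, 6.5),
    (470, 2.6, 4.2),
    (480, 1.75, 2.9),
    (490, 1.35, 2.2),
    (500, 1.25, 1.85),
    (510, 1.45, 1.85),
    (520, 1.95, 2.0),
    (530, 2.8, 2.35),
    (535, 3.05, 2.5),
    (542, 3.35, 2.75),
    (548, 2.8, 2.9),
    (555, 2.15, 3.05),
    (560, 1.95, 3.0),
    (565, 2.1, 2.9),
    (570, 2.7, 2.75),
    (577, 3.45, 2.4),
    (585, 2.4, 1.9),
    (590, 1.45, 1.55),
    (600, 0.32, 0.95),
    (620, 0.06, 0.45),
    (640, 0.03, 0.28),
    (660, 0.018, 0.17),
    (680, 0.016, 0.12),
    (700, 0.018, 0.095),
    (720, 0.022, 0.085),
    (740, 0.026, 0.11),
    (760, 0.032, 0.13),
    (780, 0.040, 0.060),
    (800, 0.047, 0.047),
    (850, 0.058, 0.040),
    (900, 0.062, 0.042),
    (940, 0.066, 0.045),
    (1000, 0.060, 0.048),
    (1010, 0.059, 0.048),
]


def main() -> None:
    anchors = np.asarray(ANCHORS, dtype=float)
    wl = np.arange(440.0, 1011.0, 1.0)
    oxy = PchipInterpolator(anchors[:, 0], anchors[:, 1])(wl)
    deoxy = PchipInterpolator(anchors[:, 0], anchors[:, 2])(wl)
    out = Path(__file__).resolve().parents[1] / "src" / "drsmargin" / "data"
    out.mkdir(parents=True, exist_ok=True)
    path = out / "hemoglobin_extinction_synthetic.csv"
    with path.open("w") as fh:
        fh.write("# Synthetic whole-blood absorption curves (mm^-1); see scripts/build_extinction_table.py\n")
        fh.write("wavelength_nm,mu_a_oxy,mu_a_deoxy\n")
        for w, o, d in zip(wl, oxy, deoxy):
            fh.write(f"{w:.1f},{o:.6g},{d:.6g}\n")
    print(f"wrote {path} ({path.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
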