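"""Regenerate the packaged meridian density-profile CSVs.

The packaged profiles are a parametric stand-in for digitized histological
RGC densities: a central rise to a ~3e4 cells/mm^2 peak near 1 mm
eccentricity and a two-exponential peripheral tail, with meridian-dependent
amplitude and tail length (nasal slowest decay, temporal fastest). Users
with real digitizations should simply replace the CSVs.
"""

from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parent.parent / "src" / "onspv" / "data"

rho = np.arange(0.0, 21.0 + 1e-9, 0.5)


def profile(rho, amp, lam1, lam2, a2):
    rise = rho**2 / (rho**2 + 0.30**2)
    return amp * rise * (np.exp(-rho / lam1) + a2 * np.exp(-rho / lam2))


PARAMS = {
    "nasal":    dict(amp=62000.0, lam1=1.35, lam2=5.0, a2=0.030),
    "temporal": dict(amp=50000.0, lam1=1.25, lam2=3.5, a2=0.020),
    "superior": dict(amp=56000.0, lam1=1.30, lam2=4.2, a2=0.025),
    "inferior": dict(amp=54000.0, lam1=1.30, lam2=4.0, a2=0.025),
}

if __name__ == "__main__":
    vals = {m: profile(rho, **p) for m, p in PARAMS.items()}
    mean_d = np.exp(np.mean([np.log(np.maximum(v, 1e-12)) for v in vals.values()], axis=0))
    total = 2 * np.pi * np.trapezoid(mean_d * rho, rho)
    print(f"approximate total RGC count: {total:.3e}")
    for m, v in vals.items():
        path = OUT / f"density_{m}.csv"
        with open(path, "w") as f:
            f.write("eccentricity_mm,density_cells_per_mm2\n")
            for r, d in zip(rho, v):
                f.write(f"{r:.1f},{d:.2f}\n")
        print(f"wrote {path}")
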