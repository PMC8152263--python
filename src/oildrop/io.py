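"""CSV serialization for oil optical constants and size distributions.

Schemas: complex-index spectra as (wavelength_nm, n, k); size
distributions as (diameter_um, density_ppm_per_um). Synthetic templates
serialize through the same schemas, so measured data can be swapped in
without touching the rest of the pipeline.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grid import SpectralGrid
from .mie import ComplexIndexSpectrum, SizeDistribution


def write_index_csv(index: ComplexIndexSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": index.grid.wavelengths, "n": index.n, "k": index.k}
    ).to_csv(path, index=False)


def read_index_csv(path: str | Path) -> ComplexIndexSpectrum:
    df = pd.read_csv(path)
    grid = SpectralGrid(df["wavelength_nm"].to_numpy(float))
    return ComplexIndexSpectrum(
        grid=grid, n=df["n"].to_numpy(float), k=df["k"].to_numpy(float)
    )


def write_psd_csv(psd: SizeDistribution, path: str | Path) -> None:
    pd.DataFrame(
        {"diameter_um": psd.diameters, "density_ppm_per_um": psd.density}
    ).to_csv(path, index=False)


def read_psd_csv(path: str | Path) -> SizeDistribution:
    df = pd.read_csv(path)
    d = df["diameter_um"].to_numpy(float)
    rho = df["density_ppm_per_um"].to_numpy(float)
    return SizeDistribution(
        diameters=d, density=rho, total_ppm=float(np.trapezoid(rho, d))
    )
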