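"""Full experiment orchestration: trophic grid x oil kinds.

Runs the reflectance simulation for every combination of water type
(default Chl-a = 0.1, 1, 10 mg/m^3) and oil treatment (none, BD, CL, FL at
1 ppm in the mixed layer), computes the band metrics, writes spectra and
metric tables as CSV with a run manifest, and checks the qualitative
directional findings that distinguish the three oil archetypes.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grid import SpectralGrid, TrophicScenario
from .indices import (
    BLUE_RANGE,
    GREEN_RANGE,
    RED_RANGE,
    BandMetrics,
    band_ratio,
    color_index,
    fold_change,
    relative_difference,
)
from .mc import RrsResult, Scenario, mix_iops, simulate_rrs
from .mie import OilIOPs, polydisperse_iops
from .oils import OIL_KINDS, make_oil_index, make_psd
from .water import build_water_iops

logger = logging.getLogger(__name__)

#: Reduced band set that still carries every directional metric below.
REDUCED_BANDS = (410.0, 440.0, 490.0, 550.0, 555.0, 560.0, 670.0, 680.0)


@dataclass(frozen=True)
class ExperimentConfig:
    """The experiment grid and its shared scenario."""

    chl_levels: tuple[float, ...] = (0.1, 1.0, 10.0)
    oils: tuple[str | None, ...] = (None, "BD", "CL", "FL")
    scenario: Scenario = field(default_factory=Scenario)
    grid: SpectralGrid = field(default_factory=SpectralGrid)
    output_dir: str | Path | None = None
    #: extra photons for red bands, where clear-water R_rs is smallest
    red_band_boost: float = 1.0
    full_scale: bool = False  # 2e9 photons per wavelength when True

    def effective_scenario(self) -> Scenario:
        if self.full_scale:
            return replace(self.scenario, n_photons=2_000_000_000)
        return self.scenario


@dataclass
class CellResult:
    chl: float
    oil: str | None
    rrs: RrsResult
    metrics: BandMetrics


@dataclass
class ExperimentBundle:
    config: ExperimentConfig
    cells: dict = field(default_factory=dict)  # (chl, oil) -> CellResult

    def natural(self, chl: float) -> CellResult:
        return self.cells[(chl, None)]


def _simulate_cell(
    scenario: Scenario,
    water,
    oil_iops: OilIOPs | None,
    grid: SpectralGrid,
    red_band_boost: float,
) -> RrsResult:
    medium = mix_iops(water, oil_iops, scenario)
    if red_band_boost <= 1.0:
        return simulate_rrs(scenario, medium)
    # split the grid so red bands get a larger budget
    red = grid.wavelengths >= 650.0
    if not red.any() or red.all():
        return simulate_rrs(scenario, medium)
    parts = []
    for mask, boost in ((~red, 1.0), (red, red_band_boost)):
        sub = SpectralGrid(grid.wavelengths[mask])
        sub_water = _subset_water(water, mask, sub)
        sub_oil = _subset_oil(oil_iops, mask, sub)
        sc = replace(scenario, n_photons=int(scenario.n_photons * boost))
        parts.append((mask, simulate_rrs(sc, mix_iops(sub_water, sub_oil, sc))))
    nw = len(grid)
    rrs = np.empty(nw)
    err = np.empty(nw)
    eu = np.empty(nw)
    budget = {k: np.empty(nw) for k in parts[0][1].budget}
    for mask, res in parts:
        rrs[mask] = res.rrs
        err[mask] = res.stderr
        eu[mask] = res.eu_ed_ratio
        for k in budget:
            budget[k][mask] = res.budget[k]
    return RrsResult(
        grid=grid, rrs=rrs, stderr=err, budget=budget,
        n_photons=scenario.n_photons, seed=scenario.seed, eu_ed_ratio=eu,
    )


def _subset_water(water, mask, sub_grid):
    from .water import WaterIOPs

    return WaterIOPs(
        grid=sub_grid,
        a_water=water.a_water[mask],
        b_water=water.b_water[mask],
        a_particle=water.a_particle[mask],
        a_cdom=water.a_cdom[mask],
        b_particle=water.b_particle[mask],
        pf=[p for p, m in zip(water.pf, mask) if m],
        chl=water.chl,
    )


def _subset_oil(oil: OilIOPs | None, mask, sub_grid) -> OilIOPs | None:
    if oil is None:
        return None
    return OilIOPs(
        grid=sub_grid,
        a_oil=oil.a_oil[mask],
        b_oil=oil.b_oil[mask],
        pf=[p for p, m in zip(oil.pf, mask) if m],
        ppm=oil.ppm,
    )


def run_experiment(config: ExperimentConfig) -> ExperimentBundle:
    """Run every (water type, oil) cell and optionally write outputs."""
    grid = config.grid
    scenario = config.effective_scenario()
    bundle = ExperimentBundle(config=config)

    oil_iops: dict[str, OilIOPs] = {}
    for kind in config.oils:
        if kind is None:
            continue
        if kind not in OIL_KINDS:
            raise ValueError(f"unknown oil kind {kind!r}")
        oil_iops[kind] = polydisperse_iops(
            make_oil_index(kind, grid), make_psd(kind, 1.0), grid
        )

    for chl in config.chl_levels:
        water = build_water_iops(TrophicScenario(chl), grid)
        for kind in config.oils:
            try:
                rrs = _simulate_cell(
                    scenario, water, oil_iops.get(kind), grid,
                    config.red_band_boost,
                )
            except Exception:
                logger.exception("cell (chl=%s, oil=%s) failed; skipping", chl, kind)
                continue
            bundle.cells[(chl, kind)] = CellResult(
                chl=chl, oil=kind, rrs=rrs, metrics=BandMetrics.from_rrs(rrs)
            )
            logger.info(
                "cell chl=%s oil=%s done (Rrs range %.2e..%.2e sr^-1)",
                chl, kind, rrs.rrs.min(), rrs.rrs.max(),
            )

    if config.output_dir is not None:
        write_outputs(bundle, Path(config.output_dir))
    return bundle


# -- output tables -------------------------------------------------------------

def _cell_name(chl: float, oil: str | None) -> str:
    return f"chl{chl:g}_{oil or 'none'}"


def write_outputs(bundle: ExperimentBundle, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sc = bundle.config.effective_scenario()
    for (chl, oil), cell in bundle.cells.items():
        cell.rrs.to_dataframe().to_csv(
            outdir / f"rrs_{_cell_name(chl, oil)}.csv", index=False
        )
    ratio_table(bundle).to_csv(outdir / "band_ratio_changes_pct.csv")
    difference_table(bundle).to_csv(outdir / "band_difference_changes_pct.csv")
    ci_table(bundle).to_csv(outdir / "color_index_table.csv")
    manifest = {
        "version": __version__,
        "seed": sc.seed,
        "n_photons": sc.n_photons,
        "red_band_boost": bundle.config.red_band_boost,
        "receiver_half_angle_deg": sc.receiver_half_angle,
        "oil_ppm": sc.oil_ppm,
        "chl_levels": list(bundle.config.chl_levels),
        "oils": [o or "none" for o in bundle.config.oils],
        "wavelengths_nm": bundle.config.grid.wavelengths.tolist(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _pct_table(bundle: ExperimentBundle, getter) -> pd.DataFrame:
    """Rows = metric, columns = (water, oil), cells = % change vs natural."""
    cols = {}
    for (chl, oil), cell in bundle.cells.items():
        if oil is None:
            continue
        nat = bundle.natural(chl)
        col = {}
        for key, pol_value in getter(cell.metrics).items():
            nat_value = getter(nat.metrics).get(key)
            if nat_value is None:
                continue
            col["/".join(map(str, key))] = relative_difference(pol_value, nat_value)
        cols[(f"chl={chl:g}", oil)] = col
    return pd.DataFrame(cols)


def ratio_table(bundle: ExperimentBundle) -> pd.DataFrame:
    return _pct_table(bundle, lambda m: m.ratios)


def difference_table(bundle: ExperimentBundle) -> pd.DataFrame:
    return _pct_table(bundle, lambda m: m.differences)


def ci_table(bundle: ExperimentBundle) -> pd.DataFrame:
    """CI values (x 1e3) per band triplet and cell, plus % changes."""
    cols = {}
    for (chl, oil), cell in bundle.cells.items():
        cols[(f"chl={chl:g}", oil or "none")] = {
            "/".join(map(str, key)): v * 1e3 for key, v in cell.metrics.ci.items()
        }
    return pd.DataFrame(cols)


# -- directional findings ------------------------------------------------------

@dataclass(frozen=True)
class DirectionalReport:
    """Qualitative pollution signatures checked on a default-grid bundle."""

    checks: dict

    @property
    def all_pass(self) -> bool:
        return all(self.checks.values()) if self.checks else True

    def __str__(self) -> str:
        if not self.checks:
            return "no polluted cells: nothing to check"
        return "\n".join(
            f"[{'PASS' if ok else 'FAIL'}] {name}" for name, ok in self.checks.items()
        )


def summarize_directional_findings(bundle: ExperimentBundle) -> DirectionalReport:
    """Evaluate the qualitative oil-pollution signatures.

    (i) the mean R_rs fold increase is ordered oligotrophic > mesotrophic >
    eutrophic for every oil; (ii) the FL-like oil lowers the 410/560
    blue-to-green ratio in oligotrophic water and makes CI less negative;
    (iii) the BD-like oil raises the 550/680 green-to-red ratio in
    oligotrophic and mesotrophic water; (iv) BD- and CL-like oils make the
    oligotrophic CI more negative while the FL-like oil moves it the other
    way.
    """
    oils = [o for o in bundle.config.oils if o is not None]
    chls = sorted(bundle.config.chl_levels)
    checks: dict[str, bool] = {}
    if not oils:
        return DirectionalReport(checks={})

    def rrs(chl, oil):
        return bundle.cells[(chl, oil)].rrs

    # (i) pollution effect ordered by trophic state, every oil
    for oil in oils:
        folds = [
            float(np.mean(rrs(chl, oil).rrs / rrs(chl, None).rrs)) for chl in chls
        ]
        checks[f"{oil}: fold increase ordered oligo > meso > eutrophic"] = all(
            folds[i] > folds[i + 1] for i in range(len(folds) - 1)
        )

    oligo = chls[0]
    meso = chls[1] if len(chls) > 1 else None

    def ratio_change(chl, oil, l1, l2):
        pol = band_ratio(rrs(chl, oil), l1, l2)
        nat = band_ratio(rrs(chl, None), l1, l2)
        return relative_difference(pol, nat)

    def ci(chl, oil):
        return color_index(rrs(chl, oil), 440, 555, 670)

    if "FL" in oils:
        checks["FL: 410/560 ratio decreases (oligotrophic)"] = (
            ratio_change(oligo, "FL", 410, 560) < 0
        )
        checks["FL: CI less negative (oligotrophic)"] = ci(oligo, "FL") > ci(
            oligo, None
        )
    if "BD" in oils:
        ok = ratio_change(oligo, "BD", 550, 680) > 0
        if meso is not None:
            ok = ok and ratio_change(meso, "BD", 550, 680) > 0
        checks["BD: 550/680 ratio increases (oligo & meso)"] = ok
        checks["BD: CI more negative (oligotrophic)"] = ci(oligo, "BD") < ci(
            oligo, None
        )
    if "CL" in oils:
        checks["CL: CI more negative (oligotrophic)"] = ci(oligo, "CL") < ci(
            oligo, None
        )
        red = fold_change(rrs(oligo, "CL"), rrs(oligo, None), RED_RANGE)
        blue = fold_change(rrs(oligo, "CL"), rrs(oligo, None), BLUE_RANGE)
        checks["CL: red-band fold exceeds blue-band fold (oligotrophic)"] = red > blue
    return DirectionalReport(checks=checks)
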