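# oildrop-rt

Monte Carlo radiative transfer and Lorenz–Mie modeling of **dispersed
oil pollution in open-ocean waters**, for researchers in ocean-color
remote sensing and marine optics who want to know how micrometre-sized
oil droplets in the water column perturb remote sensing reflectance and
the band metrics that chlorophyll algorithms rely on.

Surface slicks are routinely monitored from space; oil *dispersed* into
the column as droplets smaller than ~100 µm is not. Droplets absorb and
scatter light, so they reshape the water-leaving radiance — and can
masquerade as a change in chlorophyll. This package simulates that
end-to-end:

1. **Case-1 water model** — IOPs of oligotrophic/mesotrophic/eutrophic
   ocean water (Chl-a = 0.1/1/10 mg m⁻³) from Pope & Fry water
   absorption, a chlorophyll power law for particle absorption
   (a_p = A(λ)·Chl^E), CDOM tied to a_p(440), Morel-style particle
   scattering, and a Fournier–Forand/seawater phase-function mixture.
2. **Lorenz–Mie engine** — bulk absorption, scattering and phase
   functions of polydisperse oil droplet suspensions from complex
   refractive-index spectra and multi-mode log-normal size
   distributions (synthetic archetypes of a biodiesel **BD**, a
   lubricant **CL** and a crude oil **FL** ship with the package).
3. **Monte Carlo solver** — photon transport under a Cox–Munk rough
   surface (5 m s⁻¹ wind), sun at 30° plus diffuse sky, a 30 m oil-bearing
   mixed layer over clean water to 1000 m, and a nadir receiver at 0⁺;
   output is R_rs(λ) = L_w/E_d in sr⁻¹ with Monte Carlo error bars and
   an exact photon energy budget.
4. **Ocean-color analytics** — band ratios R_rs(λ₁)/R_rs(λ₂), band
   differences, fold changes, and the color index

   CI = R_rs(λ_green) − [R_rs(λ_blue) + (λ_green−λ_blue)/(λ_red−λ_blue) · (R_rs(λ_red) − R_rs(λ_blue))]

   evaluated at the instrument bands closest to 443/555/670 nm.

See `docs/methods.md` for the model assumptions and numerical choices.

## Worked example

```sh
python examples/03_simulate_rrs.py
```

simulates oligotrophic water (Chl-a = 0.1 mg m⁻³) with and without 1 ppm
of the lubricant-oil archetype in the mixed layer (5×10⁵ photons per
band, 15° receiver) and prints:

```
band   natural R_rs    polluted R_rs   fold
  440  0.00710+-0.00017  0.01953+-0.00031   2.75
  555  0.00119+-0.00006  0.00609+-0.00017   5.14
  670  0.00012+-0.00001  0.00059+-0.00004   5.05

energy budget (natural, 440 nm):
  absorbed_column: 0.9444
  absorbed_bottom: 0.0000
  water_leaving: 0.0219
  surface_lost: 0.0336
```

One ppm of dispersed oil nearly triples the blue reflectance and raises
the green and red reflectance five-fold — the water brightens most
where it is naturally darkest, and the spectral shape (hence any
band-ratio algorithm) is distorted. The budget lines confirm energy
conservation: every launched photon is accounted for as absorbed,
water-leaving, or lost at the surface.

The other examples build the water model (`01`), inspect the Mie-derived
oil IOPs and their characteristic 90–110° phase-function peak (`02`),
and run the full 3-water × 4-treatment experiment grid with the
directional findings report (`04`).

A thin CLI wraps the same API:

```sh
oildrop-rt simulate --chl 0.1 --oil CL --photons 1000000 --out rrs.csv
oildrop-rt run --out results/ --photons 300000
oildrop-rt indices rrs.csv
```

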