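# eprbind

Binding-constant analysis of stable-radical host–guest complexes by EPR
and NMR titration.

Nitroxide radicals (TEMPO-family probes) are paramagnetic, so their
complexation by macrocyclic hosts such as cucurbit[7/8]uril in water is
followed by EPR rather than NMR: inclusion in the hydrophobic cavity
lowers the nitrogen hyperfine coupling a_N (the three-line spectrum
contracts) and slows tumbling (the high-field line broadens). `eprbind`
turns that qualitative signature into numbers. It

* forward-simulates fast-motion nitroxide spectra — three Lorentzian
  (optionally pseudo-Voigt) derivative lines with the linewidth law
  W(mI) = α + β·mI + γ·mI², ¹³C satellites included — for monoradicals
  and magnetically independent dinitroxides;
* solves the mass-action speciation for 1:1, stepwise 2-host, and
  "shuttle" 1:1 binding (a host exchanging rapidly between the two
  stations of a dinitroxide guest → a 50/50 free-like/complexed-site
  composite spectrum);
* **globally fits** a titration series (field × concentration) with
  shared species spectra and isotherm-constrained weights to extract the
  association constant K_a, with per-spectrum scale/baseline nuisances
  solved by variable projection;
* fits fast-exchange ¹H NMR titrations of the reduced (diamagnetic)
  guests, δ_obs = δ_free + f_bound·(δ_bound − δ_free), as an independent
  cross-check of the EPR constant;
* generates synthetic titrations from provenance-tagged presets so the
  whole pipeline is testable without instrument data.

Intended users: magnetic-resonance and supramolecular-chemistry groups
who titrate spin-labelled guests and want a scripted, reproducible
alternative to opaque spectrometer fitting programs.

## Worked example

```python
import eprbind as eb

# 1. What fraction of a dinitroxide guest is complexed at 1.1 equivalents
#    of host, given Ka = 20 900 M^-1 and 0.5 mM guest?
r = eb.solve_two_state(0.5e-3, 0.55e-3, 20900.0)
print(f"{100 * r.fraction_guest_bound:.0f}% bound")        # -> 77% bound

# 2. Slow-exchange NMR integrals 5 (free) : 19 (complex):
print(f"{eb.slow_exchange_fraction(5, 19):.0f}% complexed")  # -> 79% complexed

# 3. Recover Ka from a synthetic 25-spectrum EPR titration at SNR 50:
preset = eb.get_preset("TEMPONE_CB7")
series = eb.generate_epr_titration(preset, noise=eb.NoiseSpec(snr=50, seed=1))
fit = eb.fit_titration(series, "one_to_one",
                       templates={"free": preset.free, "bound": preset.bound})
print(f"Ka = {fit.model.K_a:.0f} M^-1, R = {fit.regression_coefficient:.4f}")
# -> Ka = 4478 M^-1, R = 0.9899   (truth encoded in the preset: 4510)
```

The two percentages agreeing within a couple of points is the
EPR↔NMR consistency check: the EPR-fitted constant predicts the
independently measured NMR speciation.

The same workflow from the shell:

```bash
eprbind generate --preset TEMPONE_CB7 --snr 50 --seed 1 --outdir run/
eprbind fit-epr --manifest run/manifest.json --model one_to_one --out run/fit.json
eprbind speciate --ka 20900 --guest-mM 0.5 --host-mM 0.55
```

Spectra are plain two-column CSV (`field_G,intensity`), series are
described by a small JSON manifest, and every command writes a JSON
report embedding its configuration, seed and package version.

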