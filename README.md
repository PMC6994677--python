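# nsefold

Structural and dynamical analysis of protein folding states from
small-angle neutron scattering (SANS) and neutron spin-echo (NSE)
spectroscopy, built around the model system apomyoglobin: native-like at
pD 6, molten globule at pD 4, acid unfolded at pD 2, and GdmCl denatured.

The package is for scattering practitioners who want a tested, scriptable
version of the full analysis chain that connects those experiments:

**Structural branch.**  Dilution series are extrapolated to infinite
dilution, the form factor is fitted with a generalized Guinier law
`I(q) = A·exp(−Rg²q²/(3−α))` (globular states) or the excluded-volume
polymer form factor (unfolded states), and the chain descriptors follow
from `Rg² = l²N^{2ν}/[(2ν+1)(2ν+2)]`: Flory exponent ν (= 1/m from the
Porod exponent), Kuhn length `l`, end-to-end distance
`R_E = √((2ν+1)(2ν+2))·Rg`, compactness `R_H/Rg`, and the overlap
concentration `c* = M/(N_A·4πRg³/3)`.  Concentrated curves divided by the
form factor give the experimental structure factor `S(c,q)`, modelled by
the mean-spherical-approximation (MSA) closure for screened-Coulomb
macro-ions (solved here by spectral Ornstein–Zernike iteration, exactly
Percus–Yevick in the zero-charge limit).

**Dynamical branch.**  Normalized intermediate scattering functions
S(q,t)/S(q,0) are fitted per q by cumulants `A·exp(−D₁t−D₂t²)` and
stretched exponentials `A·exp(−D′q²t^β)`; the corrected effective
diffusion is `D_eff(q) = (D₁/q²)·S(c,q)/H_{c,q0}` with the hydrodynamic
function estimated from DLS (`H_{c,q0} = D_c·S_{q0}/D_0`) or viscosities
(`H_{c,qL} = η_dilute/η_conc`).  Chain dynamics is modelled by the Zimm
dynamic structure factor with mode times `τ_p = ηR_E³/(√(3π)k_BT)·p^{−3ν}`
and its internal-friction extension (ZIF), `τ_p → τ_p + τ_intern`; the
global fit over all q has only the center-of-mass diffusion D and
τ_intern free.

**Rigid-body branch.**  For folded states, the first cumulant D₀(q) is
computed from PDB coordinates, coherent scattering lengths (with H/D
exchange of labile protons) and a 6×6 translation–rotation diffusion
matrix; internal motions are described by anisotropic-network normal
modes, with the first internal mode (mode 7) contributing a q-dependent
`D_eff^α(q)` and the decomposition `ΔD_eff(q) = D_eff(q) − D₀(q)`.

A synthetic-data module emulates every input — SANS dilution series, NSE
spectra, scalar side measurements, coordinate fixtures — with seeded
noise, using the published parameters of the four folding states as
generating values, so the entire chain runs at desk scale.

## Worked example

Fit the synthetic GdmCl-denatured dilution series and the acid-unfolded
NSE spectra:

```python
import numpy as np
from dataclasses import replace
import nsefold as nf
from nsefold import synthetic_data as syn

# structural: dilution series -> form factor -> chain parameters
curves = syn.generate_sans("gdmcl", seed=1)          # 3, 6, 15, 30 mg/mL
form = nf.extrapolate_infinite_dilution(curves)
fit = nf.fit_form_factor(form, model="excluded_volume")
print(f"Rg = {fit.radius_of_gyration:.1f} A, nu = {fit.flory_exponent:.3f}, "
      f"l = {fit.kuhn_length:.1f} A")

# dynamical: global ZIF fit with only (D, tau_intern) free
data = syn.generate_nse("pd2", seed=1, t_grid=np.geomspace(0.5, 90, 25))
start = replace(syn.zimm_spec_for_state("pd2"),
                internal_friction=10.0, com_diffusion=2.0)
zif = nf.fit_zif_global(data, start)
print(f"D = {zif.com_diffusion:.2f} A^2/ns, "
      f"tau_intern = {zif.internal_friction:.1f} ns, "
      f"chi2 = {zif.chi2:.2f}")
```

prints

```
Rg = 70.0 A, nu = 0.639, l = 28.2 A
D = 3.03 A^2/ns, tau_intern = 49.5 ns, chi2 = 0.78
```

The structural fit recovers the generating values Rg = 70.2 Å and
ν = 0.64 of the expanded GdmCl-denatured chain (Kuhn length 28.2 Å for a
20-bead chain); the ZIF fit recovers the generating D = 3.0 Å²/ns and
τ_intern = 50.9 ns of the acid-unfolded state — an internal friction time
of the same magnitude as the first Zimm relaxation time, the signature of
a chain whose conformational changes are hindered by transient
intrachain interactions.

The same stages are available from the shell:

```bash
nsefold simulate --state gdmcl --seed 1 --outdir fixtures
nsefold fit-sans fixtures/sans_gdmcl_*.dat --outdir sans_out
nsefold fit-nse fixtures/isf_gdmcl.dat --state gdmcl --outdir nse_out
```

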