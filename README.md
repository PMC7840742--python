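# memperm

Membrane permeability and bilayer structure analysis for
molecular-dynamics data, with synthetic ground-truth generators that make
every stage testable at desk scale.

## What it computes

Passive permeation of a small molecule (e.g. a withanolide drug) across a
lipid bilayer is modelled with the **inhomogeneous solubility–diffusion
model**: the permeant experiences a free-energy profile *w(z)* and a local
diffusion coefficient *D(z)* along the membrane normal *z*, and the
permeability coefficient follows from

```
1/P  =  R  =  ∫_{z1}^{z2}  exp(β w(z)) / D(z)  dz ,      β = 1/(k_B T)
```

where the integrand `R(z) = exp(βw)/D` is the local resistivity of each
membrane slice.  The package provides the full chain that produces the
ingredients of this integral from umbrella-sampling data:

* **WHAM** — unbiasing of harmonically restrained window histograms into
  the potential of mean force *w(z)*, with sampling-gap detection,
  bootstrap errors and an explicit restraint convention
  (`U = k(z−z₀)²` or `½k(z−z₀)²`);
* **z-reflection symmetrization** of one-sided profiles (membrane
  symmetry);
* **D(z)** per window via the positional-autocorrelation estimator
  `D = var(z)² / ∫ C(t) dt`, `C(t) = ⟨δz(0)δz(t)⟩`;
* the **resistivity/permeability integral** above, reported in Å/ps and
  cm/s (1 Å/ps = 10⁴ cm/s).

Alongside the permeability core it implements the standard
membrane/permeant descriptors: area per lipid (`Lx·Ly/N_lipid`), electron
density profiles (each atom contributing *Z − q* electrons), acyl-chain
order parameters `S_CD = ⟨½(3cos²θ − 1)⟩`, Delaunay-tessellation
tetrahedrality `T = Σ_{i<j}(l_i−l_j)²/(15 l̄²)`, permeant tilt and
insertion depth, first-hydration-shell counts (3.5 Å), hydrogen-bond
run-length lifetimes, radial distribution functions, and the fraction of
native contacts Q(t).

Units throughout: Å, ps, kcal/mol, K.

## Synthetic data

MD trajectories are large and rarely shipped; `memperm.synthetic` builds
inputs whose answers are known by construction:

* a 1-D overdamped Langevin simulator on prescribed (*w*, *D*) with
  optional umbrella biases — its stationary law is exactly
  `∝ exp(−β(w+U))`, so WHAM recovery can be tested against analytic truth;
* a coarse bead bilayer (lipid head/tail beads, sterol- and water-like
  particles, controllable chain tilt) whose APL, S_CD, leaflet counts and
  group map are recorded as ground truth;
* telegraph and Ornstein–Uhlenbeck series generators (lifetime and
  diffusion-estimator oracles).

## Worked example

Generate umbrella windows on a known landscape (a 4 kcal/mol Gaussian
barrier with a cosine-modulated diffusivity), unbias them, estimate D(z)
and integrate the permeability:

```python
import numpy as np
import memperm as mp
from memperm.synthetic import LandscapeSpec, generate_umbrella_set

spec = LandscapeSpec(
    z_lo=0.0, z_hi=20.0,
    w_form="gaussian", w_params={"height": 4.0, "center": 10.0, "width2": 18.0},
    d_form="cosine", d_params={"a": 0.10, "b": 0.04, "length": 20.0},
)
windows = generate_umbrella_set(spec, centers=np.linspace(0, 20, 11),
                                k=0.5, n_steps=100_000, dt=0.02, seed=0)
for w in windows:
    w.discard = len(w.series) // 10          # 10% burn-in

pmf = mp.wham(windows, z_bins=40, anchor="bulk")
dprof = mp.diffusion_profile(windows)
perm = mp.permeability(pmf, dprof, z1=2.0, z2=18.0)

print(f"PMF barrier height : {np.nanmax(pmf.profile.values):.2f} kcal/mol")
print(f"D range            : {dprof.d.min():.4f} - {dprof.d.max():.4f} A^2/ps")
print(f"Resistance R       : {perm.resistance:.3e} ps/A")
print(f"Permeability P     : {perm.permeability:.3e} A/ps "
      f"({perm.permeability_cm_s:.3e} cm/s)")
```

Output:

```
PMF barrier height : 4.09 kcal/mol
D range            : 0.0525 - 0.1979 A^2/ps
Resistance R       : 2.024e+04 ps/A
Permeability P     : 4.941e-05 A/ps (4.941e-01 cm/s)
```

The recovered barrier (4.09 kcal/mol vs the prescribed 4.0) and the
permeability (4.94·10⁻⁵ Å/ps vs the quadrature value 4.72·10⁻⁵ for the
true landscape, a 5% discrepancy at this sampling budget) illustrate the
accuracy achievable from ~2 ns-equivalent windows; the outermost D values
carry a known reflecting-boundary bias (see `docs/methods.md`) that
contributes little to R because resistivity is concentrated at the
barrier top.

The same chain is scriptable from a shell:

```sh
memperm --config landscape.cfg --seed 3 simulate umbrella-set \
    --z-top 20 --z-center 0 --spacing 2 --k 0.5 --out-dir windows/
memperm wham --meta windows/metadata.dat --bins 40 --anchor bulk --out pmf.tsv
memperm diffusion --meta windows/metadata.dat --out dprof.tsv
memperm permeability --pmf pmf.tsv --dprof dprof.tsv --z1 2 --z2 18
```

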