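# contactprefs

Probabilistic contact preferences for protein–ligand interactions.

Crystal structures show where protein atoms sit around recurring ligand
fragments — hydroxyl and carbonyl oxygens, aromatic carbons, amino nitrogens,
halogens. `contactprefs` turns those observations into ranked, spatially
resolved predictions: given a fragment type and a region around it, which of
the 13 protein contact-atom classes (methyl and aromatic carbons, backbone
N/O, carboxyl and hydroxyl oxygens, ...) is most likely to be found there?
The output feeds knowledge-based docking and scoring, and a screening stage
that separates ligands from decoys.

It is written for structural bioinformaticians and method developers who need
directional (not merely distance-dependent) statistical potentials with
honest uncertainty estimates.

## The model

Every fragment instance is an atom triple (Main-atom, Atom1, Atom2) that
defines a canonical frame: Main-atom at the origin, the *main direction*
Atom1→Main-atom along +z, Atom2 in the half-plane {y = 0, x < 0}. Contact
atoms of class C around fragment class f, pooled over all instances, form a
cloud in spherical coordinates (r, θ, φ) that is modelled by a piecewise
density: non-overlapping polar intervals, each carrying

* a weight w_i (fraction of contacts in the interval),
* an interval-truncated von Mises in the polar angle, vM(θ; μ_i, κ_i),
* a truncated normal in distance, N(r; μ_ri, σ²_ri) on [0, R_max],
* a mixture of truncated normals over azimuthal sub-intervals,
  Σ_j w_ij N(φ; μ_ij, σ²_ij).

The component structure comes from histogram mode detection (sign changes of
adjacent bin-height differences, clamped to 1–4 modes), never from free-form
EM. Mean and concentration parameters are Bayesian: conjugate priors with
pseudo-counts give MAP updates — the normal means are precision-weighted
averages, the von Mises mean is the direction of the summed resultant, and κ
solves A₁(κ) = pooled mean resultant, A₁ = I₁/I₀. Variances keep marginal ML
estimates.

The probability mass of the density inside a spherical box
[r₁,r₂]×[θ₁,θ₂]×[φ₁,φ₂] scores a contact type in that region; masses are
multiplied by chemistry-based prior weights (a Coulomb form
|δ_f·δ_C| / d̄² built from electronegativity and Parr–Pearson
hardness/softness) and normalized over the 13 classes to give the ranked
*hierarchy*. Bootstrap-style jittering of the volume bounds yields standard
errors. A logistic regression on two per-molecule features — contact mass
per unit molecular mass (pmPerMass) and the hydrophobic/hydrophilic fragment
ratio (Phob/Phil) — drives the ligand/decoy screening stage.

## Worked example

Simulate a contact cloud from known parameters, fit it, and rank contact
types in a volume around a typical hydrogen-bond position:

```python
import numpy as np
from contactprefs import (PiecewiseDensityEstimator, SphericalVolume,
                          hierarchy, probability_mass)
from contactprefs.chem_prior import load_prior_table
from contactprefs.synthetic_data import CloudSpec, ComponentSpec, AzimuthalSpec, gen_cloud

spec = CloudSpec(
    components=[ComponentSpec(weight=1.0, mu_theta=0.6, kappa=12.0,
                              mu_r=2.9, var_r=0.04,
                              azimuthal=[AzimuthalSpec(1.0, 3.0, 0.3)])],
    r_max=4.0, n=2000, seed=5, fragment_class="f2", target_class="C14",
)
est = PiecewiseDensityEstimator().fit(gen_cloud(spec).to_array())
d = est.density_
c = d.components[0]
print(f"mu_theta={c.mu_theta:.3f} rad  kappa={c.kappa:.1f}  mu_r={c.mu_r:.3f} A")

v = SphericalVolume(2.6, 3.2, 0.3, 0.9, 2.4, 3.6)
print(f"mass in volume = {probability_mass(d, v):.4f}")

res = hierarchy("f2", {"C14": d}, load_prior_table(), v)
print(res.table.loc[["C14"], ["mass", "prior", "probability", "rank"]])
```

prints

```
mu_theta=0.589 rad  kappa=11.5  mu_r=2.900 A
mass in volume = 0.4443
         mass   prior  probability  rank
C14  0.444278  0.1068          1.0     1
```

The fitted direction (0.589 rad vs truth 0.6), concentration (11.5 vs 12) and
distance mean (2.900 Å vs 2.9) recover the generating parameters; about 44%
of the C14 probability mass lies in the chosen volume, and with only one
class supplied its normalized hierarchy probability is 1 at rank 1.

The screening stage on the packaged 27-molecule feature table:

```python
import numpy as np
from contactprefs import fit_logistic, load_screening_table, roc

table = load_screening_table()
probs = fit_logistic(table)
(pt,) = roc(probs, table["label"].to_numpy(), [0.5])
print(f"TPR={pt.tpr}  FPR={pt.fpr}  ACC={pt.acc:.2f}")
```

prints `TPR=0.75  FPR=0.0  ACC=0.93`: at the natural 0.5 threshold, 6 of the
8 ligands are recovered with no false positives among the 19 decoys.

A `contactprefs` command-line tool exposes the pipeline
(`extract`, `fit`, `mass`, `hierarchy`, `screen`, `simulate`); run
`contactprefs --help`.

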