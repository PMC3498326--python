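# Methods

## Canonical frames and coordinates

A fragment is the atom triple (Main-atom, Atom1, Atom2). The canonical model
frame translates the Main-atom to the origin and rotates so that Atom1 lies on
the negative z-axis (the main direction Atom1→Main-atom is +z) and Atom2 in
the half-plane {y = 0, x < 0}. The rotation is built by Gram–Schmidt on the
main direction, the z-orthogonalized (and negated) Main→Atom2 direction, and
their cross product; triples whose Atom1–Main–Atom2 angle has sine below 1e-6
are rejected as degenerate. Spherical coordinates follow the physics
convention restricted to this frame: θ ∈ [0, π] from +z, φ ∈ [0, 2π) from +x
counterclockwise about +z, so Atom2 sits at φ = π. At the poles and the
origin φ is defined as 0. A separate display frame used only for plots is the
cyclic permutation (x, y, z)_display = (z, x, y)_model, a proper rotation that
puts the main direction on +x and the fragment plane into the display x–y
plane.

The azimuth origin and sense are a package convention: the canonical pose
fixes the plane of the fragment but not the sign of φ; pinning φ(Atom2) = π
makes "below the fragment plane" directions reproducible across structures.

## The piecewise density

For one (fragment class, target class) pair the density over (r, θ, φ) is
piecewise in θ: non-overlapping intervals cover [0, π], each with weight w_i
(Σ w_i = 1), a von Mises factor vM(θ; μ_i, κ_i), a normal distance factor
N(r; μ_ri, σ²_ri) and azimuthal sub-intervals with weights w_ij and normal
factors N(φ; μ_ij, σ²_ij). Three numerical conventions matter:

* **Truncation, not wrapping.** Every 1D factor is renormalized to its own
  interval (distance normals to [0, R_max]). Sub-interval weights then carry
  all cross-interval mass and the full product integrates to exactly one.
  Wrapped azimuthal normals would double-count mass across sub-interval
  boundaries under interval-local weights.
* **No sin θ Jacobian.** The model fits the marginal coordinate samples
  directly; "uniform" means uniform in (r, θ, φ), not in 3D volume. This is a
  deliberate modelling choice — the component structure is chosen from 1D
  histograms of the same marginals — and all masses, hierarchies and tests
  are consistent with it.
* **Support cut.** Density is zero for r > R_max, the collection cutoff of
  the class pair.

Component structure is found by histogram mode detection: bin heights are
scanned for sign changes of adjacent differences; each +/− change is a local
maximum, and interval boundaries are placed at the minimal bin between
retained maxima. The initial bin count follows Sturges' rule and is adjusted
one bin at a time until the mode count falls in the configured clamp
(default [1, 4]); if no bin count satisfies the clamp the highest maxima are
retained. Fewer than 10 samples fall back to a single full-interval mode.
Distance distributions inherit one normal per polar component; per-(i,j)
distance refinement is not implemented.

### Estimation

Per polar interval the weight is the record fraction; distance mean/variance
are sample moments (variance floored at 1e-4 Å² or rad² for degenerate
clusters); azimuthal structure is fitted by mode detection on φ within the
interval. The polar von Mises (μ_i, κ_i) starts from the circular mean and
the resultant equation A₁(κ) = R̄ (A₁ = I₁/I₀, solved by bracketed
root-finding to 1e-8, capped at κ = 500 where the distribution is numerically
a point mass) and is then refined by maximizing the interval-truncated von
Mises likelihood (Nelder–Mead on (μ, log κ)): the fitted component is
renormalized to its interval, so the full-circle moment estimates are biased
whenever the interval clips the density — e.g. a cluster close to the pole —
and the truncation-aware ML removes that bias. Intervals with fewer than two
records are merged into a neighbor.

`PiecewiseDensityEstimator` exposes the fit in scikit-learn style
(`fit(X)` on an (n, 3) array, `score_samples`, `get_params`); passing a
`PriorHyper` turns the fit into a MAP update of the ML partition.

## Conjugate MAP updating

Mean parameters carry conjugate priors with pseudo-counts:

* normal means (r and φ): MAP = (τ₀ m₀ + n x̄)/(τ₀ + n); the fixed known
  variance σ₀² defaults to 0.04 Ų (configuration, not canon);
* von Mises mean: MAP is the direction of c₀(cos μ₀, sin μ₀) + Σ(cos θ_k,
  sin θ_k); the posterior pseudo-resultant is the length of that sum;
* concentration: variance matching through a Bessel-form prior — the
  posterior mean cosine (c_κ R₀ + n C̄)/(c_κ + n), with C̄ the data mean
  cosine about the mean direction, is equated to A₁(κ).

By convention the pseudo-count of a parameter is the number of observations
behind its prior estimate; with no prior dataset the pseudo-counts default to
zero (MAP reduces to ML, with a warning in the CLI). All pooled statistics
are linear in counts, so sequential updating with clouds A then B (carrying
`posterior_hyper_` forward) reproduces the joint update with A∪B exactly for
the mean parameters; the concentration agrees up to the (small) difference in
the direction each step measures its mean cosine about. Variances always
keep marginal ML values: the data-generation process (refinement restraints,
thermal motion, crystal packing) biases spreads in ways a credible prior
cannot capture. The conjugate updates use the standard full-circle forms; for
heavily interval-clipped components they inherit the moment bias that the ML
refinement removes, which is acceptable when priors are weak or components
well separated, and is flagged here as a known limitation.

## Probability masses and hierarchies

Masses over a spherical box factorize per piece into 1D integrals, computed
two ways that must agree to 1e-6: closed forms (normal factors by error
functions; von Mises factors by the Bessel cosine series
∫exp(κcos x) = I₀(κ)(b−a) + 2Σ_k I_k(κ)[sin k(b−μ) − sin k(a−μ)]/k, terms
scaled by e^−κ and truncated at k ≈ κ + 12√κ + 30) and fixed-order
Gauss–Legendre quadrature (default 64 points per dimension per piece). A
third, brute-force route (million-cell midpoint Riemann sums per factor) and
a piece-local 3D tensor-grid integral of the assembled density serve as
oracles in the tests.

The hierarchy for fragment class f in volume V is score(C) = prior(f, C) ×
mass_C(V), normalized to sum to one over the 13 target classes and ranked
descending with ties broken by class index. Normalization happens after
prior weighting. Classes without a fitted density score zero and are
reported. Standard errors come from recomputing the normalized probabilities
in n volumes (default 1000) whose six interval bounds are independently
jittered by a uniform ±5% of the interval width; jittering the volume center
as well is supported but off by default (shape-only perturbation). The
jitter magnitude is configuration — there is no canonical value.

## Chemistry priors

Softness of element X in G = {C, N, O, S, F, Cl, Br, I} is
2·mean_G(hardness) − hardness(X), with Parr–Pearson absolute hardness and
Pauling electronegativities packaged as cited data files. The prior weight of
a (fragment, target) pair is |δ_f δ_t| / d̄² with d̄ the mean contact
distance. The mapping from element constants to the partial-charge surrogate
δ is underdetermined; the packaged default is
δ(X) = (χ(X) − χ̄_G) · S(X)/S̄_G, and because of that freedom the packaged
prior-probability table (13 fragment classes × 13 target classes, rows
summing to 1 within rounding) is the default source; the computed route is
labelled experimental and is only checked for scale invariance and
normalization, not against published numbers.

## Structure processing

PDB files are read with gemmi; only X-ray-style criteria are enforced
(resolution ≤ 2.5 Å by default; violations are flagged, never silently
dropped). Alternate locations keep the highest-occupancy conformer, ties
prefer altloc A. Ligand bonds are inferred from distances (sum of covalent
radii + 0.4 Å); rings come from the cycle basis of the bond graph, and a
5/6-ring is aromatic when planar within 0.1 Å with all members C/N/O/S of
degree ≤ 3 — a deliberately self-contained perception that avoids external
chemical dictionaries. Carbonyl-type C–O bonds are recognized below 1.32 Å.
Every admissible Atom2 choice yields its own fragment instance; the choices
are genuinely distinct densities related by rotation about the Main–Atom1
bond. Contact collection uses three distance criteria — H-bond/charged
(O,N–O,N pairs), dispersion, halogen — which are configuration with
non-canonical packaged defaults of 3.3/4.0/3.6 Å. Target atoms are classified
by element, residue and main/side-chain membership via an explicit lookup
table; atoms outside the 13 classes are skipped. Carbamoyl O/N mislabels
(indistinguishable electron densities) can be corrected by swapping the two
coordinates; the swap is an involution and is applied only when explicitly
requested.

## Synthetic data

`CloudSpec` draws clouds from exact ground-truth densities (inverse-CDF
sampling of the truncated von Mises on a 4096-point grid; scipy truncated
normals elsewhere), seeded and deterministic. `gen_fixture_pdb` writes a
minimal PDB with an exemplar ligand (classes f2 and f26 ship exemplars with a
unique Atom2, so manifests map one-to-one onto extracted records) and protein
residue stubs whose classified atom sits exactly at each planted model-frame
position, with the remaining stub atoms placed radially outward beyond the
cutoffs. Coordinates are rounded to the 0.001 Å PDB precision *before* the
manifest is computed, so extraction reproduces the manifest exactly.
Fixtures emulate geometry and classification only — not crystallographic
noise (constant B-factors, unit occupancies), disorder, waters or metals —
so passing fixture tests demonstrates correctness of the extraction
machinery, not robustness to real crystallographic artifacts. Planted
contacts should sit at r ≥ 2.5 Å so the stub backbone stays outside the
default cutoffs.

## Screening

A molecule in a pose is summarized by pmPerMass (sum of direct-contact
probability masses, excluding designated anchor fragments such as
metal-coordinating oxygens, divided by molecular mass in hydrogen-mass
units — an intensive quantity) and Phob/Phil (hydrophobic/hydrophilic
fragment count ratio; undefined and rejected at zero hydrophilic count).
Pose generation is out of scope: features are computed for supplied poses,
and the packaged 27-molecule table (8 ligands, 19 decoys in two subgroups)
carries precomputed features. The ligand/decoy model is logistic regression
with intercept on the two features; a ridge penalty (default 1e-4, slopes
only) keeps the optimizer convergent under the quasi-separation present in
the packaged data (ligand Phob/Phil reaches 12 against a decoy maximum of
4.5). The 0.5-threshold operating point, ROC over the 12 standard
thresholds, and ranking statements are insensitive to the ridge over several
orders of magnitude. Prediction at a threshold uses ≥ (closed on the ligand
side). Bootstrap errors resample each decoy subgroup with replacement,
keeping ligands fixed, and refit; replicates that collapse to a single class
are skipped and counted. Rotatable-bond counts are carried in the table but
never fitted by default.

## Problem sizes and defaults

The test suite and the acceptance script run at desk scale by design: clouds
of 2000 records for parameter recovery, 100 random densities for
normalization and integration checks, million-cell Riemann oracles per 1D
factor, 1000-volume bootstraps, and the 27-molecule screening table. Key
defaults: mode clamp [1, 4]; variance floor 1e-4; κ cap 500; quadrature order
64; bootstrap jitter ±5%; ridge 1e-4; σ₀² = 0.04 Ų; cutoffs 3.3/4.0/3.6 Å.
Every default that stands in for unpublished configuration is marked
non-canonical in `data/defaults.yaml` and surfaced through the CLI.

## Known limitations

* Full-scale training against an archive-wide structure harvest (and the
  reference-set validation that depends on it) is outside the package; the
  packaged prior table is the only large-data artifact shipped.
* Azimuthal sub-intervals never wrap across 0/2π; a cluster straddling the
  fragment plane on the +x side is split into two sub-components.
* The computed chemistry-prior route has no published ground truth (the
  partial-charge surrogate and training-set mean distances are free inputs).
* Conjugate updates use full-circle sufficient statistics; strong truncation
  plus strong priors can re-introduce the moment bias discussed above.
* Aromaticity perception is geometric (planarity) rather than electronic;
  exotic ring systems may be misclassified.
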