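# Methods

## Scope and model

`metacv` captures the *methodology* of characterizing a two-state
conformational transition — descriptor harvesting, discriminant CV
construction, ratchet-and-pawl and well-tempered metadynamics biasing, and
landscape analysis — as a general, testable library.  It deliberately does
not re-implement all-atom MD: the biasing and analysis machinery is exercised
on analytic toy potentials in CV space and on synthetic oligomers, where
every expected result is known in closed form or by quadrature.  What passing
tests show is that the mathematics of the method is implemented correctly;
they say nothing about force fields, solvation, or the conformational
ensemble of any real protein.

## Contact criteria

* **Salt bridge**: minimum distance between acidic side-chain oxygens
  (Asp OD1/OD2, Glu OE1/OE2, C-terminal OXT) and basic side-chain nitrogens
  (Lys NZ, Arg NE/NH1/NH2, His ND1/NE2) ≤ 6 Å.  One contact per residue
  pair; the canonical atoms are the closest O–N pair at detection time, and
  the descriptor tracks that *fixed* pair over the trajectory.  A fixed pair
  keeps the descriptor a plain differentiable distance that exports directly
  to a biasing engine; the per-frame minimum would not.
* **Hydrogen bond**: donor–acceptor heavy-atom distance ≤ 3.0 Å *and*
  deviation from linearity of D–H···A (180° minus the angle at H) ≤ 30°.
  The angle's vertex is stated explicitly because conventions differ between
  tools.  Hydrogens must be present in the input; they are never inferred.
* Pairs within one residue are never reported (this also excludes the
  spurious OXT–NZ "bridge" of a C-terminal lysine with itself).
* **Protomer scope**: interprotomer contacts only, except inside designated
  terminal protomers, where intraprotomer contacts are admitted too — the
  terminal subunits are the ones that move most in an opening/closing
  transition, so their internal rearrangements are informative.
* **Pool threshold**: a contact enters the descriptor pool if its occupancy
  is ≥ `min_occ` (default 0.5) in at least one state.  An `exclusive` flag
  restricts the pool to contacts occupied in exactly one state; the default
  is non-exclusive, since partially shared contacts still carry discriminant
  weight.

## HLDA

With per-state sample means μ and (n−1)-normalized covariances Σ (ridge
ε = 10⁻⁶ Å² on the diagonal to keep constant descriptors invertible), the
within-class scatter is the harmonic mean S_w = (Σ_A⁻¹ + Σ_B⁻¹)⁻¹ and the
discriminant is w ∝ S_w⁻¹(μ_A − μ_B), unit-normalized.  Any constant
prefactor on S_w cancels in the direction, so none is carried.  Design
choices that the method itself leaves open:

* **Sign**: w is oriented so the first state (A) maps to the larger CV
  value.
* **Truncation order**: ranking by |w_i| happens on the full pooled model,
  *then* the top-K survivors are kept (rank-then-truncate); the residue
  filter (e.g. pore-loop contacts) is applied before ranking.  Ties break
  toward the lexicographically smaller label so selection is deterministic.
* **Renormalization**: the truncated weight vector is rescaled to unit norm,
  keeping CV magnitudes comparable across K.
* Two states only; multi-class discriminants and nonlinear CVs are out of
  scope.

## Sampling engines

A fictitious particle of mass m (amu) moves on an analytic potential U(s)
under the BAOAB discretization of underdamped Langevin dynamics.  Internal
units: Å, kJ/mol, ps, amu, K (k_B = 0.0083144621 kJ/mol/K; accelerations use
1 kJ/mol = 100 amu Å²/ps²).  Defaults dt = 0.01 ps, friction 5 ps⁻¹,
T = 300 K, m = 50 amu; the comparatively heavy mass gives the CV particle
the sluggish, diffusive character of a real collective coordinate and a
well-separated Kramers time for barrier crossing.

* **Ratchet-and-pawl**: V = k/2 (s − s_best)² when s lags the running best
  value in the chosen direction, zero otherwise; s_best only ever advances.
  Default k = 5 kJ/mol/Å² (≡ 500 kJ/mol/nm²).  The published protocol of
  choosing k by iterative halving from 10,000 kJ/mol/nm² is a
  human-in-the-loop procedure and is documented here rather than automated.
  For the pawl to rectify diffusion up a slope, k must satisfy
  max|U′| / k ≲ a few × sqrt(k_BT/k); the default double well
  (barrier 15 k_BT, wells 17 Å apart) is sized so this holds at
  k = 5 kJ/mol/Å², while its unbiased Kramers escape probability over a
  10⁵-step run stays ≪ 1.
* **Well-tempered metadynamics**: hills of width σ (default 0.05 Å per CV)
  deposited every `pace` = 500 steps with height
  W = w₀ exp(−V(s)/(k_B(γ−1)T)), w₀ = 1.2 kJ/mol, γ = 20.  Hill evaluation
  is exact by default.  For long 1D runs an optional grid cache (spacing
  σ/5, linear interpolation of energy and analytic gradient) makes the
  per-step force O(1); deposit heights always use the exact hill sum, and
  points outside the cached range fall back to exact evaluation.  The
  interpolation error is sub-percent of the bias and only perturbs the
  dynamics, not the recorded hills.
* **Walls**: one-sided κ(s − bound)² (no ½), default κ = 100 kJ/mol/unit²;
  boundary values are always user-supplied, since they encode where the CV
  stops being meaningful.
* **Multiple walkers** share one hill list and advance in deterministic
  round-robin blocks of `sync_stride` steps.  Within a block a walker sees
  hills deposited by walkers scheduled before it; this deterministic
  approximation of asynchronous file polling is what makes runs exactly
  reproducible.  A one-walker pool is bitwise identical to a single run.
* **FES**: F(s) = −(γ/(γ−1)) V(s) on a user grid, min-shifted to zero.
  Basin free-energy differences integrate exp(−F/k_BT) over each side of a
  dividing point (trapezoidal on the grid); the synthetic reference uses
  adaptive quadrature of the exact potential split at the barrier top.

## Landscape analysis

* **Minima**: strict local minima on the full Chebyshev stencil (all 3ᵈ−1
  neighbors); boundary nodes compare against their existing neighbors.
* **k-means**: scikit-learn's k-means++ under a fixed seed, best of
  `n_init` = 10 starts.  The representative frame of a basin is the member
  sample closest to its centroid (ties → smallest index).
* **Stability**: fraction of a CV series inside a closed axis-aligned box;
  the "stable" verdict defaults to the strict 100% criterion, matching the
  practice of requiring that a follow-up unbiased run never exits the
  minimum.
* **RMSD**: SVD-based Kabsch superposition restricted to proper rotations;
  backbone means atoms named N, CA, C, O.
* **Twist angle**: for each consecutive protomer pair in the given order,
  the Kabsch rotation over matched atoms (same residue number and atom
  name) is extracted and its angle taken from arccos((tr R − 1)/2); the
  reported twist is the mean over interfaces (a `cumulative` flag returns
  the sum instead).  This definition is this package's own — reported twist
  values in the literature rarely state the computation — and is flagged as
  such.

## Synthetic fixtures

* Two-state Gaussian descriptor populations with the exact optimal
  discriminant w* = S_w⁻¹Δμ (population covariances) returned alongside the
  draws.
* Helical toy oligomers: a ~32-atom, four-residue protomer template
  (Gly/Glu/Lys/Ser, hydrogens on every donor) repeated with per-interface
  twist about z and rise along z.  Contacts are planted by moving the
  donor/acidic atom (plus its hydrogen rider) along the existing
  interatomic direction to the exact target distance (realized to ≤ 10⁻⁶ Å;
  an atom claimed twice is a hard error).  Protomers are small so O(N²)
  oracles stay instant.
* Transition trajectories are linear coordinate interpolations plus
  isotropic Gaussian jitter — sufficient to exercise harvesting and CV
  plumbing end to end, but *not* physical paths: they carry no momenta, no
  excluded volume, and no realistic kinetics.
* Every generator is a pure function of its spec, seed included.

## Problem sizes and numerical choices

Test and verification runs use desk-scale sizes chosen so each estimate's
statistical error sits well inside its assertion: 2×10⁴ samples/state for
discriminant recovery, 100 random ~200-atom configurations for detection
oracles, 10 seeds × 10⁵ steps for ratchet efficacy, and 2×10⁶ steps per seed
for free-energy recovery (measured |ΔF error| ≲ 0.8 kJ/mol against the
quadrature reference across seeds).  Ridge ε, the σ/5 cache spacing, and the
10⁻⁶ Å planted-contact tolerance are stated above; float formatting in all
text formats is fixed (%.6f for CV exports, %.9f for HILLS/COLVAR) so
serialization is bit-stable.

## Known limitations

* No periodic-boundary imaging; inputs are assumed whole.
* No insertion codes in atom identifiers; author residue numbering is used
  verbatim.
* H-bond detection requires explicit hydrogens.
* The grid cache is 1D-only; 2D metadynamics runs evaluate hills exactly.
* Toy potentials and oligomers are statistical/geometric stand-ins; no
  attempt is made to mimic any real protein's geometry or energetics.
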