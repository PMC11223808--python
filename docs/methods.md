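# Methods

## The path model

The molecule is described by the 3N coordinates `X` of its retained
atoms. On time scales long compared to momentum relaxation, dynamics
follow the overdamped Langevin equation `γ dX/dt = −∇U(X) + noise`;
rescaling time sets γ = 1, so the total path time `F` is dimensionless
(default 1). The probability of a path is `∝ exp(−β S)` with the
Onsager–Machlup action `S = ½ ∫₀^F (dX/dt + ∇U)² dt`; the most probable
(minimum-action) path between fixed endpoints satisfies the
Euler–Lagrange equation `d²X/dt² = ∇∇U · ∇U`.

The energy surface is deliberately minimal: harmonic expansions around
both endpoints, combined as `U = min(U_A + ΔE, U_B)` with
`U_A(X) = ½ (X−X_A)ᵀ H_A (X−X_A)`. The ½ convention is used
throughout, so `H` is the literal second-derivative matrix of the
underlying ENM energy and the per-well equation of motion reduces to
`d²X/dt² = H²(X − X_ref)`. Within a well this linear boundary problem
has the closed-form solution

    X(t) = X_ref + f(H, t, t_s) (X_ts − X_ref),
    f(x, t, t_s) = sinh(x t)/sinh(x t_s),

applied through the spectrum of `H`. Two scalar kernels matter:

* `f(x, t, t_s)`, computed overflow-safely as
  `exp(x(t−t_s)) (1−e^{−2xt}) / (1−e^{−2x t_s})` with the L'Hôpital
  limit `t/t_s` for `x t_s < 1e-8` (the rigid-body modes);
* the arrival-velocity kernel `x coth(x t_s)` (limit `1/t_s`), which
  defines `M = H coth(H t_s)` mapping `X_ts − X_ref` to the half-path's
  end velocity. `M ⪰ (1/t_s) I`, so the continuity system below is
  strictly positive definite even though `H` itself has a 6-dimensional
  kernel.

## Transition-state search

For a trial time split `(t_A, t_B = F − t_A)`, velocity continuity at
the crossing is the linear system `(M_A + M_B) X_ts = M_A X_A + M_B X_B`,
solved by conjugate gradients with matrix-free products (each product
is two matrix-function applications). Position continuity is automatic
(both halves end at `X_ts` by construction). Energy continuity,
`g(t_A) = U_B(X_ts) − U_A(X_ts) − ΔE = 0`, is enforced by an outer 1-D
search on `t_A`: the midpoint `F/2` is evaluated first (it is the exact
answer for spectrally identical wells, where the CG start guess
`(X_A+X_B)/2` already solves the linear system with zero residual and
the energy gap vanishes identically), then a sign-change bracket on
`[0.02 F, 0.98 F]` is bisected, at most 60 steps. Absence of a sign
change means the requested ΔE admits no well crossing and is an error.

Defaults: `tol_E = 1e-4 · max(U_A(X_B), U_B(X_A)) + 1e-12` for the
energy gap, `1e-4` relative for the velocity residual (the residual is
reported even when met), CG tolerance three orders tighter than the
velocity tolerance. Both residuals, the outer-iteration count and the
CG matvec count are logged so that any pathology is visible; on the
bundled toys the outer search converges in roughly 9–15 evaluations.

## Matrix-function backends

* **dense** (auto-selected for 3N ≤ 3000): one symmetric
  eigendecomposition per well, cached on the operator; eigenvalues in
  `[−1e-8·scale, 0)` are clamped to zero (numerical noise on the
  rigid-body kernel), anything more negative aborts — an ENM Hessian at
  its own reference must be positive semidefinite.
* **krylov**: Lanczos with full reorthogonalization (twice per step);
  the subspace grows in steps of 10 up to order 100, stopping when
  successive iterates of `‖v‖ V_m f(T_m) e₁` differ by < 1e-8
  relative; an invariant subspace (breakdown) terminates early and is
  exact. Non-convergence at the cap produces a warning with the
  attained change, not silent acceptance.

The two backends agree to ~1e-10 on systems small enough to run both;
this is asserted in the tests and re-measured by the acceptance script.

## Elastic networks

Networks are built on each endpoint's **own** geometry (H_A from X_A,
H_B from X_B), so the two wells genuinely differ when the conformations
do. Geometries:

* **cutoff**: all pairs within `R_c`, via a k-d tree. Defaults
  `R_c = 13 Å` for one-bead-per-residue, `8 Å` for all-atom — the
  low-to-middle of the ranges in common use. Isolated atoms are an
  error (they would add spurious zero modes).
* **Delaunay** (default): the 1-skeleton of the 3-D Delaunay
  tetrahedralization — parameter-free, and robust for dangling or
  loosely connected parts. Degenerate (coplanar) inputs are retried
  once with a 1e-6 Å jitter from a fixed seed; rest lengths always come
  from the unjittered coordinates. An optional `--max-edge` cap exists
  but is off by default.

The Tirion Hessian is assembled at the rest state, where the
`(r − r⁰)` terms vanish and each edge contributes exactly the rank-1
block `k û ûᵀ` (û the unit edge vector): the operator is sparse, exactly
PSD, and carries exactly the six rigid-body zero modes for any
non-degenerate connected network.

Spring constants default to `k₁ = k₂ = 0.1 kcal/mol/Å²`. The
calibration `k = A/⟨B⟩` from the mean crystallographic B-factor is
provided and logged (with a warning outside the empirically expected
window 0.16 ± 0.09 kcal/mol/Å²), but not applied automatically: ⟨B⟩ of
both inputs is reported so users can set the k₁/k₂ ratio themselves.

## Go-like potential

For proteins a CA-only structure-based potential is available:
quadratic virtual bonds (i, i+1) and angles (i..i+2), a two-term cosine
dihedral (i..i+3), and a 12-10 native-contact term
`ε[5(σ/r)¹² − 6(σ/r)¹⁰]` for CA pairs within 8 Å separated by ≥ 4
residues in a chain (inter-chain pairs always qualify). Constants are
the classic CA parametrization, `K_bond = 100 ε/Å²`,
`K_angle = 20 ε/rad²`, `K_dih,1 = ε`, `K_dih,3 = ε/2`, `ε = 1
kcal/mol`, so the model needs no user parameters. The native structure
is the exact minimum; the Hessian is therefore the Gauss–Newton sum of
positively weighted outer products of the internal-coordinate
gradients (coefficients `2K_b`, `2K_a`, `K₁ + 9K₃`, `120 ε/σ²`) —
exactly PSD with the same rigid-body kernel, satisfying the same
operator contract as the Tirion Hessian. Non-native repulsion is
excluded: it contributes nothing at the native state, which is the only
point where the Hessian is taken. Nucleic acids are rejected with a
clear error.

## Matching and superposition

Different atom counts and chain namings between the two inputs are
reconciled by global sequence alignment (match +1, mismatch 0, gap open
−10, extend −0.5 — chosen to strongly favor ungapped matches of
near-identical chains, the regime of real endpoint pairs), all chains
against all chains of the same polymer type, followed by a greedy
one-to-one assignment by descending score with a minimum score of 10.
The assignment is content-driven, so crossed chain namings are resolved
correctly. Aligned amino-acid pairs are retained when both residues
fall in the same of five physico-chemical classes — (P,A,G,S,T),
(D,N,E,Q), (H,K,R), (F,Y,W), (V,L,I,C,M) — nucleotides must be
identical; atoms of retained residue pairs are paired by name. Modified
residues outside the standard alphabets are excluded.

Endpoint B is rigidly superposed onto A (proper-rotation least squares
over the common atoms) before any network is built. This removes
spurious rigid-body motion from the path; it also means all reported
RMSDs live in this shared frame, and per-frame RMSDs are *not* refit by
default (`--fit-per-frame` opts in) so that rigid drift along the path
stays visible.

## Trajectory analytics

* Per-frame energy is the two-well `U = min(U_A + ΔE, U_B)` evaluated
  from the quadratic wells — the surface the path actually moves on.
* `Q1`/`Q2` are the fractions of the start/target structure's contacts
  still formed, where the contact sets are the endpoint elastic-network
  edge lists and a contact counts as formed when `r ≤ λ r⁰`, λ = 1.2.
  Both the contact set and λ are documented knobs (`--q-lambda`); Q
  values are therefore comparable between runs of this package, not
  across tools with other contact definitions. Note the criterion is
  stretch-only: transitions that purely compress an interface leave Q
  at 1.
* The action `S` is reported diagnostically by trapezoidal quadrature
  with central-difference velocities and the gradient of the active
  well; it converges from above as the frame count grows and is never
  optimized directly.

## Synthetic test systems

The fixture generators emulate the geometry of real transitions at toy
scale: `make_helix_pair` (hinge bending of an ideal CA helix),
`make_dumbbell_pair` (two rigid quasi-lattice lobes joined by a linker;
closure = 14 → 11 Å approach plus a 100° twist of one lobe about the
inter-lobe axis, so each endpoint owns interface contacts and both Q1
and Q2 move along a path), and `make_mutation_pair` (same backbone,
mutated identities, for the class-matching rule). All are deterministic
in their seed and write both PDB and mmCIF, so the I/O layer is
exercised by every integration test. They are *not* physically
realistic proteins: B-factors are a seeded spread around 25 Å², lobes
are internally rigid, and no side chains exist — so passing tests
certify the mathematics and the pipeline, not force-field realism on
real structures.

On the dumbbell toy, stiffening the start well (k₁ = 5k₂) moves the
transition earlier in time and its Q2 below the symmetric setting;
stiffening the end well mirrors this — the two Q1-vs-Q2 curves bend to
opposite sides of the symmetric curve, which is measured at the curve's
corner (the transition frame) because Q1 along these paths is
non-monotone with a much smaller dynamic range than Q2, making
interpolation at a fixed Q1 level ill-conditioned. Both asymmetric
settings pay a substantially higher transition-point energy than the
symmetric one.

## Numerical choices and limitations

* Bisection (not a faster root finder) for `t_A`: `g` is cheap,
  monotone in practice, and bisection is unconditionally robust.
* Uniform frame times over `[0, F]`, with the interior grid point
  nearest `t_A` replaced by `t_A` so the transition state is always a
  frame; first and last frames are set to the endpoints exactly.
* Identical endpoints short-circuit to a constant trajectory.
* Alternate locations keep the highest occupancy (first on tie);
  insertion codes are carried through residue identity.
* Problem sizes in the tests and the acceptance script (5–200 atoms,
  ≤ 41 frames) were chosen as the smallest systems that exhibit each
  property being measured; all quantities are size-free errors,
  fractions or counts.
* The transition state of a two-well harmonic surface is generically
  high in energy; no post-hoc relaxation of the path is performed.
  Anisotropic or B-factor-refined per-pair spring constants, nucleic
  acid Go models, and multi-well (> 2) surfaces are out of scope.
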