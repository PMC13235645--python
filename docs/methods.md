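# Methods

## The model

Each plasmid is an unknotted ring of `N` beads of diameter `s` (2.5 nm,
about 7.4 bp of double-stranded DNA).  Energies are measured in `k_B T`,
lengths in `s`, times in the Lennard-Jones unit `tau`; one time unit is
1000 integration steps at the default `dt = 0.001 tau`.  Every bead also
carries a right-handed orthonormal triad `[u, f, v]` that represents the
local material frame of the double helix, stored as a unit quaternion.

The potential energy is the sum of

* **WCA repulsion** between all bead pairs (cutoff `2^(1/6) s`), under the
  minimum-image convention in the periodic box;
* **FENE bonds** between consecutive beads (`K = 40 eps/s^2`,
  `R0 = 1.6 s`), giving an equilibrium bond length near `0.97 s`;
* **Kratky-Porod bending** on consecutive bond vectors (`K_bend = 20`),
  which alone would give a persistence length
  `l_p = -b / ln(coth(beta K) - 1/(beta K)) ~ 19.5 s`;
* **tilt** (`K_tilt = 200`) locking `u_i` to the bond direction `t_i`;
* **two dihedral terms** per bond (`K_torsion = 50` each) penalising the
  rotation of `f` and `v` about the bond between consecutive beads, which
  gives the ribbon its torsional stiffness.

All gradients are analytic, including the rotational generalized forces
(the derivative of the energy with respect to an infinitesimal body
rotation of each triad) and the translational forces induced by the tilt
and dihedral terms through their dependence on the bond vector.  A central
finite-difference check at relative tolerance 1e-5 is part of the test
suite.

Two deliberate realization choices:

* **Preferred pitch angle `psi0`.**  The dihedral pair as written is
  minimal at aligned frames.  For `psi0 != 0` we evaluate the dihedrals
  with the second bead's ribbon vectors pre-rotated by `-psi0` about that
  bead's *own* long axis `u` (a body-fixed rotation).  This puts the
  minimum at a relative frame rotation of `psi0`, reduces exactly to the
  bare form at `psi0 = 0` (the only case used in the driven study), and
  keeps all gradients exact because the pre-rotated vectors are still
  body-fixed.  Rotating about the bond axis instead would make the
  rotation position-dependent and complicate the force expressions with no
  physical benefit, since tilt keeps `u` and the bond aligned to within a
  few degrees.
* **Frame-induced stiffening.**  The tilt + dihedral chain adds a small
  effective bending stiffness on top of `K_bend`: bending the backbone
  forces consecutive frames apart, which the dihedrals resist.  Measured
  `<cos theta>` in equilibrium is ~0.956 versus 0.950 for the bare
  Kratky-Porod weight, i.e. `l_p` is ~22 s rather than 19.5 s.  The
  sampling tests therefore check the bond-angle marginal against the bare
  weight only with the frame terms switched off, and check the full model
  through the dihedral marginal (a von Mises law with concentration
  `2 K_torsion`) and the `<cos theta>` moment at a tolerance that brackets
  the stiffening.

## Dynamics

Translations and rotations follow an underdamped Langevin equation with
friction `gamma = 1/tau` and thermal noise obeying the
fluctuation-dissipation relation; rotations use a scalar moment of
inertia (default 1, exposed as a parameter — its value only affects how
fast orientations equilibrate, not equilibrium averages).  Both sets of
degrees of freedom are integrated with a BAOAB splitting; quaternions are
advanced by exact incremental rotations, which preserves orthonormality of
the triads to rounding.  The free-particle limits (velocity decay at
`T = 0`, Einstein relation `D = k_B T/(m gamma)`), equipartition, and the
Boltzmann marginals above are all asserted by the suite.

**The supercoiling agent** is a fixed torque `+-TQ` applied about one bond
of each ring, with the two dihedral potentials removed on that bond (the
tilt term is kept — only the dihedrals are released).  The torque is
applied directly to the two bond beads' rotational equations; in force
language it is a couple at lever distance `0.80 s` from each bead center,
which at `TQ = k_B T` and 300 K corresponds to 2.07 pN.  The accumulated
relative frame angle `psi_a` across the motor bond (incrementally
unwrapped, no modulo jumps) measures the injected supercoiling
`sigma = psi_a / (2 pi N)`; its sign is chosen so positive torque produces
positive writhe.  At `TQ = 0` the motor bond is simply a torsionally free
("nicked") joint.

**Preparation** starts from flat circles (untwisted frames, `Tw = 0`) on a
primitive cubic lattice, then iterates short thermalization runs with a
coordinate-and-box rescale by `(L0 - s)/L0` per cycle until the target
density, followed by an equilibration run.  Pairwise Gauss linking numbers
are verified to be zero after compression (an error otherwise).

## Topology

* **Gauss integrals** are evaluated segment-pair-wise with the exact
  solid-angle formula for polygons, so linking numbers of disjoint
  polygonal curves are integers to rounding rather than quadrature
  approximations.
* **Lk of a ribbon** is the Gauss integral between the bead contour and an
  edge curve offset by `eps` along the material normal `f` (default
  `eps = 0.2 s`, halved adaptively until the result is integer-stable).
  The offset must be perpendicular to the backbone: offsetting along the
  bond-aligned vector `u` cannot register twist and breaks the
  Calugareanu-White identity, so the ribbon edge uses `f`.
* **Tw** accumulates the rotation of `f` about the contour measured
  against a parallel-transport reference frame; **Wr** is the self Gauss
  integral.  `Lk = Tw + Wr` to better than 1e-3 on all ribbon fixtures is
  a three-way cross-check of independently coded quantities.
* **Local writhe profile** `W(i)`: the Gauss kernel between the two
  sub-contours `[i - w, i]` and `[i, i + w]` (window `w = 20` beads, about
  one persistence length).  Plectoneme tips appear as cyclic local maxima;
  branches are maxima with `W >= W_thr` (default 0.35), plateaus counted
  once at their leftmost index.  The detector thresholds signed maxima, so
  profiles of negatively supercoiled rings should be negated before
  counting.  Known biases (open tips undercount, wrapped branches
  overcount) are reported, not corrected.

## Threading

A disk-like surface is spanned on every ring: a fan from the centroid
refined once by midpoint subdivision to exactly `4N` triangles.  The ring
beads *and* the chord midpoints subdividing the boundary edges are held
fixed (they lie on the ring polygon); the `N + 1` interior vertices are
relaxed by gradient descent on total area with backtracking line search,
stopping when the relative area change stays below 1e-6 for ten
consecutive iterations (at most 1e4).  Non-converged surfaces flag the
snapshot for exclusion.  Against an L-BFGS reference on saddle boundaries
the relaxed areas agree to ~0.1 %.

Piercings of another ring's contour through the surface use
Moller-Trumbore segment/triangle intersection; under periodic boundaries
all 27 nearest images with overlapping bounding spheres are tested, and
piercings from all images are merged into one record per directed pair.
An odd total piercing count is a numerical failure (the pair is excluded
after one deterministic 1e-9 nudge retry).  Ordered piercing positions cut
the threader contour into bead-count segments `L_1..L_p` (sum exactly
`N`); the separation length is `L_sep = min(sum even, sum odd) <= N/2`.
The directed graph (edge = threading with `L_sep` above the threshold,
default 0) is decomposed into weakly connected components; `f_max` is the
largest-component fraction and `f_0` the fraction of isolated (dangling)
rings.

## Effective 1D Monte Carlo model

Each ring becomes a doubly folded linear chain of `N_eff` sites (default
50) moving in unit curvilinear steps.  A threading carries an active
coordinate `x_a` on the threading chain (initialized from the MD snapshot
as `L_sep N_eff/(N/2)`, rounded and clamped) and a passive coordinate
`x_p` on the threaded chain (placed uniformly, or end-excluded with a
margin — the surface analysis cannot locate passive piercings on the
contour, so both placement rules are provided without claiming either is
correct).  Per sweep every chain, in random order, attempts one step: a
passive threading at the facing end rejects the move; an accepted move
shifts all coordinates carried by the mover by the step; an active
coordinate leaving the chain removes the threading from both partners.  No
threadings are ever created, so the count is monotone non-increasing.
Frame convention: "moving right" adds `+1` to every coordinate expressed
in the mover's own contour frame; partner-frame coordinates are untouched
by the partner's motion.  Note that a two-chain cycle with a *single*
mutual end-blocking passive each can still relax (the chain drifts the
unblocked way until its own active coordinate escapes); the minimal truly
frozen motif is mutual double threading, with each chain pierced at both
of its ends — this is the `deadlock` network fixture, asserted frozen over
1e6 sweeps.

## Scaled-down study conditions

The full-scale study (M = 200 rings of N = 400 beads, box `L = 100 s`,
runs of 4e6 tau) is cluster-scale.  The package's tests and the
acceptance script instead run desk-scale systems chosen to sit in the same
physical regimes:

* **Driven runs:** M = 8 rings of N = 48 beads at melt-like density
  `rho s^3 = 0.2`, driven for 120 tau with `beta TQ` of 2 and 10,
  four independent replicas of the high-torque run for population
  statistics.  Small stiff rings have a far higher overlap concentration
  than 3 kbp plasmids, so the above-overlap, percolating-threading-network
  regime (overlap parameter ~4 in the full-scale study) is reached here by
  raising the monomer density to 0.2 rather than the chain length; at the
  study density 0.08 the same small rings sit below overlap and their
  equilibrium threading graph is sparse.
* **What carries over:** supercoiling builds and saturates with
  plateau increasing with torque (|sigma| ~ 0.1 at `beta TQ = 10`, above
  the ~6 % typical of plasmids because tiny rings store relatively more
  writhe per bead); the mean threading number drops sharply after the
  activity onset while the dangling fraction grows.
* **What does not:** absolute time scales (the full-scale diffusive
  crossover near 1e6 tau, the Gamma(t, t') curves at t' = 1e4 tau),
  cluster-size statistics at M = 200, and branch-number statistics over
  long aging windows are not reproducible at this size; nothing in the
  tests asserts them quantitatively.  The threaded-versus-dangling
  mobility ordering (threaded rings slower) is, at this system size and
  run length, at or below statistical noise: pooled four-replica g3/t
  ratios across independent seed families straddle 1.  The suite still
  computes and asserts the faithful pooled statistic, so that check
  documents the desk-scale limitation rather than hiding it; resolving the
  ordering would need runs one to two orders of magnitude longer (the
  regime where the full-scale study observes it).
* At `beta TQ = 10` the driven runs very occasionally break a FENE bond
  at `dt = 0.001` (a known hazard of fixed-step Langevin integration under
  strong local driving); driven-run helpers treat this as a retriable
  event with a fresh noise seed rather than lowering the global timestep.

## Numerical choices and degenerate inputs

* Bond of zero length in bend/tilt/torsion: domain error; bond parallel to
  a frame vector in a dihedral: that pair is skipped (degenerate cross
  product).
* FENE at `r >= R0` (or non-finite coordinates) aborts the run with the
  ring and bond index.
* Gauss solid angle of touching or coplanar segment pairs is zero (the
  kernel's principal value), which also implements the excluded self-pairs
  of the writhe and the profile.
* The branch detector on an exactly constant profile reports zero tips.
* Cell lists for the WCA search cap the grid at ~4 cells per particle so
  the per-step reset stays O(beads); below three cells per side the search
  falls back to the all-pairs minimum-image loop.
* MSD refuses wrapped input (a jump larger than `L/2` between frames);
  trajectories store unwrapped coordinates throughout, and the dump reader
  re-wholes rings by minimum-image walking, validating every bond against
  `R0`.

## Known limitations

* One motor per ring, fixed torque; no enzymatic kinetics (bursts,
  waiting times, strand passage).
* Rotational friction and inertia are scalar and bead-isotropic.
* Rings comparable in size to the periodic box (unavoidable at desk
  scale) make image-merged threading records approximate when one ring
  threads two images of another simultaneously.
* No hydrodynamic interactions; no knot classification (rings are
  prepared and verified unknotted).
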