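# Methods

## Representation

The package converts a time-ordered series of molecular poses into a static
"motion structure".  Each selected atom's positions across the $M$ poses
become the control points of a per-atom pathline; the pathlines, a single
imposed backbone pose, and optional trailing ribbons or ladder rails are
assembled into a scene of colored primitives and serialized for rendering,
interactive viewing, or 3D printing.  The underlying assumption is that the
pose series is uniformly spaced in simulation time and that the selected
atoms (the C$\alpha$ trace by default) carry the conformational signal while
filtering out high-frequency side-chain motion.

## Pathline splines

Pathlines are natural cubic splines through each atom's pose positions,
parameterized by pose index.  Parameterization is uniform, not chord-length:
poses are uniformly spaced in time, and time — not geometry — is the
physically meaningful parameter.  "Natural" is taken literally: the second
derivative is pinned to zero at both end knots, so the interior moments
solve the classical tridiagonal system (solved per axis with a banded
LAPACK routine).  For $M = 2$ the spline degenerates to the straight
segment.  Consequences tested and relied upon elsewhere:

* evaluation at knots reproduces the control points exactly (to 1e-9 Å);
* the curve is C² across interior knots;
* fitting commutes with rigid rotation and translation (the solve is linear);
* collinear input reproduces the line to round-off.

Evaluation refuses extrapolation outside $[0, M-1]$; there is no data beyond
the first and last pose, and a natural spline's linear extension would
invent motion.  Arc length uses 16-point Gauss–Legendre quadrature per knot
interval (the integrand is the norm of a quadratic, so this is effectively
exact); it is additive over adjacent intervals and monotone.

No smoothing is applied beyond pose subsampling.  The degree of smoothing is
controlled by which and how many poses the user feeds in (`--poses`); any
low-pass filter would hide exactly the thermal-noise structure some users
want to see.

## Excursion detection

Smooth interpolants can rarely overshoot dramatically between poses,
producing petal-shaped loops.  Per knot interval we report the **excursion
ratio**: the maximum distance from the curve (64 dense samples by default)
to the chord segment between the interval's control points, divided by the
chord length (guarded by ε = 1e-12 Å for stationary atoms).  The default
flag threshold is 2.0 — an excursion twice the chord.  The paper-regime
calibration is behavioral, not numeric: Brownian wander of an atom within a
couple of atomic radii produces ratios mostly below 1 (measured flag rate
≈ 0.3% of 20-pose trajectories), while an abrupt 100× jump in an otherwise
small zigzag drives the ratio of the adjacent small-chord intervals far
above 2.  The threshold is exposed (`detect_excursions(..., threshold=)`).

## Coloring and the ribbon fade

Two piecewise-linear RGB gradients: temporal (blue → red → yellow over the
trajectory) applied to tubes, ribbons and rungs; sequential (red → green →
blue along the chain) applied to the backbone, chosen so the two palettes
overlap only at their endpoints.  Interpolation is linear in RGB space —
only the waypoint colors are semantically fixed, and linear RGB keeps every
exporter bit-reproducible.  Out-of-range gradient parameters are clamped
with a logged warning rather than raised: endpoint jitter from sampling must
not abort an export.

Ribbon opacity fades linearly: $\alpha(\Delta t) = \alpha_{\max}\max(0, 1 -
\Delta t / L)$ where $\Delta t$ is the pose-index lag behind the backbone
and $L$ the fade length.  Defaults $\alpha_{\max} = 0.6$ and $L = 20\%$ of
the pose span are aesthetic choices (nothing in the method fixes them) and
are exposed as flags.

## Scene geometry

* **Tubes** are extruded along $(M-1)s + 1$ uniform samples with
  parallel-transport ring frames — the frame is rotated by the minimal
  rotation between successive tangents — rather than Frenet frames, which
  flip at inflection points.  Rings have $r \ge 3$ vertices; the tube is
  open-ended, giving exactly $((M-1)s+1)\,r$ vertices and $2(M-1)s\,r$ side
  triangles.  Coincident consecutive samples (stationary atoms) reuse the
  previous tangent; a fully stationary pathline yields a degenerate
  zero-area tube, which is valid geometry but excluded from the
  non-degeneracy guarantees.
* **Backbone**: one sphere per atom at $S_k(t_b)$, $K-1$ linking cylinders.
  Backbone time defaults to the final pose; `backbone_snap` rounds to the
  nearest input pose for users who distrust interpolated bond geometry.
  Linking cylinders interpolate their two atoms' sequential colors (the
  flat-vs-interpolated choice is free; interpolation avoids color steps).
* **Ribbons** pair pathlines disjointly — (1,2), (3,4), … in chain order,
  $\lfloor K/2 \rfloor$ ribbons — which reproduces three ribbons among six
  pathlines; the alternative reading (every sliding pair) would give five.
* **Ladder rails** place rung cylinders between *adjacent* pathlines at
  every `rung_interval` poses (default every pose, with the final pose
  always pinned), so the printed model is one connected component; this is
  verified by union-find over primitive anchor points with reach equal to
  each primitive's radius.
* **Camera** is always computed, never hard-coded: on +z at 2.5× the
  bounding-sphere radius of the control points, looking at their center,
  with one key light offset above-right of the camera.  Users retune it by
  editing the exported `#declare` variables.

Default radii — tube 0.3 Å, backbone sphere 1.0 Å, linking cylinder 0.5 Å,
rung 0.4 Å — make the single-pose backbone read as visually dominant over
the pathline field; all are configurable.

## File formats

* **PDB input**: fixed-column ATOM/HETATM records, poses delimited by
  MODEL/ENDMDL in file order (MODEL serial numbers are ignored — trajectory
  dumps renumber them inconsistently).  Every model must present the
  identical ordered roster of (name, resname, chain, resseq, icode)
  identities; the first mismatching model is named in the error.  Alternate
  locations other than blank/'A' are dropped for deterministic roster
  matching; HETATM is opt-in; TER-based chain splitting of the backbone
  links is exposed rather than guessed.  The reader is hand-written because
  the pipeline needs line-numbered parse errors and per-model roster
  diagnostics; biotite independently verifies round-trips in the tests.
* **POV-Ray**: native `sphere`/`cylinder` primitives plus `mesh2` blocks
  with one texture per vertex; opacity maps to `transmit` $= 1 -$ opacity
  (POV's convention, stated explicitly since transparency encodings vary).
  Cylinder pigments use the mean of the two end colors (POV cylinders take
  a single pigment; the gradient is preserved in the tessellated formats).
  Numbers print with 6 significant digits.
* **VRML 2.0**: everything tessellated (UV spheres 8×12, capped 12-sided
  prisms), merged into one IndexedFaceSet per connected component,
  `colorPerVertex TRUE`, fixed-decimal numbers (no scientific notation —
  printer toolchains reject it), membranes dropped with a warning.
* **PLY** (ascii): single merged mesh, per-vertex 8-bit RGBA; membranes are
  omitted, mirroring the opaque on-screen form of the visualization.  PLY
  was chosen over OBJ because per-vertex color is standard PLY; OBJ has no
  portable color extension.

All writers emit LF line endings and locale-independent formatting, so
identical scenes produce byte-identical files.

## Synthetic trajectories

The fixtures emulate three motion archetypes and carry analytic ground
truth:

* **Hinge** — a stationary chain segment plus an arm rotating rigidly about
  an axis through the last fixed atom; arm-atom arc length is $d\theta$ and
  the 180° end-to-end displacement is the diameter $2d$.
* **Helix half-turn** — two ideal helices (rise 1.5 Å, 100°/residue, C$\alpha$
  radius 2.3 Å) rotating 180° about their own vertical axes, with a
  protruding pseudo-γ carbon per lysine residue at twice the C$\alpha$
  radius so the side-chain (CA+CG) selection path is exercised; orthogonal
  Procrustes between first and last pose recovers the half turn per helix.
* **Thermal jitter** — i.i.d. zero-mean Gaussian displacement (per-axis σ)
  of every atom in every pose, so per-atom RMS displacement is σ√3.

What they deliberately do not model: bonded geometry and sterics at
interpolated positions, solvent, correlated thermal motion, or realistic MD
force fields.  Passing tests therefore demonstrate the geometric and
serialization pipeline, not the physical plausibility of interpolated
conformations — interpolated bond lengths between widely spaced poses are
inaccurate by construction, which is exactly why the backbone can be snapped
to an input pose.

## Problem sizes and numerical choices

The test suite and the acceptance script run on small scenes (≤ 24 pathlines,
10–200 poses, 200 random spline trajectories with $M \in [3, 20]$), sizes at
which every closed-form count and analytic ground truth is checkable
exactly; the pipeline itself is vectorized per pathline and scales linearly
in atoms × poses × tessellation density.  Key tolerances: spline-vs-dense
oracle 1e-8 Å; knot reproduction 1e-9 Å; numerical end-curvature 1e-3
(finite-difference stencils at h = 1e-4 — the stencil's own truncation error
scales with the interior moments, so this bound applies in the smooth-input
regime the method targets); VRML round-trip 1e-4 Å (print precision); PLY
color 1/255 (8-bit quantization).

## Known limitations

* No viewpoint or pose-count optimization: choosing informative views and
  temporal resolution remains the user's job, by design.
* Flower-petal excursions are inherent to smooth interpolation; they are
  detected and logged, not removed.
* Chain breaks never split the backbone automatically; whether a break in
  the author's chain labeling should break the rendered backbone is the
  user's call, via the `split_chains` flag (`--split-chains`).
* mmCIF and binary trajectory formats (DCD/XTC) are out of scope; convert
  to multi-model PDB first.
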