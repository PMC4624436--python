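# Methods

`altconf` rebuilds a crystallographic protein model residue by residue as a
*multiconformer* model: each residue carries 1–4 discrete conformations with
occupancies `w_i ∈ [t, 1]`, `Σ w_i ≤ 1`, selected so the occupancy-weighted
calculated density best explains the observed map. This note records the
model, the parameters that matter, the synthetic-data protocol, and the
numerical choices, in enough detail to reimplement or audit each step.

## Density model

Observed maps are real-space grids in an orthogonal P1 box with an affine
grid→Cartesian mapping. Calculated density is a sum of isotropic Gaussians
per atom from 5-term element form factors (four Gaussians + constant; the
constant treated as a zero-width Gaussian, floored at an effective width of
0.5 Å² to stay integrable). The atomic displacement parameter B enters by
the standard isotropic Debye–Waller substitution `b_k → b_k + B`, so one
atom's map integral equals its electron count — verified to 2% by numeric
integration at spacing d/4. Atom contributions are truncated beyond
`3 + r(d)` Å. Anisotropic B tensors are reduced to their isotropic
equivalent (trace/3) for density calculation.

Before fitting, the observed map is put on the calculated map's scale by a
least-squares linear model `obs = gain·calc + offset` over the masked model
region, and each residue's fitting target is the *residual* map
`obs − calc(background)`, where the background is every atom not being
rebuilt. The rebuilt set per residue k is: sidechain atoms beyond Cβ, the
carbonyl O of k, and (when flip sampling is active) the peptide atoms C(k)
and N(k+1). This background-subtraction target emulates an omit map; no
reciprocal-space refinement is performed anywhere in the package.

## Backbone sampling

For residue k, a fragment of 7 consecutive residues centered on k is
extracted (truncated at chain ends). The free degrees of freedom are the
φ/ψ dihedrals of the interior residues; N, Cα, C of the two end residues
are anchors. All moves are pure dihedral rotations, so covalent geometry is
preserved exactly.

**Thermal-ellipsoid surrogate.** In place of an anisotropically refined
displacement tensor, the guide atom's ellipsoid is the density-weighted
second-moment tensor of the (positive part of the) scaled observed map
within `r(d) + 0.5` Å of the guide atom (Cβ; backbone O for glycine). The
tensor is scale-invariant in the map values; if no positive density is
present an isotropic fallback of (radius/2)² is used with a warning.

**Guide displacements.** Six targets at `± mc_ampl·√λ_j·ê_j` along the
ellipsoid eigenvectors, with a uniform random addition of `± 0.05·√λ_j` to
the magnitude (seeded). `mc_ampl` takes the values 0.1, 0.2 and 0.3; one
model is produced per value and recovery is judged across all three.

**Nullspace inverse kinematics.** Each displaced target is reached by
Gauss–Newton steps restricted to the nullspace of the anchor Jacobian
(SVD, relative singular-value cutoff 1e-8; the anchor Jacobian has rank 6,
leaving a 4-dimensional nullspace for a length-7 fragment), followed by a
Gauss–Newton anchor correction after every accepted step, under a monotone
backtracking line search (guide–target distance never increases).
Convergence: guide within 0.05 Å of target or 200 iterations; converged
solutions keep anchors within 0.01 Å. Steps are capped at 0.3 rad with a
small ridge (1e-3) on the reduced normal equations.

**Peptide flips.** Four recurrent flip geometries (two ≈180° rotations of
the peptide plane about the Cα–Cα axis with different in-plane
translations, and one each ≈+120°/−120°) are stored as centroid coordinates
in the canonical peptide frame (x along Cα1→Cα2, y the Gram–Schmidt
orthogonalized Cα1→O1, z their cross product). A flip candidate is built by
rigidly mapping the centroid into the current peptide's frame and then
*realizing* it with the same nullspace IK machinery (targets = the five
peptide atoms, Cα goals down-weighted 0.4 vs 1.0 for the plane atoms,
with a full-weight restart kept if it lands closer; seeds = ±nominal
crankshaft ψ(k)/φ(k+1) rotation). A realization is kept only if it
registers as a genuine flip of the starting peptide (rotation ≥ 90°,
carbonyls apart, flanking Cα reconverged < 1.5 Å). Flip sampling is
suppressed in helices and strands, assigned by a φ/ψ-window run-length
heuristic (helix windows over runs ≥ 4, strand over runs ≥ 3) — a
deliberate simplification of a full DSSP-style assignment.

Candidate count per residue: (1 unflipped + 4 flipped) × (1 undisplaced +
6 displaced) = 35 where flips are allowed, 7 otherwise. The identity
conformation is always a candidate, so single-conformer residues can stay
single. A residue whose fragment center falls at a chain end cannot move
(its atoms are anchors) and keeps only the identity candidate.

## Sidechain sampling

Sidechains are built on each backbone candidate from ideal residue
templates (chemical component dictionary) by sequential atom placement
with template internal coordinates; chi-defining torsions are shifted so
built χ angles equal the request exactly (ring residues rebuild their rings
template-consistently). Rotamers come from a shipped plain-text library in
the penultimate style covering all 18 χ-bearing types; the modal values are
standard but the file is not a byte copy of any published library.

* Small residues (Asn, Asp, Cys, Ile, Leu, Pro, Ser, Thr, Val): every
  rotamer, every χ offset in {−20, −10, 0, +10, +20}° per χ (Cartesian
  product), on every backbone. Ser: 3 rotamers × 5 offsets × 35 backbones
  = 525 candidates.
* Large residues (Arg, Glu, Gln, His, Lys, Met, Phe, Trp, Tyr): hierarchical
  sampling — per level, 12 offsets covering a 50° window in 4.5° steps on
  χ_ℓ; survivors selected by the occupancy selector fitting density up to
  the atoms built so far; survivors per level capped at floor(1/t).
* Proline: ring closure forbids free χ rotation; χ1 is adjusted by rotating
  Cγ about the Cβ–Cδ "flap" axis (preserving ring bond lengths exactly),
  with offsets restricted to {−10, 0, +10}°. Built proline χ is therefore
  approximate, unlike every other type.
* Candidates whose sidechain (beyond Cβ) overlaps another fragment
  residue's backbone worse than 0.4× the van-der-Waals radius sum are
  discarded.

## Occupancy selection (QP → MIQP)

Over the union of voxel spheres of radius `r(d) = 0.7 + (d − 0.6)/3` (d <
3 Å; `0.5 d` above) around every candidate's Cβ-and-beyond and carbonyl-O
atoms, the selector minimizes `‖ρ_obs − Σ w_i ρ_i^c‖²` subject to
`w_i ∈ {0} ∪ [t, 1]` and `Σ w_i ≤ 1`. The threshold t makes the fit
parsimonious and bounds the conformer count by floor(1/t).

* Convex pre-fit: threshold relaxed to 0 (accelerated projected gradient
  onto `{w ≥ 0, Σ ≤ 1}`, then an exact active-set polish on the identified
  support).
* Exact stage: enumeration of support sets up to size floor(1/t) in
  tie-break order (size, then lexicographic); a batched unconstrained
  least-squares lower bound prunes supports that cannot beat the incumbent
  (the bound is exact, so pruning never changes the optimum). Each
  surviving support is solved exactly by a primal-dual active-set method
  accepted only with a verified KKT certificate, with exhaustive active-set
  pattern enumeration as the fallback when the certificate fails. Ties
  break toward fewer conformers, then lexicographic support. When more
  than 30 candidates survive the pre-fit, the 30 largest pre-fit weights
  are kept (with a warning); when the total candidate count is ≤ 16
  (notably in fragment synchronization, whose combined columns are highly
  collinear) the enumeration runs over all candidates, since restricting
  to one relaxed support can lose the integer optimum there.
* Threshold schedule: t = 0.25 for d < 1.8 Å (up to 4 conformers), t = 1/3
  at 1.8 Å and worse (up to 3). The schedule is a package default — the
  resolution dependence is qualitative in the source protocol and no
  numeric values are published — and is overridable per run.

**Fragments.** Maximal runs of consecutive residues with ≥ 2 backbone
conformations (pairwise backbone RMSD > 0.1 Å) are re-synchronized: all
`C_f = Π C_i` combinations of per-residue conformers become combined
candidates for one MIQP whose selected combinations each carry a single
occupancy for every atom in the fragment. Above 1024 combinations a
divide-and-conquer splits the run at the midpoint residue boundary,
MIQP-fits the segments, recombines the segment survivors and re-fits.

## Label assignment and finalization

Conformer labels are optimized by downhill Monte Carlo on a 12-6
Lennard-Jones score (minimum −ε at the vdW radius sum; ε = 1, cutoff 6 Å;
heavy atoms only; pairs within 3 covalent bonds excluded; blank-altloc
atoms interact with every conformer exactly once; intra-residue pairs are
label-invariant and omitted). 10,000 proposed swaps per trial, 10 trials,
best kept. Because acceptance is strictly downhill, a trial stops early
once an exhaustive check over all distinct swaps confirms a local optimum
— the outcome is identical to exhausting the remaining steps. Finally,
conformers within 0.15 Å all-atom RMSD merge (transitive closure, so the
result is conformer-order independent; occupancies summed, representative
= highest occupancy with a coordinate tie-break) and per-residue
occupancies rescale to exactly 1.

## Synthetic benchmark

The generator emulates the synthetic validation protocol: anisotropic B
converted to isotropic; B inflated by 10 Å² per Å of resolution lost
relative to the 0.9 Å original; model in a comfortably enclosing P1 box
(grid spacing d/4); density band-limited at 1/d; zero-mean complex Gaussian
noise added per structure factor with σ = 0.10 × the mean amplitude over
retained non-DC frequencies (a per-reflection proportional mode is also
available behind a flag; the normalization of "10% noise in complex space"
is not published, and mean-amplitude scaling is the simplest reading).
Optional flat-mask bulk solvent (k_sol = 0.4, b_sol = 45 Å², blurred in
reciprocal space) is off by default because the fragment-scale box has no
real solvent region.

Fragment-scale cases graft each flip centroid as conformer "B" of the
peptide between residues 6 and 7 of an idealized 11-residue poly-alanine
host with glycine at the flip's second position (matching the observed
glycine enrichment) and loop dihedrals φ/ψ = (−80°, 130°), which sit
outside the helix/strand suppression windows. Occupancies are 70/30 for
"tweaked down" and 50/50 for the other three clusters; base B-factor 10 Å².
The sweep covers 4 clusters × 12 resolutions (0.9–2.0 Å in 0.1 Å steps) =
48 cases; the pipeline starts from the "A" conformer only and a case counts
as recovered if the fitted model contains a detected flip at that peptide
for *any* of the three sampling amplitudes. Reported false-positive rates
come in two weightings (per peptide and per case) because the aggregation
weighting is a free choice.

What the host does **not** emulate: crystal packing and solvent, sidechain
heterogeneity beyond Ala/Gly (so the benchmark's rotamer false-positive
channel is exercised only by the unit tests, not the sweep), experimental
phase error, and resolution-dependent completeness. Passing the sweep shows
the sampling/selection machinery recovers planted backbone heterogeneity
under calibrated noise — not that real crystallographic maps at these
resolutions behave this way.

## Determinism and problem sizes

Every stochastic stage (map noise, displacement jitter, Monte-Carlo
relabeling, k-means restarts) draws from generators seeded from a single
run seed; per-residue sub-seeds are derived arithmetically from the residue
number, so results are independent of worker count and run-to-run
identical. Default problem sizes — 11-residue hosts, one noise realization
per sweep case, 100 random MIQP oracle instances, 10 noise seeds for
occupancy recovery — are the package's test-scale defaults; all are
parameters.

## Known limitations

* Output peptide geometry after fragment synchronization can be mildly
  distorted (bonds within 10%); a downstream refinement engine is expected
  to regularize it, and none is bundled.
* Multiconformer *input* residues are collapsed to their highest-occupancy
  conformer before fitting (logged); the method starts from single-conformer
  models by design.
* Flip realization is dihedral-only, so the achieved geometry approximates
  the centroid (typically 0.2–0.7 Å rms); the flanking-Cα translations of
  the "tweaked down" class are at the edge of what the 4-dimensional
  nullspace can reach.
* The k-means module clusters whatever mined observations it is given; the
  shipped centroid file is a synthetic reconstruction satisfying the
  documented geometric properties of the mined clusters, not the original
  mined coordinates.
* Space groups other than P1, mmCIF input, hydrogens, and reciprocal-space
  refinement are out of scope; ligands and waters are carried as rigid
  background and never resampled.
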