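# Methods

This note documents the models, conventions and numerical choices behind
fieldqsar, and what the synthetic validation does and does not establish.

## Activity scale and splitting

Activities enter as IC50 in µM and are modelled as
pIC50 = log₁₀(10⁶/IC50), so 1 µM ↦ 6.0 and potency increases with the
value. The train/test split stratifies by activity: compounds sorted by
pIC50 (ties broken by id for reproducibility) are cut into
`round(n · test_fraction)` consecutive groups — when n is not divisible,
the lowest-activity groups take the extra member — and one compound per
group is drawn uniformly (seeded) into the test set. This guarantees the
test set touches both ends of the activity range; any seed satisfies the
size contract. Enantiomer annotations are carried through but never
enumerated; records are used as supplied.

## Alignment

Template alignment is rigid-only: the atoms matched by a SMARTS pattern are
superposed onto the reference compound's matched atoms by Kabsch
least-squares (proper rotations only; collinear templates are rejected as
under-determined). For symmetric templates with several automorphic
matches, the mapping minimizing the fitted RMSD is kept, which makes the
choice deterministic. The default reference is the most potent compound
containing the template. Docking alignment passes externally supplied
poses through untouched — the package consumes poses, it does not dock.
Compounds without the template are reported as excluded, never silently
dropped, so modeled + excluded always partitions the input.

## Fields

The lattice uses 1 Å spacing, extends 3 Å beyond the union bounding box of
the *training* compounds only, and masks points closer than 2 Å to any
training atom (strictly closer: a point at exactly the exclusion radius is
kept). Test compounds are evaluated on the training lattice even where
they protrude — the lattice definition never sees test data.

Per included point and compound, five fields:

* **S** — Lennard-Jones 12-6 energy of an sp3-carbon probe
  (ε 0.066 kcal/mol, σ 3.5 Å) against an element-wise parameter table
  (H, C, N, O, F, S, Cl; editable CSV in package data) with
  Lorentz–Berthelot combining. Truncated from above at +30 kcal/mol after
  summation; the attractive well is never clipped.
* **E** — Coulomb energy of a +1 e probe over partial charges
  (332.0636 q/r kcal·Å/(mol·e²), dielectric 1), truncated to ±30 kcal/mol.
  Charges are Gasteiger by default with a per-atom CSV override; the
  original study used a proprietary force field's charges, which are not
  reproducible here, so absolute electrostatic values differ from it by
  construction.
* **H** — Gaussian similarity field Σᵢ aᵢ·exp(−α r²) over the
  Ghose–Crippen per-atom hydrophobicity contributions (RDKit's Crippen
  table); atoms without a parameter contribute 0 with a warning.
* **A/D** — Gaussian fields over H-bond acceptor/donor feature points
  (RDKit BaseFeatures), each *projected* 1 Å beyond the heavy atom along
  the idealized interaction direction — one point per D–H bond for donors,
  the lone-pair bisector (away from the heavy-atom neighbours' centroid)
  for acceptors — with weight +1. α defaults to 0.3 Å⁻² for all three
  Gaussian fields and is a configuration knob; these fields are bounded by
  construction, so no truncation applies.

**Column pruning and scaling.** Columns whose per-column training sd is
below 0.01 are eliminated. The retained columns of each field are then
divided by one standard deviation computed over all of that field's
training entries (block scaling). This puts the heterogeneous fields on a
common footing while preserving the spatial variance structure *within* a
field. The alternative — dividing every column by its own sd
(`scaling="auto"`) — is provided but not default: autoscaling inflates
remote, low-variance columns (most visibly the slowly-decaying Coulomb
tails) into unit-variance descriptors that act as nearly noise-free copies
of the compound identity, which distorts model selection toward the
electrostatic field regardless of where the signal actually lives. We
observed exactly this pathology on synthetic data, and it is a known
failure mode of autoscaled grid QSAR.

Column order is deterministic: field-major, lattice z-fastest.

## PLS and validation

The regression engine is single-response NIPALS PLS (sequential
covariance-maximizing factors with rank-one deflation), capped at 6
factors as an over-fitting guard. Coefficients are mapped back through the
W(PᵀW)⁻¹q identity; predictions are linear in the (scaled) descriptors.

Statistics per (field set, factor count):

* R² on training; RCV² = 1 − Σ(y−ŷ_LOO)²/Σ(y−ȳ)² from leave-one-out;
* SD = √(Σe²/(n−NC−1)), the conventional standard error of the estimate;
* stability = squared Pearson correlation between LOO and full-model
  training predictions;
* Rtest² = squared Pearson correlation between predicted and observed test
  activities (the predictive-residual variant q²_ext is reported
  alongside, since the correlation convention is the primary one);
* RMSE on test; mean signed/unsigned errors and the fraction of
  |residual| < 0.5 over train + test;
* acceptability ⇔ RCV² > 0.5 and Rtest² > 0.5.

During LOO, column elimination and scaling stay frozen from the full
training set (the customary protocol for grid QSAR, and the cheap one); a
strict mode re-eliminates and re-scales within every fold
(`loo_mode="strict"`). On the synthetic series the two agree to within a
few hundredths of RCV².

Model selection evaluates a list of field combinations, choosing for each
the factor count in 1..6 that maximizes RCV², and ranks reports by
(acceptable, RCV², Rtest², stability, −RMSE) lexicographically. The
default combination list is the five single fields plus the steric +
hydrophobic pair that the synthetic generator plants. Supersets of the
planted pair are deliberately absent from the default list: all five
fields are deterministic functions of the same substituents, so a superset
of the true combination is never less informative and always wins the
ranking, making "the true combination ranks first" ill-posed. Any
combination grid (e.g. the nine-combination grids typical of published
field-QSAR tables) can be passed explicitly.

Field contributions use the stdev·coefficient convention: per column, the
raw-unit coefficient (the fitted coefficient divided by the column's
scaling divisor) times the column's training sd; summed per field and
normalized to 100%.

## Contour maps

The coefficient lattice of a field assigns each retained grid point its
stdev·coeff contribution (eliminated and excluded points are 0).
Thresholding at ±4.0 × 10⁻³ (the conventional display level; the unit is
the model's, so the level is exposed as a knob) yields
favorable/unfavorable point sets. The package exports thresholded point
clouds plus the full scalar lattice in OpenDX; triangulated isosurfaces
are left to visualization programs — point clouds are bit-stable and
testable.

## Interaction geometry

Hydrogen bonds: donor–acceptor heavy-atom distance ≤ 4.0 Å and
D–H···A angle ≥ 120°, both directions across the interface. The distance
cutoff is deliberately generous — published per-residue mean distances for
this kind of pocket run up to ~3.6 ± 0.1 Å — and configurable. Receptor
donor hydrogens are taken explicitly when present, otherwise placed 1 Å
from the donor along the direction away from the centroid of its bonded
heavy atoms.

π-stacking: aromatic ring pairs (5- and 6-membered; receptor rings from
residue atom-name templates, ligand rings from aromaticity perception)
with centroid–centroid distance ≤ 5.5 Å, classified by the angle between
ring plane normals — ≤ 30° parallel (sandwich/parallel-displaced), ≥ 60°
T-shaped, in between reported unclassified with its angle. The 30°/60°
bands are the conventional reading and configurable.

Pose compliance is evaluated against an explicit required-interaction
specification (a list of residue/kind requirements, each optionally with
alternates, e.g. a Thr965 hydroxyl H-bond substituting for Gln1001). The
policy is explicit per run because observed pose sets often retain poses
lacking individual contacts; the package reports per-pose missing and
satisfied requirements rather than hard-coding a policy.

Summaries keep at most one record per pose per (residue, group, kind) —
the shortest distance — and report N, mean, and sample sd (n−1; N = 1 ⇒
sd = 0).

## Synthetic data: what it emulates and what it does not

The series generator emulates a congeneric design: a rigid benzene
scaffold with substituents from a small library (H, F, CH₃, CF₃, OH, NH₂,
CN — H/C/N/O/F elements only) at two para ring positions, placed by fixed
internal coordinates (no conformer search), so all compounds share the
scaffold frame exactly and template alignment is exact by construction.
Coordinates are quantized to the SDF precision (10⁻⁴ Å) so that writing
and re-reading a series is the identity.

Activities are planted as
y = w_S·z(S(compound, r_S)) + w_H·z(H(compound, r_H)), affinely rescaled
to span 3.5–9.5 log units (the breadth of a realistic inhibitor
collection; configurable), plus N(0, σ²) noise with σ = 0.3 by default.
r_S sits 6.4 Å from the ring centre along the first substituent direction
(inside the Lennard-Jones dynamic range of the library, clear of the
truncation), r_H 3.9 Å along the second. Both probe evaluations are the
package's own field functions, so the planted signal is *exactly linear*
in field values — by design, since the aim is to verify that the pipeline
recovers a known field-linear signal, not to simulate real binding.

Defaults (n = 60, σ = 0.3, 7-group library on 2 sites) were chosen so that
the planted signal is identifiable: under them the planted pair passes the
acceptability bar and ranks first across seeds, and in the noiseless limit
its LOO Q² exceeds 0.99. Two caveats define what passing these tests
means. First, the validation is self-referential: descriptors and planted
signal share one implementation, so recovery demonstrates internal
consistency of alignment → grid → scaling → PLS → selection, not
predictive validity on laboratory data. Second, real series have flexible
scaffolds, correlated substituent effects, activity cliffs and measurement
error structure that the generator does not emulate; headline statistics
from published compound sets (which additionally depend on proprietary
charges and docked conformations) are not reproducible from this package's
inputs and are not claimed.

The complex generator places pseudo-residues (His961, Gln1001 amide,
Thr965 hydroxyl, Asn843 amide, Phe972 and Phe1004 rings — named after the
pocket they imitate) at fixed, mutually distant positions and constructs
minimal ligand fragments (formaldehyde acceptors, methylamine donors,
benzene rings) realizing each planted interaction at its target distance
exactly (within the 10⁻⁴ Å coordinate quantum); planted-absent contacts
are placed beyond the cutoff. Fragment chemistry is deliberately minimal —
geometry, not realism, is the point — and files are labelled synthetic.

## Numerical choices and degenerate inputs

* Distances are floored at 10⁻⁶ Å before energy evaluation; truncation
  then bounds the result.
* PLS factor extraction stops early when the residual weight or score norm
  falls below 10⁻¹²; requested factor counts above the usable rank are
  reduced with a warning; constant responses are an error.
* A descriptor matrix whose columns are all eliminated (no variance) is
  returned empty with a warning rather than an error.
* All-zero coefficient vectors yield uniform field contributions with a
  warning.
* Test sets smaller than 3 flag their statistics unreliable instead of
  raising.
* The pipeline is a pure function of (inputs, config, seed) up to timings:
  reports are byte-identical across reruns; the run log carries seed,
  config hash and stage timings separately.

Problem sizes used by the shipped validation: series of 15–60 compounds,
grids of roughly 1–3 thousand included points, 20-seed replicate studies —
sizes at which every stage's behaviour is exercised and the full suite
runs in well under a minute of compute per study.
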