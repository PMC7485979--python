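# Methods

## Scope and model of the problem

The package operates downstream of docking: its inputs are an ensemble of
rigid-body docking models of a binder–target complex (PDB coordinates), and
its experimental signal is a table of dissociation constants for designed
target variants. It assumes the binder and the target are individually
rigid enough that (a) a near-native pose is present in the ensemble and
(b) residue-level contact geometry of a model is meaningful without
re-minimization. Those assumptions hold well for leucine-rich-repeat
scaffolds and antibody-like binders; for targets with large binding-induced
conformational changes the contact sets, and hence everything built on
them, degrade.

Docking itself, full-atom force-field minimization, side-chain repacking
ΔΔG prediction and homology/loop modeling are deliberately outside the
package. Where a pipeline stage conventionally uses their outputs, the
package accepts them as tables (per-model energies as TSV `model_id,
energy`; per-mutation ΔΔG as TSV `chain, number, icode, wt, sub, ddg`) and
otherwise falls back on documented coarse surrogates authored here (below).

## Coordinates and superposition

Structures are chains → residues → heavy atoms, keyed by author residue
number plus insertion code exactly as deposited — positions like an
antibody Fc's H310 are meaningful only in author numbering, so nothing is
renumbered. Hydrogens are dropped on read; alternate locations collapse to
the highest-occupancy conformer (alphabetical altloc on ties); multi-model
files default to the first model. HETATM records are excluded from
residue-level analyses unless requested.

Rigid superposition is the least-squares Kabsch solution with the
determinant correction that excludes reflections (delegated to
`scipy.spatial.transform.Rotation.align_vectors`); degenerate (collinear or
< 3 point) inputs are rejected because the rotation is underdetermined.
Cα RMSD pairs residues by identical author keys, or by global sequence
alignment of chain sequences for cross-entry comparisons of the same
protein; all common residues are used (no subrange), with unpaired
residues excluded but counted.

## Contacts, epitopes, symmetry

Two residues across the binder/target partition are in contact when their
minimum heavy-atom distance is strictly below the cutoff (default 5.0 Å,
the native-contact convention in community docking assessment; the strict
inequality makes boundary cases deterministic). A model's epitope is the
target-side projection of its contact set. For homodimeric targets a
`SymmetryMap` declares protomer chains equivalent; a position is
"contacted" when any symmetry copy is in the epitope, because a
single-binder complex engages one protomer while mutations are necessarily
introduced on both.

## Variant-panel design

Epitope residues from all models are clustered into patches by
single-linkage on Cβ–Cβ distance (Cα for glycine), radius 8.0 Å — about
two side-chain lengths, so one multi-point variant stays local. Candidate
variants are all ≤ *k*-subsets of a patch (*k* = 3 by default: enough
signal to disrupt binding, small enough to leave fold stability mostly
untouched); candidates with identical model coverage collapse to the one
with the highest summed disruption score. A variant covers a model when at
least one mutated position lies in the model's epitope ("all positions"
coverage is available by flag). The minimum panel is found exactly by
iterative-deepening branch-and-bound over candidates — instances are tens
of models and tens of candidates, so exactness is cheap — with ties broken
by maximal summed disruption, then lexicographic order, making panels
reproducible. Next-best distinct covering panels are returned as
alternates. Models no candidate can cover are reported, never dropped.
Stability screening is reduced to an optional per-position exclusion list;
patches with more than 15 usable positions are truncated to the 15 most
disruptive before subset enumeration to bound the search.

The builtin disruption proxy for a mutation is (cross-partition heavy-atom
contacts of the position within 5 Å) × (0 if wild type and substitution
share a coarse physicochemical class, else 1): a crude but deterministic
stand-in for repacking-based ΔΔG, used only to order candidates. Imported
ΔΔG tables take precedence verbatim. The default disruptive substitution is
charge reversal for charged residues and lysine otherwise.

## Position calls and filtering

Fold-change = Kd(variant)/Kd(wt). A single-mutant position is *disrupted*
at fold-change ≥ τ and *neutral* at fold-change ≤ τ/slack (slack 1.0 by
default, i.e. no ambiguous band); positions seen only inside multi-mutant
variants stay *untested*, since a disruptive triple mutant does not reveal
which of its positions matters. The default τ = 1.4: calorimetry resolves
~1.5-fold single-mutant losses as meaningful while replicate noise sits
well below 1.3-fold, and a threshold just under the smallest meaningful
change avoids misclassifying a genuine ~1.45–1.5-fold disruption as
neutral. τ is configurable everywhere it appears.

A model is consistent when it contacts (under symmetry) every disrupted
position and no neutral position; untested positions never constrain.
Neutral-contact rejection is strict by default with a flag to relax —
whether "no contact" tolerates weak contact is a judgment call the data
rarely settle. Contradictory calls on one position therefore legitimately
empty the consistent set.

## Interface energy surrogate

The builtin scorer sums, over cross-partition heavy-atom pairs within
10 Å, a Lennard-Jones term 4ε[(σ/r)¹² − (σ/r)⁶] with per-element σ, ε and
Lorentz–Berthelot mixing, plus a screened Coulomb term q·q′/(4r²) — a
distance-dependent dielectric ε(r) = 4r, the standard coarse trick for
omitting solvent — with integer formal charges split over the carboxylate
oxygens of Asp/Glu and the basic nitrogens of Lys/Arg. Energies are in
arbitrary units, deterministic given coordinates, and invariant under
rigid motion; pairs closer than 0.5 Å set a clash flag (distance clamped
to keep the value finite). This is an interface-only surrogate for a
minimized whole-complex force-field total: adequate for ordering rigid
poses of the same complex, not for absolute energetics — imported energy
tables are the faithful path. Ranking is ascending with lexicographic
tie-breaks.

## Quality metrics

f_nat, I-RMSD and interface recovery follow community assessment
conventions, which the source data for such comparisons rarely restate:
contacts at 5 Å, interface residues at 10 Å, I-RMSD over backbone
(N, Cα, C, O) atoms of *reference*-defined interface residues after
superposition on exactly those atoms. Interface recovery is
|predicted ∩ native| / |predicted| on target-side interface residues —
a precision, so a model cannot score well by predicting everything.
Undefined cases (reference without contacts; model with empty interface)
return NaN with a warning rather than a fake number.

## Conservation and design

Conservation classes over an aligned homolog set are computed per column
from the distinct-character count (gaps distinct): one → shared by all,
all-distinct → unique, otherwise shared by a proper subset. Specificity
candidates are binder residues ranked by the number of contacted target
positions that are not shared by all species — the residues gripping
sequence-divergent surface are the levers of cross-species specificity.

Mutation scans use a residue-class contact potential (salt bridges −1,
like charges +1, hydrophobic packing −0.5, etc.); the score of a
substitution is the change in summed potential over the position's
existing contacts, so identity substitutions are exactly 0 and negative
values predict affinity gains. Cys and Pro are excluded by default
(disulfide and backbone-geometry risks). The greedy double design picks
the substitution minimizing the aggregate across targets at site 1, fixes
it, and re-scans site 2 with stage-1 scores added; with the additive
per-site scorer and sum aggregation this equals the exhaustive pair
optimum, while worst-case (max-over-targets) aggregation — the default —
encodes "must bind every target". Loop/segment replacements are recorded
at sequence level only (start key, removed and inserted sequences
verbatim); structural remodeling of a truncated loop is out of scope.

## Synthetic fixtures

Toy complexes are compact five-atom pseudo-residues (N, Cα, C, O, Cβ
within 1.2 Å of the residue centre) on 8 Å-spaced lines: planted contact
pairs sit at 4 Å centre gap (heavy atoms well under the 5 Å cutoff),
everything else ≥ 8 Å apart (heavy atoms above it), with ±0.03 Å seeded
jitter so determinism is tested without threatening the margins. The
generator verifies the realized contact set equals the planted list and
raises otherwise. Decoys are rigid-body binder perturbations labelled with
oracle-computed metrics; the homodimer fixture relates two protomer chains
by an exact 180° rotation. Simulated assays draw
Kd = wt_Kd × effect^(epitope hits) × lognormal noise — multiplicative,
matching how calorimetric fold-changes behave — with single-mutant entries
for every panel position. These fixtures have idealized geometry, uniform
composition and no experimental artifacts (aggregation, partial unfolding,
titration-fit error beyond lognormal noise); passing tests demonstrate
algorithmic correctness on clean ground truth, not robustness to every
failure mode of real assay or docking data.

## The recovery experiment

`planted_native_recovery` runs 100 seeded trials on a 12-decoy ensemble
(identity, ±1–3-residue epitope slides, separations, flips). Decoy scores
are true I-RMSD plus Gaussian noise with σ = 0.5 × the ensemble's I-RMSD
range — an intentionally unreliable energy. Per trial, a panel is designed
once, an assay simulated (3-fold effect per epitope hit, 0.1 log-fold
noise), positions called, models filtered, and the lowest-scoring model
selected with and without the filter. Problem sizes (12 decoys, 12-residue
target, 100 trials) keep the experiment in the seconds range while leaving
the contrast unambiguous: the filter typically leaves only the native-
epitope pose, so filtered selection is near-perfect while unfiltered
selection tracks the noise.

## Known limitations

- The surrogate energy and contact potential are ordering heuristics;
  absolute values carry no physical units.
- Consistency filtering inherits the contact cutoff: an epitope position
  at 5.2 Å from a model genuinely contacting it will refute that model.
  The cutoff is configurable per call.
- Cross-entry Cα RMSD pairs chains by id when the id sets match, else by
  order; structures with permuted, unequal chain sets need manual chain
  selection first.
- No mmCIF input, crystallographic symmetry expansion, or structure
  repair; models are consumed as given.
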