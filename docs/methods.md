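# Methods

## Scope and shape

`graphpka` predicts microscopic pKa values of small organic acids and bases
from 2D structure. It deliberately excludes 3D geometry, conformers,
tautomer enumeration and stereochemistry: pKa is modeled as a function of
the bonded environment of the ionization center, which is where inductive
and resonance effects live. The package is organized as scikit-learn
estimators (`GraphAttentionPkaRegressor`, `FingerprintPkaRegressor`) so the
models compose with sklearn pipelines and model selection; the module-level
functions (`train`, `forward`, `evaluate`, `grid_search`, `train_baseline`)
are thin wrappers over them.

## The paired-graph representation

An acid/base pair shares one heavy-atom skeleton and differs by one proton.
Both forms are featurized and concatenated per atom and per bond, because
the *change* between forms carries the signal: a carboxylate gains
resonance stabilization its neutral acid lacks, and a model seeing only one
form cannot represent that. The ionization center is always atom index 0,
and hydrogens are implicit (a per-atom H count feature), which keeps the
two skeletons identical.

Atom features per form, with normalization fixed over the shipped element
registry (H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I) rather than refit per
dataset, so featurization of an unseen molecule never depends on the
training corpus:

| feature | scale | normalization |
| --- | --- | --- |
| electronegativity | Pauling | min–max over registry → [0, 1] |
| hardness | Pearson absolute hardness, eV | min–max over registry |
| atomic diameter | 2 × single-bond covalent radius, Å | min–max over registry |
| formal charge | elementary charge | raw integer |
| hybridization | {sp, sp2, sp3, other} | one-hot |
| ring size | smallest SSSR ring, capped at 8 (0 = acyclic) | /8 |
| hydrogen count | total H, capped at 4 | /4 |
| element one-hot | registry heavy elements | optional, off by default |

An element outside the registry raises an error — silent zero vectors would
poison training invisibly. Multi-fragment inputs (salts) keep the largest
organic fragment with a logged warning, since a pKa refers to one species.

Bond features per form: bond-order one-hot (single / aromatic / double /
triple), a two-bit conjugation block (*conjugated*, *enhanced resonance*)
and directed polarization. Full mode concatenates both forms (14 per edge);
*focused* mode treats bond order as equivalent between forms and keeps only
the acid's block (10); `acid_only` / `base_only` emit a single 7-wide block.

### Revised conjugation

Standard toolkit conjugation perception marks a carboxylic acid and its
carboxylate as equally conjugated, erasing the resonance asymmetry that
makes the acid acidic. The package's assignment works in three steps:

1. the plain *conjugated* flag follows standard alternating-π perception
   (RDKit's), which is adequate for neutral systems;
2. a single bond from a π-system atom to a negatively charged lone-pair
   donor (N, O, S, Se) gets the *enhanced resonance* flag — the lone pair
   delocalizes into the π system (phenolate, thiolate on arene, …);
3. when one atom carries both a double bond and a single bond to a
   negatively charged partner of the same element (carboxylate, sulfonate,
   nitro; or the cationic mirror image, amidinium/guanidinium), those bonds
   form a **resonance-equivalent group**: all are flagged conjugated +
   enhanced, their bond order is encoded in the delocalized (aromatic)
   slot, and their polarization is oriented away from the shared π-center
   atom.

Step 3's polarization override needs a word: directed polarization is
normally EN(farther) − EN(closer) relative to the ionization center, so the
two C–O bonds of a carboxylate centered on one O would point in opposite
directions and featurize differently — chemically wrong, since the two
bonds are indistinguishable. Orienting the group's bonds away from the
shared atom (the carboxyl carbon) keeps the equivalent bonds identical
while preserving the electron-withdrawing direction. Atom pairs equidistant
from the center (odd-membered rings) get polarization 0: no direction is
defined, and zero is the symmetric choice.

## The masked attention regressor

`L` GATv2-style multi-head attention layers with edge features run over the
**full** graph; the readout sum-pools only atoms with bond distance ≤ `m`
from the center. The mask restricts the readout, not message passing, so an
atom at distance `m` still carries information gathered from `L` bonds
further out: the effective receptive radius is exactly `L + m`, and the
test suite asserts this bitwise (an edit at distance `L + m + 1` cannot
change the prediction). Sum pooling (rather than mean) preserves size
information — hydrogen-count and substituent-count effects are real.
Defaults: 4 heads, hidden width 64, dropout 0.1, `L = 3`, `m = 4`
(radius 7, the distance over which aliphatic inductive effects decay to
noise).

After pooling, two molecule-level scalars — net charge and the center's
formal charge — are appended (two slots, not literal bits: charges exceed
{0, 1}), followed by two fully connected layers to the scalar output.

Training: Adam, L1 loss by default (MAE is the quantity of interest; MSE
available), fixed epoch budget with best-validation checkpointing when a
validation set is supplied, and no early stopping — determinism matters
more than a few saved epochs. Targets are standardized inside `fit`
(de-standardized in `predict`): the output layer then starts on the right
scale and the optimizer does not spend hundreds of steps walking the output
bias to pKa ≈ 10. Mini-batches are composed once from a seeded shuffle and
reused across epochs with reshuffled order; packing the block-diagonal
batch arrays otherwise dominates runtime. A non-finite loss aborts with a
diagnostic rather than training through NaNs. Everything — initialization,
batch composition, dropout — is a pure function of the seed.

The network and its gradients run on a minimal vectorized reverse-mode
autodiff core (`graphpka.nn.autodiff`, float64). Every operation's gradient
is checked against central finite differences in the test suite, including
the segment-softmax composition used by the attention layer. Forward passes
are deterministic elementwise/row-wise computations, which is what makes
the receptive-field contract checkable bitwise rather than to a tolerance.

Model selection follows the package's evaluation protocol: exhaustive grid
search on an explicit validation set (ties keep the first configuration in
grid order), and experiments are repeated over three seeds with the
**median** test MAE reported, since initialization noise on small datasets
is comparable to the effects being measured.

## Ionizable-site rules and the inference protocol

Site detection is a SMARTS table (shipped as editable TSV): acidic —
carboxylic, sulfonic and phosphonic acids, phenols, thiols, imides and
activated amides, sulfonamides, azole N–H, and activated C–H only when
carbon centers are enabled; basic — aliphatic amines, anilines, pyridine-
type ring N, amidines, imines. Two deliberate exclusions mirror how the
groups behave in practice: sp3 alcohols (pKa typically > 14) and terminal
amides are not ionization centers. An atom keeps its first match in table
order; malformed patterns fail at load time, not match time. The
functional-group classes double as the taxonomy for error analysis and for
the transparent `RuleBasedScorer`.

The inference protocol starts from the fully deprotonated state and
repeatedly (a) rescores every remaining site in the *current* state — never
cached, since each protonation changes the others' microscopic pKa — and
(b) protonates the highest-scoring site, recording its value. Exactly one
step per site, values non-increasing, ties broken to the lowest atom index
for determinism. The state at a given pH (default 7.4, physiological)
protonates exactly the sites whose recorded pKa exceeds the pH.

## Synthetic data: what it emulates and what it does not

The generator emulates the distance-attenuated inductive effect in small
acids and bases. Each molecule is a head group (carboxylic acid 4.76,
primary amine 10.6, thiol 10.5, sulfonamide 10.1, para-substituted phenol
10.0 — textbook base values) on a linear carbon chain (lengths 1–7) with up
to two substituents (F −3.0, Cl −2.7, Br −2.5, C≡N −3.6, NO₂ −4.0 as
electron-withdrawing; methyl +0.4 as donating; first-shell shifts in the
spirit of the substituted-acetic-acid series). Ground truth:

    pKa = pKa₀ + Σᵢ Δᵢ · ρ^(dᵢ − 1) + ε,   ε ~ N(0, σ²)

with `d` the bond distance from substituent to ionization center, per-bond
attenuation ρ = 0.4 and σ = 0.1 pKa units by default. Substituent distances
span 1–7 bonds so receptive-field experiments are exercisable. A terminal
methyl is excluded (it would make one molecule a longer chain with two
conflicting ground truths). Enumeration order is seeded, duplicates are
removed on canonical SMILES, and the center is always atom 0 of the emitted
SMILES.

What passing tests on this library shows: the model can recover a planted
additive, geometrically attenuated structure through the graph features,
across a similarity-capped split, down to near the label noise. What it
does **not** show: performance on real measurements — the library has no
resonance-driven shifts beyond the head group, no intramolecular hydrogen
bonds, no tautomers, no conjugated scaffolds beyond phenol, and far less
structural diversity than a curated experimental set. Real-data accuracy
claims require real data.

Problem sizes used by the shipped studies (chosen to keep a laptop-class
run comfortable): parameter recovery trains on 2000 molecules for 60
epochs, three seeds; overfit sanity memorizes 50 molecules; split soundness
scans a 500-molecule library exhaustively.

## Similarity-capped splitting

Molecules are clustered by sphere exclusion on 2048-bit radius-2 circular
fingerprints at the cap (Tanimoto 0.65 by default), then clusters are
merged transitively wherever any cross-cluster pair still exceeds the cap —
sphere exclusion alone does not guarantee inter-cluster dissimilarity, and
the package treats the cap as a hard post-condition, verified by exhaustive
scan in the tests. Whole clusters go to one side; the test side is filled
smallest-cluster-first until the requested fraction is met (±5% tolerance;
an infeasible request names the blocking cluster). Duplicate molecules with
conflicting labels keep the first occurrence and log both values.

Augmentation relabels atom indices (50 randomized isomorphic copies per
molecule by default, center fixed at index 0, labels copied) and is
generated once at dataset build for reproducibility, not per epoch.

## Known limitations

- Microscopic pKa only; no macro-pKa aggregation over microstates.
- No tautomer reconciliation: each input structure is taken at face value.
- The rule table is a curated default, not an exhaustive ionization
  chemistry; symmetric equivalent sites are scored identically and split
  only by the deterministic index tie-break.
- CPU-scale training: the autodiff core is vectorized NumPy, appropriate
  for thousands of small graphs, not millions.
- Checkpoints embed the element-registry version and refuse to load against
  a drifted registry — retrain rather than silently shifting features.
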