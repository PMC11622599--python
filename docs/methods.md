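# Methods

## Model and assumptions

The optimizer treats molecular design as global minimization of a scalar
objective over the space of molecules reachable by BRICS recombination from
a starting pool and a fragment database. Two assumptions follow. First,
chemistry is identified with canonical SMILES: two inputs with the same
canonical form are the same molecule everywhere (deduplication, caching,
bank uniqueness). Second, chemical distance is Tanimoto distance on binary
Morgan fingerprints with frozen parameters (radius 2, 2048 bits, no counts,
no chirality bits). The fingerprint choice is a documented convention, not a
derived quantity; all radii and distance thresholds in the package are only
meaningful relative to it.

## Fragmentation and virtual synthesis

Fragments arise from **single** BRICS bond cleavages only: each fragment has
exactly one attachment point, encoded as an isotope-labelled dummy atom so a
(core, link-type) pair round-trips through SMILES text. Fragments of three
or fewer heavy atoms are discarded (strict bound; the dummy is not counted).
Multi-cut fragments are deliberately out of scope — recombination joins
exactly two one-point fragments, and a fragment database built elsewhere is
accepted as input.

Joining forms the single bond between the two attachment atoms (double bond
for the alkene–alkene pair, which is the one BRICS join that restores a
C=C), removes the dummies, and re-sanitizes. Incompatible pairs and valence
failures return a failure value rather than raising, since failed joins are
routine events inside a sampling loop. One known and accepted loss: cleaving
a stereo-defined alkene cannot preserve E/Z configuration in one-point
fragments, so cleave-then-join reconstructs the stereo-stripped parent for
those bonds and the exact parent for every other bond.

Fragment sampling weight is the mean over the fragment's set fingerprint
bits of `log(count + pseudocount)` (natural log, pseudocount 1, clamped at
zero). This is the simplest reading of "probability proportional to average
log frequency" that yields one scalar per fragment; with an empty table all
weights coincide and sampling is uniform, so the weighting is strictly
optional. Seed and partner fragments are sampled independently; compatible
pairs are not enumerated exhaustively.

## Annealing loop

A **cycle** is one batch: up to six seeds drawn uniformly from bank entries
not yet used as seeds, trials generated and applied sequentially (the bank
may shift mid-batch), and the niching radius updated once. Seed flags reset
only when every entry has seeded, so a full pass over a 60-molecule bank
spans ten cycles and a default 50-cycle run makes five passes. The reading
"cycle = full pass, 50 passes" was considered and rejected: it performs an
order of magnitude more synthesis and evaluation than the method's reported
operating scale of a few thousand unique evaluations per run.

"Up to 60 chemicals per partner source" is implemented as a budget of 60
sampled join attempts whose failures and duplicates are lost, with unique
products capped at the same number (`RunConfig.attempt_factor` scales the
attempt budget for users who want saturated 60-product batches). Partner
molecules are drawn from the **initial** bank throughout the run, not the
evolving bank; the evolving bank contributes through the seeds.

The update rule is classic niching: a trial within `R_cut` of its nearest
bank member competes only with that member; a trial outside every niche
competes with the worst member. Replace-worst requires the trial to beat the
worst value — the rule's "otherwise discarded" covers that case — so the
multiset of bank values is monotone non-increasing one replacement at a
time. Tie-breaks are deterministic everywhere: nearest-entry ties resolve
toward the better value then lexicographic SMILES, worst-entry ties toward
lexicographically larger SMILES, and initialization sorts by (value,
SMILES). A replacement entry inherits the replaced entry's used-as-seed
flag, keeping the seed schedule's length fixed within a pass.

Objective values are cached by canonical SMILES and the evaluation counter
counts unique molecules, making the counter comparable with the cost an
expensive scorer would actually pay. Objectives are minimized; QED and
similarity are negated/complemented at registration.

## Shape overlap

The sphere-overlap score uses exact two-sphere lens volumes on radii scaled
to 0.7× Bondi van der Waals radii. Self-overlap sums run over all ordered
pairs including the diagonal, read literally from the double sums in the
definition; ordered-versus-unordered is immaterial to the ratio as long as
it is applied consistently, which it is. Flexible alignment is out of
scope: scoring assumes a common frame, and a Kabsch helper performs rigid
superposition of matched atom indices for tests and tooling. Only atoms
present in the molecular graph get spheres; conformers stripped of
hydrogens are scored on heavy atoms.

## Diversity metrics

#Circles is the maximum number of molecules whose pairwise distances all
exceed the threshold (default 0.7) — a maximum independent set on the
conflict graph. The exact branch-and-bound solver is refused above 25
molecules; larger sets use deterministic farthest-point packing, which is a
valid lower bound (any packing is). Distance statistics use the population
standard deviation so that two-molecule inputs are well-defined.

Library curation is leader clustering in input order at similarity 0.7:
order-dependent but deterministic, and the CLI freezes input order by
sorting on canonical SMILES first.

## Synthetic fixtures

The bundled fixture list holds 300 drug-like molecules: ~130 well-known
small-molecule drugs plus BRICS-recombination products of their own
fragments, filtered to molecular weight 200–550 and QED ≥ 0.45. It stands
in for a curated screening library so every workflow runs without
downloads. It reproduces the *mechanics* of a real campaign — fragmentable
drug-like chemistry, realistic link-type usage, pool redundancy — but not
the scale or bias of real collections: the fragment database derived from
it (default fixture: 200 fragments, sampled 100 per batch) is ~1000× smaller
than a commercial fragment collection, so absolute diversity numbers and
unique-evaluation counts from fixture runs characterize the implementation,
not any external library. Default run sizes (pool 100, bank 60, 50 cycles,
~10⁴ unique evaluations, ~15 s) were chosen so a complete optimization is a
routine desk experiment.

Conformer fixtures are small rigid molecules embedded with a fixed ETKDG
seed and MMFF-relaxed — sufficient for exercising shape scoring, not a
conformational ensemble.

## Numerical choices and degenerate inputs

Tanimoto distance between two empty fingerprints is defined as 0 for equal
SMILES and 1 otherwise (logged). Trial generation from an unfragmentable
seed, or against an empty partner pool, yields an empty batch rather than an
error. A constant objective degenerates the search into pure
diversity-driven replacement and still terminates, because cycle counts, not
convergence, bound the run. The lens-volume formula switches to the closed
forms for disjoint and contained spheres at the exact geometric boundaries;
the score ratio is clipped to [0, 1] against floating-point noise only.

## Known limitations

- Single-cut fragmentation only; molecules whose interesting substructures
  require ring cutting or multi-point recombination are out of reach.
- No tautomer or stereoisomer enumeration; E/Z information is lost across
  alkene cleavage.
- The fragment-frequency weighting accepts any user table but ships no
  corpus-scale counts; the built-in counter is intended for small corpora.
- Shape scoring does not align: scores on un-aligned conformers are valid
  numbers but chemically meaningless.
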