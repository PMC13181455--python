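# Methods

## Problem and model

A heterobifunctional degrader is modelled as three moieties joined by two
single bonds: a warhead (protein-of-interest ligand), a linker, and an E3
ligase ligand. Decomposition is cast as exact graph partitioning against
reference libraries: a solution is a partition of the parent's heavy atoms
into three connected pieces such that the two terminal pieces are
canonical-SMILES-equal to library members and the partition conserves both
the heavy-atom count and the SSSR ring count of the parent. Conservation is
the core validity notion — the tool never reports a decomposition whose
fragments do not account for the entire molecule.

## Identity and standardization

Canonical SMILES (RDKit) is the identity relation for every comparison:
library deduplication, the bidirectional consistency check, and solution
deduplication. All inputs pass through one standardization step — largest
covalent component, optional stereo stripping, canonicalization — so parents,
library entries and extracted fragments live in the same representation.
Stereochemistry is ignored by default (`stereo="ignore"`): reference
libraries are commonly drawn without stereo annotations, and 2-D substructure
matching is the intended semantics; `strict` mode preserves stereo and
matches with chirality for users whose libraries encode it.

Ring counting uses RDKit's `CalcNumRings` (symmetrized SSSR) everywhere —
one convention, applied to parents, library fragments and linkers alike, so
the conservation arithmetic is internally consistent even for bridged
systems where SSSR is not unique.

## The bidirectional pass and why it can disagree

Each directional pass matches the first library against the *parent*,
deletes the matched atoms, and matches the second library against the
*remainder molecule*. Subtraction operates on a kekulized copy (so partially
removed aromatic systems leave well-defined alternating bonds) followed by
re-sanitization (so intact rings are re-perceived as aromatic). Matching the
second fragment against the remainder — rather than against the parent with
a disjointness constraint — is a deliberate choice: when a first-pass match
cuts into a fused ring, the remainder's perception changes, and the two
directions can genuinely produce different candidate sets. That asymmetry is
the mechanism behind the `linker_inconsistent` failure class, which is why
the check exists at all.

Branches whose first subtraction disconnects the remainder are *carried
forward*, not pruned: their candidate linkers end up multi-component and are
rejected by the single-linker filter. This keeps the
`multiple_linker_fragments` failure class observable instead of silently
preventing it.

A match as large as the whole parent is rejected (all three moieties must be
nonempty), and the linker must retain at least one heavy atom — there is no
linker-less pathway.

## Filters, enumeration, ordering

Consistent candidates pass three checks, in order: single connected linker
(≥ 1 heavy atom), heavy-atom conservation, ring conservation. All violations
are recorded, not only the first. Because matched atom sets partition the
parent by construction, heavy-atom conservation can only fail for externally
constructed candidates; ring conservation is the live filter — it rejects
every solution that would cut a ring or rely on a non-induced (extra-bond)
substructure embedding.

All surviving solutions are emitted, deduplicated by the canonical
(warhead, linker, E3) triple, in a stable order: descending warhead size,
then descending E3 size, then lexicographic linker SMILES. Library iteration
is itself deterministic (descending fragment size, ties by canonical
SMILES), embeddings are deduplicated as atom sets and sorted, so two runs on
identical inputs are byte-identical.

## Failure taxonomy

Exactly one category is assigned per unresolved molecule, by earliest-stage
cause: `warhead_not_found` (no warhead-library embedding in either pass),
`e3_not_found` (warhead found, no E3 embedding), `linker_inconsistent` (both
moieties present but the two directions produced no identical triple — this
includes overlapping warhead/E3 claims on the same atoms, where one or both
passes yield no candidate at all), `multiple_linker_fragments` (every
consistent candidate had a disconnected linker), `count_discrepancy` (the
rest: conservation violations, in practice ring cuts through fused systems).
Unparseable input rows receive a separate `input_error` status rather than a
silent skip. The precedence order is a package design choice; the categories
themselves are standard failure modes of library-based decomposition.

## The two-cut enumeration oracle

`oracle.enumerate_two_cut_solutions` is an independent reference
implementation used in tests: it tries every pair of bond deletions that
splits the parent into exactly three connected pieces and keeps assignments
whose terminal pieces equal library members under the same conservation
arithmetic. It shares no code path with the match-and-subtract decomposer
(no substructure matching, no directional passes). A conservation-valid
decomposition must cut exactly two bridge bonds — cutting a ring bond
changes the ring count, and any extra attachment bond would create a
spanning cycle — so the oracle's solution space is exactly the decomposer's,
and the two are asserted equal on seeded corpora of parents ≤ 30 heavy
atoms. Quadratic bond-pair enumeration keeps the oracle practical only at
that scale, which is why it is the reference and not the implementation.

## Descriptors

Six descriptors summarize a linker: average molecular weight (Da, implicit
hydrogens included; the average — not monoisotopic — convention is used),
carbon count nC, TPSA (Å², standard contribution scheme), HBD/HBA (RDKit's
`CalcNumHBD`/`CalcNumHBA` N/O-based definitions — donor/acceptor conventions
differ between toolkits, so this choice is pinned here and used throughout;
group comparisons are internally consistent under any fixed choice), and the
Kier molecular flexibility index Φ = ¹κα·²κα / A computed from RDKit's
alpha-modified kappa shape indices. Φ is pinned by a closed form: on an
unbranched sp³ alkane of A atoms the formula collapses to Φ = A − 1
(α = 0), asserted for A = 3…10; hand evaluation for n-butane gives
¹κ = 4·9/9 = 4, ²κ = 3·4/4 = 3, Φ = 12/4 = 3. Fragments with fewer than
three heavy atoms have no second-order path; Φ = 0 is returned by
convention. `profile_set` emits one row per molecule plus per-label group
means; efficacy labels (e.g. poor/moderate/strong degradation classes) are
opaque user-supplied strings — the package computes structure, not potency.

## Synthetic study conditions

The generator assembles degraders from pools of small drug-like fragments —
indole/quinazoline/sulfonamide warhead stand-ins, thalidomide-type
glutarimide and VHL-like amide E3 ligands, alkyl/PEG/amide/piperazine
linkers — by forming two single bonds at hydrogen-bearing attachment atoms,
so the ground-truth triple and both conservation identities hold by
construction. Default problem sizes: a 200-molecule round-trip corpus
(decomposed against per-molecule truth libraries, requiring 100% recovery),
a 50-parent oracle-equivalence corpus built from smaller pools so every
parent stays ≤ 30 heavy atoms, and a 25-member linker-variation series
sharing one warhead and one thalidomide-type E3 ligand with 25 distinct
linkers — the shape of a lead-optimization campaign in which only the linker
changes. These sizes make the full suite run in seconds while covering fused
rings, heteroaromatics, N-attachments and flexible chains.

What the generator does *not* emulate: real degraders with overlapping or
nested library chemotypes (hundreds of warheads, many sharing cores),
stereocenter-rich VHL ligands, salts and charged species, and tautomeric
ambiguity. Passing the round-trip and oracle tests therefore demonstrates
correctness of the algorithm and its filters, not field performance on a
public degrader database — on heterogeneous collections the success rate is
governed by library completeness, and unresolved molecules land in the
failure taxonomy by design.

The adversarial fixtures are hand-built molecule/library pairings, one per
failure category: a missing-warhead and a missing-E3 case; an
overlapping-claims case (2-ethylpyridine and N-ethylpiperidine libraries
over a pyridine–C3–piperidine parent — both moieties match, but they claim
the same methylene, so neither direction completes a consistent triple); a
mid-chain warhead whose subtraction disconnects the linker; a benzene
matched into a quinoline fusion (the consistent triple loses one SSSR ring);
and a two-warhead library shifting the boundary by one methylene, which
yields exactly two valid solutions.

## Numerical and degenerate-input choices

Library loading skips unparseable rows with a warning (an all-unparseable
file is an error), collapses duplicates to the first occurrence, and assigns
missing ids after sorting so shuffled input yields an identical library.
Fragments under 3 heavy atoms are flagged by validation and excluded from
batch runs by default (`min_fragment_heavy_atoms`), because tiny fragments
generate degenerate matches; the loader itself keeps them so the diagnostic
is observable. Subtraction branches whose remainder cannot be re-sanitized
are dropped from that pass (they cannot yield a conservation-valid solution).
Batch outputs are written in input order with fixed schemas; re-runs are
byte-identical.

## Known limitations

* Accuracy is bounded by library completeness; novel warheads or E3 binders
  land in `warhead_not_found`/`e3_not_found` until the libraries grow.
* Matching is substructure-based: a library fragment that is a substructure
  of a larger library fragment produces alternative boundary solutions by
  design; curating overlapping entries out of the library is the recommended
  remedy for high-precision work.
* Linker identity is bare canonical SMILES; attachment positions are tracked
  as atom indices in the solution bookkeeping but do not distinguish linkers
  in the consistency check (two attachment regiochemistries of the same bare
  linker compare equal).
* Only two-cut, single-bond junction topologies are considered valid —
  degraders whose moieties share fused rings are reported as
  `count_discrepancy`, not decomposed.
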