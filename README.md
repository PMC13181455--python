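# protacdec

Rule-based decomposition of heterobifunctional degraders (PROTACs) into
their three constituent moieties — **warhead**, **linker**, and **E3 ligase
ligand** — directly from SMILES, plus the physicochemical descriptor suite
used for linker structure–activity ("linkerology") analysis.

PROTACs recruit a protein of interest (via the warhead) to an E3 ubiquitin
ligase (via the E3 ligand) through a connecting linker, driving ternary
complex formation and proteasomal degradation of the target. Annotating
large degrader collections at the moiety level — which warhead, which E3
binder, which linker — is a prerequisite for warhead replacement, library
mining, and linker optimization, but doing it by hand does not scale and
machine-learned splitters can hallucinate atoms or fail on novel chemotypes.
`protacdec` is deterministic instead: it only reports decompositions whose
fragments account for the *entire* parent molecule.

## The algorithm

Given a degrader *P* and two reference libraries (warheads *W*, E3 ligands
*E*), each entry standardized to a canonical SMILES:

1. **Pass A** — for every substructure embedding of a *w ∈ W* in *P*,
   subtract the matched atoms; match every *e ∈ E* against the remainder;
   the leftover atoms are a candidate linker *l*.
2. **Pass B** — the identical procedure starting from the E3 ligand.
3. **Bidirectional consistency** — a candidate triple (*w*, *l*, *e*) is
   retained only if the identical triple (canonical-SMILES equality of all
   three parts) arises in both directions.
4. **Conservation filters** — the linker must be a single connected fragment
   with ≥ 1 heavy atom, and

   N<sub>heavy</sub>(w) + N<sub>heavy</sub>(l) + N<sub>heavy</sub>(e) = N<sub>heavy</sub>(P),
   N<sub>rings</sub>(w) + N<sub>rings</sub>(l) + N<sub>rings</sub>(e) = N<sub>rings</sub>(P)

   (SSSR ring counts): no atom is invented, lost, or double-counted, and no
   ring is cut.

All valid solutions are reported in a stable order — alternative boundaries
(for example, a terminal amine assigned to the linker versus the ligand) are
real chemical ambiguities, and the choice is left to the user. Molecules
with no valid solution are exported separately with a single failure
category: `warhead_not_found`, `e3_not_found`, `linker_inconsistent`,
`multiple_linker_fragments`, or `count_discrepancy`, so libraries can be
expanded in a targeted way.

For each extracted linker the descriptor suite reports size (average MW),
hydrophobicity (carbon count nC), polarity (TPSA, HBD, HBA), and flexibility
(Kier index Φ = ¹κα·²κα / A, from the alpha-modified kappa shape indices).

## Worked example

With a two-entry warhead library (`wh.smi`: pyridine and 2-methylpyridine)
and a piperidine E3 stand-in (`e3.smi`), the toy degrader
pyridine–propylene–piperidine has two chemically plausible boundaries, and
both are reported:

```console
$ protacdec decompose-one "c1ccc(nc1)CCCN1CCCCC1" -w wh.smi -e e3.smi
2 solution(s) for c1ccc(CCCN2CCCCC2)nc1
  [0] warhead (mepyr): Cc1ccccn1
      linker:  CC
      e3      (pip): C1CCNCC1
  [1] warhead (pyr): c1ccncc1
      linker:  CCC
      e3      (pip): C1CCNCC1
```

The larger warhead claims one methylene of the chain, leaving a two-carbon
linker; the bare pyridine leaves all three. Both solutions conserve the
parent's 15 heavy atoms and 2 rings exactly. Batch workflows use
`protacdec decompose INPUT.csv -w ... -e ... -o solved.csv -u unresolved.csv`;
`protacdec profile` emits the descriptor table, and `protacdec make-fixtures`
writes a synthetic corpus with known ground truth.

As a library:

```python
from protacdec import library_from_smiles, bidirectional_decompose

warheads = library_from_smiles(["c1ccncc1"], "warhead")
e3s = library_from_smiles(["C1CCNCC1"], "e3_ligand")
report = bidirectional_decompose("c1ccc(nc1)CCCN1CCCCC1", warheads, e3s)
report.solutions[0].triple   # ('c1ccncc1', 'CCC', 'C1CCNCC1')
```

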