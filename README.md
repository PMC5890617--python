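# parity

Ranking enzyme structures by how closely their bound ligands resemble the
cognate reactants and products of the reaction they catalyse.

Structural databases are full of enzyme structures whose bound small
molecules are crystallisation additives, fragments or inhibitors rather than
the biological substrate. Anyone assembling datasets for docking, virtual
screening or pharmacophore work wants the structures whose ligands are
*biologically relevant* — similar to the cognate ligands of the catalysed
reaction. `parity` scores that similarity and ranks structures by it.

## The PARITY score

PARITY (Proportion of Atoms Residing in Identical Topology) compares a bound
molecule B and a cognate molecule C by finding the maximum common
substructure on the most permissive basis — any atom may match any atom, any
bond any bond, so only the connectivity constrains the mapping — and then
counting the mapped atom pairs whose element symbols agree. The score is a
Tanimoto-style intersection over union:

    S = I / U = N_sim / (N_B + N_C − N_sim)

where N_B and N_C are the heavy-atom counts and N_sim is the maximum number
of same-element pairs over all connected permissive mappings. A single atom
change in the middle of a molecule therefore lowers the score gently instead
of shattering the common substructure the way an element-matched MCS does.

At the reaction level, cognate compounds on one side of a reaction are
greedily matched to their most similar bound ligands (water, protons and
dihydrogen are excluded as cognates), and the side score is

    S_side = Σ I(C_m, B_m) / Σ U(C_m, B_m)

summed over every cognate slot — unmatched cognates contribute I = 0,
U = N_C, so incomplete matching is penalised; surplus bound ligands are
discarded. The better of the reactant and product side is reported, with the
side recorded. Generic (Markush) cognates are instantiated per pair by
grafting the bound molecule's fragment in place of the R group. The batch
pipeline maps structures to candidate reactions through their (possibly
partial) EC numbers, clusters structures with identical FASTA sequences, and
emits rank-ordered CSVs per structure, cluster, reaction and EC.

## Worked example

2-oxoglutarate (KEGG C00026, the co-substrate of many dioxygenases) versus
N-oxalylglycine (PDB component OGA, the inhibitor usually bound in their
structures) — ten heavy atoms each, identical skeleton, one central C→N
difference:

```python
from parity import parse_smiles, parity_score, strict_mcs_score

bound   = parse_smiles("OC(=O)CNC(=O)C(O)=O", "OGA")
cognate = parse_smiles("OC(=O)CCC(=O)C(O)=O", "C00026")
print(parity_score(bound, cognate).rounded)      # 0.82
print(strict_mcs_score(bound, cognate).rounded)  # 0.33
```

Running `python examples/01_score_pair.py` prints:

```
PARITY:     0.82  (N_B=10, N_C=10, N_sim=9)
strict MCS: 0.33  (N_sim=5)
```

The full 10-atom skeletons superpose; 9 of the 10 mapped pairs agree on
element, giving 9/(10+10−9) = 0.82. The strict MCS keeps only the 5-atom arm
beyond the nitrogen, 5/(10+10−5) = 0.33 — the disproportionate collapse
PARITY is designed to avoid. The other scripts in `examples/` demonstrate
Markush substitution, reaction-level scoring and the batch pipeline, and a
`parity` command-line tool wraps the same operations
(`parity score|reaction|rank|fixtures --help`).

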