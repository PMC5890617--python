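"""Score a structure's bound ligands against a whole reaction.

Emulates a dioxygenase structure holding N-oxalylglycine (OGA),
ethanediol (EDO, a cryoprotectant) and trimethyllysine (M3L) scored
against a reaction with three cognate reactants.  Greedy matching pairs
each cognate with its most similar bound ligand; the side score is
sum(I)/sum(U) over all cognate slots, so unmatched cognates drag the
score down and surplus bound ligands are simply discarded.
"""

from parity import (
    BoundLigandSet, Reaction, parse_smiles, score_reaction, round_half_up,
)
from parity.pipeline import format_cpd_matches

smiles = {
    "C07088": "OC(=O)COc1ccc(Cl)cc1",   # 4-chlorophenoxyacetate
    "C00026": "OC(=O)CCC(=O)C(O)=O",    # 2-oxoglutarate
    "C00007": "O=O",                    # dioxygen
    "CTOY01": "Oc1ccc(Cl)cc1",          # 4-chlorophenol
    "C00042": "OC(=O)CCC(O)=O",         # succinate
    "C00011": "O=C=O",                  # CO2
    "OGA": "OC(=O)CNC(=O)C(O)=O",
    "EDO": "OCCO",
    "M3L": "C[N+](C)(C)CCCCC(N)C(O)=O",
}
mol = {cid: parse_smiles(s, cid) for cid, s in smiles.items()}

reaction = Reaction(
    "R05493",
    reactants=(mol["C07088"], mol["C00026"], mol["C00007"]),
    products=(mol["CTOY01"], mol["C00042"], mol["C00011"]),
)
bound = BoundLigandSet("3AVR-like", (mol["OGA"], mol["EDO"], mol["M3L"]))

res = score_reaction(bound, reaction)
print(f"side={res.side}  combined={round_half_up(res.combined_score):.2f}")
print(f"pairs: {format_cpd_matches(res)}")
# The 2-oxoglutarate/OGA pair contributes its 0.82-score match; the
# combined value is lower because the other cognates match less well.
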