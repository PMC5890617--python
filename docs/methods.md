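# Methods

## The similarity model

PARITY scores two molecules as hydrogen-suppressed labelled graphs. All atom
counts in the package exclude hydrogens: the worked 2-oxoglutarate /
N-oxalylglycine pair only yields denominators of 10+10−N with heavy-atom
counting, and crystallographic data cannot resolve hydrogen positions
anyway. Formal charges are parsed and retained on atoms but do not enter the
score; "atoms of the same type" means same element symbol only, and bond
orders are never compared.

The common substructure is the standard *non-induced*, *connected* common
subgraph: every mapped bond must exist in both molecules, but a bond present
in only one molecule does not block the mapping. Non-induced matching is
what allows a 5-atom path to be the common substructure of a six-ring and a
five-ring; requiring connectivity is what stops the fully permissive
matcher from trivially pairing any equal-sized atom sets. A
`connected=False` flag exists for completeness (it reduces to shared
element-multiset counting) but is off by default.

N_sim is defined as the **maximum number of element-agreeing mapped pairs
over all connected permissive mappings**, not merely over the
maximum-cardinality ones. The two definitions coincide on chemically
sensible pairs (including every worked example), but the all-mappings
definition is the one under which PARITY provably dominates the strict
element-matched MCS score — any strict mapping is itself a feasible
permissive mapping — and under which the score is exactly reproducible by
exhaustive enumeration. `permissive_mcs` separately exposes the full set of
maximum-cardinality mappings (up to an enumeration cap, default 1000, with a
truncation warning).

## Search algorithm

The matcher is a branch-and-bound over atom pairs. A mapping grows from a
root pair — constrained to be the lexicographically smallest pair it
contains, so every mapping is reachable exactly once — and at each step the
search branches on the smallest candidate pair that would extend the common
subgraph while keeping it connected: include it, or exclude it from the
entire subtree. Bounds use the count of still-mappable atoms; with the
agreement objective a branch is cut when even all-agreeing completion cannot
beat the incumbent. The search is exact for the molecule sizes the package
targets; a node budget (default 5×10⁶) and a per-pair wall-clock budget
(default 60 s) return the best-found mapping with a `truncated` flag on
pathological inputs. Ties between equal-objective mappings resolve to the
first found in the deterministic enumeration order, so results are
reproducible run to run.

The test oracle (`brute_force_parity`) answers the same question by a
deliberately different route: undirected enumeration of every connected
mapping with a seen-set for deduplication and only the trivially sound
bound. It refuses molecules above 12 heavy atoms.

## Markush instantiation

Generic cognates carry R-group atoms (MOL symbols `R`, `R#`, `*`, `A` —
over-inclusive on purpose, each hit logged). To score one, the non-R core is
anchored into the bound molecule with an **element-agreeing** common-
substructure match, and for each R atom the bound fragments hanging off the
image of its attachment atom are grafted in place of R. Among equally large
anchor mappings the choice prefers (1) mappings that preserve every mapped
core bond in the bound molecule — a non-faithful anchor can otherwise
recombine core and fragment bonds into topology neither molecule has — and
(2) the mapping grafting the most atoms. A permissive anchor was considered
and rejected: it absorbs exactly the atoms that should be grafted (matching
a phenol O onto a toluene methyl leaves nothing to transplant), whereas the
element-agreeing anchor reproduces the expected R-phenol + toluene →
cresol-like behaviour. An R whose attachment cannot be placed is deleted,
i.e. treated as hydrogen; a cognate that is only an R atom becomes the empty
molecule and scores 0. Substitution happens per (cognate, bound) pair inside
the score matrix, so different bound ligands instantiate R differently.
Unmatched Markush cognates contribute their non-R atom count to ΣU.

## Reaction-level aggregation

Cognates with IDs in the exclusion set (default {C00001, C00080, C00282}:
water, proton, dihydrogen; configurable) are dropped before matching.
Greedy matching always takes the highest-scoring unmatched (cognate, bound)
pair; ties prefer the cognate with more heavy atoms, then the smaller
cognate ID, then the smaller bound ID. Zero-score pairs are never matched:
pairing them would add N_B to ΣU without adding intersection, so leaving
the cognate unmatched (U = N_C) and discarding the bound ligand gives the
larger — best-match — combined score. Duplicate cognates are independent
slots, each needing its own partner. The side with the larger ΣI/ΣU wins;
ties report the reactant side. Scores are carried at full precision and
rounded half-up to 2 decimals only in output; histogram binning rounds to
the nearest 0.05, halves up.

Bound-ligand eligibility is decided by the input bound-ligand lists, not by
the cognate exclusion set: buffer components like ethanediol are legitimate
(if weak) match targets, and the fixtures exercise exactly that.

## Batch pipeline

Structure→chain→EC annotations follow the SIFTS `pdb_chain_enzyme.csv`
layout. A partial EC (dash-suffixed, or truncated) expands to all complete
descendants in the hierarchy implied by the EC→reaction table; a complete EC
maps to itself if known. Candidate reactions are unioned over a structure's
chains (chain-level scoring is not attempted; the output is per structure).
`num_kegg` counts all reactions reachable via EC before usability filtering
— it describes the mapping, not the scoring. Structures whose candidate
reactions all lack cognate structures (e.g. polymer substrates) are excluded
with a logged reason. Sequence clusters group structures whose sorted chain
sequences are byte-identical (SHA-256 digest). Ranking keeps, per structure
/ cluster / reaction / EC, the maximum combined score, ties resolved to the
smallest (structure, reaction) pair. The four-bucket summary is: none bound;
score ≤ 0.3; 0.3 < score < 0.7; score ≥ 0.7. The per-EC and per-reaction
CSVs report the top match plus every other match at or above the 0.70
threshold (configurable); the per-compound CSV lists individual
bound–cognate pairs at or above the threshold. All output is
deterministically sorted, so identical inputs produce byte-identical files.

## The fixture corpus

The generator emulates, at toy scale, the inputs of a structure-to-reaction
ranking study: a component table mixing KEGG compounds and PDB components
(including the proton and dihydrogen entries that have no heavy atoms and
are flagged unusable), six reactions covering an exact-match case, a
Markush case, an excluded-cognate case, a duplicated-cognate case and an
unscorable case, eleven structures covering multi-chain EC union, partial-EC
expansion, a ligand-free structure, an identical-sequence pair and two
excluded structures, and a manifest of hand-derived expected scores with
their derivations. Extra molecules for oracle-equivalence testing are grown
by seeded valence-legal attachment over {C, N, O, S} (4–12 heavy atoms,
occasional double bonds and one optional ring closure), rejected until they
round-trip through SMILES. The corpus is deterministic per seed and
byte-identical across runs.

What the corpus does **not** emulate: real chemical-space diversity, large
ligands (the biggest fixture has 13 heavy atoms), stereochemistry,
tautomers and protonation states, multi-EC annotation conflicts at scale,
or the volume of a full structural-database snapshot. Green tests therefore
demonstrate correctness of the scoring and ranking machinery, not the
field-scale statistics of any particular database release; full-corpus
percentages depend on bulk database snapshots and are out of scope.

## Known limitations

- The MCS search is exponential in the worst case; beyond ~25 heavy atoms
  per molecule the budgets may truncate and the score becomes best-found
  (flagged). This matches the intended use on small metabolites/ligands.
- Greedy matching is not an optimal assignment; like any greedy scheme it
  can be beaten by a global assignment on adversarial score matrices, and
  adding a bound ligand is not formally guaranteed never to lower the
  combined score even though it cannot on the fixture cases.
- No stereochemistry, no 3D information, no protonation handling; aromatic
  and Kekulé forms of the same compound are harmonised by a single
  perception model applied to both input paths.
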