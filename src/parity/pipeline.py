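"""Batch ranking of structures by cognate-ligand similarity.

Structures are linked to candidate reactions through their EC
annotations (SIFTS ``pdb_chain_enzyme.csv`` layout): partial EC numbers
expand to all downstream leaves of the EC hierarchy, each leaf maps to
zero or more reactions, and the candidates for a structure are the union
over its chains.  Every (structure, reaction) pair is scored with the
reaction-level PARITY machinery, structures are clustered by identical
FASTA sequence content, and rank-ordered tables are produced per
structure, per cluster, per reaction and per EC, together with a
four-bucket summary (none bound / <=0.3 / between / >=0.7) and binned
score histograms.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .molecule import ComponentTable, Molecule, load_component_table
from .reaction import (
    DEFAULT_EXCLUDED_COGNATES,
    BoundLigandSet,
    Reaction,
    ReactionMatchResult,
    bin_score,
    score_reaction,
)
from .score import round_half_up

logger = logging.getLogger(__name__)

__all__ = [
    "ECAnnotation",
    "ECTree",
    "SequenceCluster",
    "RankTables",
    "expand_partial_ec",
    "map_structures_to_reactions",
    "cluster_identical_sequences",
    "rank_and_summarize",
    "write_outputs",
    "run_pipeline",
    "load_sifts_annotations",
    "load_ec_reaction_map",
    "load_reactions",
    "load_bound_sets",
    "load_fasta_sequences",
]

_EC_FIELD = re.compile(r"^\d+$")


@dataclass(frozen=True)
class ECAnnotation:
    """One SIFTS row: a chain of a structure carries an EC number."""

    structure_id: str
    chain_id: str
    ec_number: str


@dataclass(frozen=True)
class SequenceCluster:
    """Structures sharing a byte-identical set of chain sequences."""

    cluster_id: str
    members: tuple[str, ...]
    digest: str


def _parse_ec(ec: str) -> list[str]:
    """Validate an EC string; returns its fields padded to 4 with '-'."""
    fields = ec.strip().split(".")
    if not 1 <= len(fields) <= 4:
        raise ValueError(f"malformed EC number {ec!r}")
    fields = fields + ["-"] * (4 - len(fields))
    seen_dash = False
    for k, f in enumerate(fields):
        if f == "-":
            if k == 0:
                raise ValueError(f"malformed EC number {ec!r}: first level missing")
            seen_dash = True
        elif _EC_FIELD.match(f):
            if seen_dash:
                raise ValueError(f"malformed EC number {ec!r}: '-' only allowed as suffix")
        else:
            raise ValueError(f"malformed EC number {ec!r}: bad field {f!r}")
    return fields


class ECTree:
    """EC hierarchy implied by a leaf EC -> reaction-ID mapping."""

    def __init__(self, leaf_to_reactions: Mapping[str, Iterable[str]]):
        self._map: dict[str, frozenset[str]] = {}
        for ec, rids in leaf_to_reactions.items():
            fields = _parse_ec(ec)
            if "-" in fields:
                raise ValueError(f"reactions may attach only to complete ECs, got {ec!r}")
            self._map[".".join(fields)] = frozenset(rids)

    @property
    def leaves(self) -> list[str]:
        return sorted(self._map)

    def reactions_for(self, leaf_ec: str) -> frozenset[str]:
        return self._map.get(leaf_ec, frozenset())

    def __contains__(self, ec: str) -> bool:
        return ec in self._map


def expand_partial_ec(ec: str, tree: ECTree) -> list[str]:
    """Complete EC -> itself; partial EC -> all downstream leaves."""
    fields = _parse_ec(ec)
    if "-" not in fields:
        full = ".".join(fields)
        if full in tree:
            return [full]
        logger.warning("EC %s not present in the hierarchy", ec)
        return []
    prefix = fields[: fields.index("-")]
    matches = [
        leaf for leaf in tree.leaves
        if leaf.split(".")[: len(prefix)] == prefix
    ]
    if not matches:
        logger.warning("partial EC %s has no downstream leaves", ec)
    return matches


def map_structures_to_reactions(
    annotations: Sequence[ECAnnotation],
    tree: ECTree,
    usable_reactions: set[str] | None = None,
) -> tuple[dict[str, set[str]], dict[str, set[str]], dict[str, str]]:
    """Union of candidate reactions per structure over chains and ECs.

    Returns (structure -> reaction IDs, leaf EC -> structures, exclusion
    log).  Structures none of whose candidate reactions are usable
    (``usable_reactions``, when given, is the set with resolvable cognate
    structures) are excluded with a reason, mirroring the removal of
    polymer-substrate enzymes from the original ranking.
    """
    struct_to_rxn: dict[str, set[str]] = {}
    ec_to_struct: dict[str, set[str]] = {}
    excluded: dict[str, str] = {}
    for ann in annotations:
        leaves = expand_partial_ec(ann.ec_number, tree)
        rxns = struct_to_rxn.setdefault(ann.structure_id, set())
        for leaf in leaves:
            rids = tree.reactions_for(leaf)
            if rids:
                ec_to_struct.setdefault(leaf, set()).add(ann.structure_id)
            rxns.update(rids)
    for sid in sorted(struct_to_rxn):
        rxns = struct_to_rxn[sid]
        if not rxns:
            excluded[sid] = "no reaction mapped via EC annotations"
        elif usable_reactions is not None and not (rxns & usable_reactions):
            excluded[sid] = "no mapped reaction has cognate ligand structures"
    for sid in excluded:
        logger.warning("structure %s excluded: %s", sid, excluded[sid])
        struct_to_rxn.pop(sid, None)
    return struct_to_rxn, ec_to_struct, excluded


def cluster_identical_sequences(
    sequences: Mapping[str, Sequence[str]],
) -> list[SequenceCluster]:
    """Group structures whose sorted chain-sequence multisets are identical.

    Chain order is irrelevant; sequences are sorted before hashing.  A
    structure with no sequence becomes its own singleton cluster.
    """
    by_digest: dict[str, list[str]] = {}
    for sid in sorted(sequences):
        seqs = sorted(str(s) for s in sequences[sid])
        if not seqs:
            logger.warning("structure %s has no sequence; singleton cluster", sid)
            digest = "noseq-" + hashlib.sha256(sid.encode()).hexdigest()[:12]
        else:
            digest = hashlib.sha256("\n".join(seqs).encode()).hexdigest()[:12]
        by_digest.setdefault(digest, []).append(sid)
    clusters = []
    for k, digest in enumerate(sorted(by_digest, key=lambda d: by_digest[d][0])):
        clusters.append(
            SequenceCluster(
                cluster_id=f"CL{k + 1:04d}",
                members=tuple(sorted(by_digest[digest])),
                digest=digest,
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# ranking


def format_cpd_matches(result: ReactionMatchResult) -> str:
    """Serialize matched pairs as ``bound;cognate;score`` joined by ``_``."""
    chunks = []
    for pair in result.pairs:
        bound = pair.bound_id if pair.bound_id is not None else "NONE"
        chunks.append(f"{bound};{pair.cognate_id};{round_half_up(pair.result.score):.2f}")
    return "_".join(chunks)


def _bucket(record: Mapping) -> str:
    if record["none_bound"]:
        return "none_bound"
    s = record["combined_score"]
    if s <= 0.3:
        return "sim_le_0.3"
    if s < 0.7:
        return "sim_0.3_to_0.7"
    return "sim_ge_0.7"


_BUCKETS = ("none_bound", "sim_le_0.3", "sim_0.3_to_0.7", "sim_ge_0.7")

_COLUMNS = [
    "key", "structure_id", "reaction_id", "num_kegg",
    "r_or_p", "combined_score", "cpd_matches", "none_bound",
]


@dataclass
class RankTables:
    per_structure: pd.DataFrame
    per_cluster: pd.DataFrame
    per_reaction: pd.DataFrame
    per_ec: pd.DataFrame
    all_records: pd.DataFrame
    ec_records: pd.DataFrame
    summary: dict
    histograms: dict

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, f"per_{name}")


def _best_per_key(df: pd.DataFrame) -> pd.DataFrame:
    """Max combined_score per key; ties to smallest (structure, reaction)."""
    if df.empty:
        return df.iloc[0:0]
    ordered = df.sort_values(
        ["key", "combined_score", "structure_id", "reaction_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ordered.groupby("key", as_index=False).head(1).reset_index(drop=True)


def _summarize(df: pd.DataFrame) -> dict:
    n = len(df)
    counts = {b: 0 for b in _BUCKETS}
    for _, row in df.iterrows():
        counts[_bucket(row)] += 1
    pct = {b: (100.0 * counts[b] / n if n else 0.0) for b in _BUCKETS}
    return {"n": n, "counts": counts, "percent": pct}


def _histogram(df: pd.DataFrame) -> dict[str, int]:
    hist: dict[str, int] = {}
    for s in df.loc[~df["none_bound"], "combined_score"]:
        key = f"{bin_score(float(s)):.2f}"
        hist[key] = hist.get(key, 0) + 1
    return dict(sorted(hist.items()))


def rank_and_summarize(
    results: Mapping[tuple[str, str], ReactionMatchResult],
    num_kegg: Mapping[str, int],
    clusters: Sequence[SequenceCluster],
    ec_to_struct: Mapping[str, set[str]] | None = None,
    tree: ECTree | None = None,
) -> RankTables:
    """Best-match tables per structure / cluster / reaction / EC.

    ``results`` holds one ReactionMatchResult per scored (structure,
    reaction) pair; ``num_kegg`` the candidate-reaction count per
    structure (the union over chains, before scoring).
    """
    rows = []
    for (sid, rid) in sorted(results):
        res = results[(sid, rid)]
        rows.append({
            "key": "",
            "structure_id": sid,
            "reaction_id": rid,
            "num_kegg": int(num_kegg.get(sid, 0)),
            "r_or_p": res.side,
            "combined_score": float(res.combined_score),
            "cpd_matches": format_cpd_matches(res),
            "none_bound": bool(res.none_bound),
        })
    all_records = pd.DataFrame(rows, columns=_COLUMNS)

    per_structure = all_records.assign(key=all_records["structure_id"])
    per_structure = _best_per_key(per_structure)

    member_to_cluster = {
        sid: cl.cluster_id for cl in clusters for sid in cl.members
    }
    per_cluster = all_records.assign(
        key=all_records["structure_id"].map(member_to_cluster)
    ).dropna(subset=["key"])
    per_cluster = _best_per_key(per_cluster)

    per_reaction = all_records.assign(key=all_records["reaction_id"])
    per_reaction = _best_per_key(per_reaction)

    ec_rows = []
    if ec_to_struct and tree is not None:
        for leaf in sorted(ec_to_struct):
            rids = tree.reactions_for(leaf)
            members = ec_to_struct[leaf]
            sub = all_records[
                all_records["structure_id"].isin(members)
                & all_records["reaction_id"].isin(rids)
            ]
            if not sub.empty:
                ec_rows.append(sub.assign(key=leaf))
    ec_records = (
        pd.concat(ec_rows, ignore_index=True) if ec_rows else all_records.iloc[0:0]
    )
    per_ec = _best_per_key(ec_records)

    tables = {
        "structure": per_structure,
        "cluster": per_cluster,
        "reaction": per_reaction,
        "ec": per_ec,
    }
    summary = {name: _summarize(df) for name, df in tables.items()}
    histograms = {name: _histogram(df) for name, df in tables.items()}
    return RankTables(
        per_structure=per_structure,
        per_cluster=per_cluster,
        per_reaction=per_reaction,
        per_ec=per_ec,
        all_records=all_records,
        ec_records=ec_records,
        summary=summary,
        histograms=histograms,
    )


def _report_rows(df_all: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Per key: the top record plus any other record scoring >= threshold."""
    frames = []
    for key, sub in df_all.groupby("key", sort=True):
        sub = sub.sort_values(
            ["combined_score", "structure_id", "reaction_id"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        keep = (sub["combined_score"] >= threshold) | (
            sub.index == sub.index[0]
        )
        frames.append(sub[keep])
    return pd.concat(frames, ignore_index=True) if frames else df_all.iloc[0:0]


def write_outputs(
    tables: RankTables,
    out_dir: str | Path,
    *,
    threshold: float = 0.70,
    exclusions: Mapping[str, str] | None = None,
    component_skips: int = 0,
) -> dict[str, Path]:
    """Write the three deposited-style CSVs plus a JSON run summary.

    ``ec_pdb.csv`` and ``kegg_pdb.csv`` carry, per EC / per reaction, the
    top-ranked structure plus every other match scoring at least
    ``threshold``.  ``keggCpd_pdb.csv`` lists, per cognate compound per
    reaction, every bound-ligand pair scoring at least ``threshold``.
    Output is deterministic: fixed sort keys, 2-decimal scores.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def finalize(df: pd.DataFrame, key_name: str) -> pd.DataFrame:
        if key_name == "KEGG":
            df = df.drop(columns=["key"])
        out = df.rename(columns={
            "key": key_name, "structure_id": "PDB", "reaction_id": "KEGG",
            "num_kegg": "num_KEGG", "combined_score": "score",
        })
        out["score"] = out["score"].map(lambda s: f"{round_half_up(float(s)):.2f}")
        cols = [key_name, "PDB", "KEGG", "num_KEGG", "r_or_p", "score", "cpd_matches"]
        if key_name == "KEGG":
            cols = ["KEGG", "PDB", "num_KEGG", "r_or_p", "score", "cpd_matches"]
        return out[cols]

    all_rec = tables.all_records
    paths: dict[str, Path] = {}

    ec_report = _report_rows(tables.ec_records, threshold)
    ec_path = out_dir / "ec_pdb.csv"
    finalize(ec_report, "EC").to_csv(ec_path, index=False)
    paths["ec"] = ec_path

    kegg_all = all_rec.assign(key=all_rec["reaction_id"])
    kegg_report = _report_rows(kegg_all, threshold)
    kegg_path = out_dir / "kegg_pdb.csv"
    finalize(kegg_report, "KEGG").to_csv(kegg_path, index=False)
    paths["kegg"] = kegg_path

    # per-compound file: every winning-side pair >= threshold
    cpd_rows = []
    for _, row in all_rec.iterrows():
        for chunk in row["cpd_matches"].split("_"):
            if not chunk:
                continue
            bound_id, cognate_id, score_s = chunk.split(";")
            score = float(score_s)
            if bound_id != "NONE" and score >= threshold:
                cpd_rows.append({
                    "KEGG": row["reaction_id"],
                    "compound": cognate_id,
                    "PDB": row["structure_id"],
                    "bound": bound_id,
                    "score": f"{score:.2f}",
                })
    cpd_df = pd.DataFrame(
        cpd_rows, columns=["KEGG", "compound", "PDB", "bound", "score"]
    )
    if not cpd_df.empty:
        cpd_df = cpd_df.sort_values(
            ["KEGG", "compound", "score", "PDB", "bound"],
            ascending=[True, True, False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    cpd_path = out_dir / "keggCpd_pdb.csv"
    cpd_df.to_csv(cpd_path, index=False)
    paths["keggCpd"] = cpd_path

    summary = {
        "buckets": tables.summary,
        "histograms": tables.histograms,
        "excluded_structures": dict(sorted((exclusions or {}).items())),
        "n_excluded_structures": len(exclusions or {}),
        "n_unusable_components": component_skips,
        "threshold": threshold,
    }
    summary_path = out_dir / "run_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    paths["summary"] = summary_path
    return paths


# ---------------------------------------------------------------------------
# input loading


def load_sifts_annotations(path: str | Path) -> list[ECAnnotation]:
    """Read a SIFTS-layout CSV (PDB, CHAIN, ACCESSION, EC_NUMBER)."""
    df = pd.read_csv(path, comment="#", dtype=str).fillna("")
    cols = {c.upper(): c for c in df.columns}
    for required in ("PDB", "CHAIN", "EC_NUMBER"):
        if required not in cols:
            raise ValueError(f"{path}: missing column {required}")
    out = []
    for _, row in df.iterrows():
        ec = str(row[cols["EC_NUMBER"]]).strip()
        if not ec or ec == "?":
            continue
        out.append(ECAnnotation(
            structure_id=str(row[cols["PDB"]]).strip(),
            chain_id=str(row[cols["CHAIN"]]).strip(),
            ec_number=ec,
        ))
    return out


def load_ec_reaction_map(path: str | Path) -> ECTree:
    """Read a two-column CSV (EC_NUMBER, REACTION_ID) into an ECTree."""
    df = pd.read_csv(path, comment="#", dtype=str).fillna("")
    cols = {c.upper(): c for c in df.columns}
    ec_col = cols.get("EC_NUMBER") or df.columns[0]
    rx_col = cols.get("REACTION_ID") or df.columns[1]
    mapping: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        mapping.setdefault(str(row[ec_col]).strip(), set()).add(str(row[rx_col]).strip())
    return ECTree(mapping)


def load_reactions(
    path: str | Path,
    table: ComponentTable,
    excluded: frozenset[str] = DEFAULT_EXCLUDED_COGNATES,
) -> tuple[dict[str, Reaction], set[str]]:
    """Read reactions.csv (reaction_id, reactants, products; sides are
    space-separated compound IDs).  Returns (reactions, usable IDs): a
    reaction is usable when every non-excluded compound resolves to a
    structure in the component table.
    """
    df = pd.read_csv(path, comment="#", dtype=str).fillna("")
    reactions: dict[str, Reaction] = {}
    usable: set[str] = set()
    for _, row in df.iterrows():
        rid = str(row["reaction_id"]).strip()
        sides: dict[str, list[Molecule]] = {}
        ok = True
        for col, label in (("reactants", "r"), ("products", "p")):
            ids = str(row[col]).split()
            mols = []
            for cid in ids:
                mol = table.get(cid)
                if mol is None:
                    if cid not in excluded:
                        ok = False
                    continue
                mols.append(mol)
            sides[label] = mols
        reactions[rid] = Reaction(rid, tuple(sides["r"]), tuple(sides["p"]))
        if ok:
            usable.add(rid)
        else:
            logger.warning("reaction %s: missing cognate structures, not scorable", rid)
    return reactions, usable


def load_bound_sets(path: str | Path, table: ComponentTable) -> dict[str, BoundLigandSet]:
    """Read bound_ligands.csv (structure_id, ligands space-separated)."""
    df = pd.read_csv(path, comment="#", dtype=str).fillna("")
    out: dict[str, BoundLigandSet] = {}
    for _, row in df.iterrows():
        sid = str(row["structure_id"]).strip()
        ligands = []
        for cid in str(row["ligands"]).split():
            mol = table.get(cid)
            if mol is None:
                logger.warning("structure %s: bound ligand %s has no structure", sid, cid)
                continue
            ligands.append(mol)
        out[sid] = BoundLigandSet(sid, tuple(ligands))
    return out


def load_fasta_sequences(path: str | Path) -> dict[str, list[str]]:
    """FASTA headers ``>structure|chain`` grouped per structure."""
    from Bio import SeqIO

    out: dict[str, list[str]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        sid = record.id.split("|")[0]
        out.setdefault(sid, []).append(str(record.seq))
    return out


def run_pipeline(
    *,
    compounds: str | Path,
    reactions: str | Path,
    sifts: str | Path,
    ec2rxn: str | Path,
    fasta: str | Path | None = None,
    bound: str | Path,
    out_dir: str | Path,
    threshold: float = 0.70,
    excluded: frozenset[str] = DEFAULT_EXCLUDED_COGNATES,
) -> RankTables:
    """End-to-end batch run over a corpus directory; writes the CSVs."""
    table = load_component_table(compounds)
    reaction_map, usable = load_reactions(reactions, table, excluded)
    annotations = load_sifts_annotations(sifts)
    tree = load_ec_reaction_map(ec2rxn)
    bound_sets = load_bound_sets(bound, table)
    sequences = load_fasta_sequences(fasta) if fasta else {}

    struct_to_rxn, ec_to_struct, exclusions = map_structures_to_reactions(
        annotations, tree, usable_reactions=usable
    )
    num_kegg = {sid: len(rids) for sid, rids in struct_to_rxn.items()}

    results: dict[tuple[str, str], ReactionMatchResult] = {}
    for sid in sorted(struct_to_rxn):
        bset = bound_sets.get(sid, BoundLigandSet(sid, ()))
        for rid in sorted(struct_to_rxn[sid] & usable):
            results[(sid, rid)] = score_reaction(bset, reaction_map[rid], excluded)

    clusters = cluster_identical_sequences(
        {sid: sequences.get(sid, []) for sid in struct_to_rxn}
    )
    tables = rank_and_summarize(results, num_kegg, clusters, ec_to_struct, tree)
    write_outputs(
        tables, out_dir, threshold=threshold,
        exclusions=exclusions, component_skips=table.n_skipped,
    )
    return tables
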