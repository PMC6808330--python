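"""Consensus of two delimitations and rule-based species assembly.

The distance-based and the tree-based delimitation each yield a partition;
groups confirmed by both ("mutual groups") are the conservative starting
point for species.  Pairs of mutual groups that are sisters on the
phylogeny may then be merged into a single species when the node support is
high enough AND their ranges are adjacent AND their shells are similar —
the latter two judgments are supplied by the user, the module only
mechanizes the conjunction and keeps an audit trail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .exceptions import InputError
from .partition import Partition
from .trees import PhyloTree

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


@dataclass(frozen=True)
class MutualGroupSet:
    """Groups confirmed by both input partitions, with provenance."""

    groups: tuple[frozenset[str], ...]
    provenance: tuple[dict, ...]  # per group: indices of source groups in A and B

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def mutual_groups(pA: Partition, pB: Partition, mode: str = "strict") -> MutualGroupSet:
    """Intersect two partitions into mutual groups.

    ``strict``: a group qualifies only with identical membership in both
    partitions.  ``compat``: additionally, a group of ``pA`` qualifies when
    ``pB`` merely splits it into sub-groups wholly contained in it (the
    provenance records the refinement).
    """
    if mode not in {"strict", "compat"}:
        raise InputError(f"unknown mode {mode!r}")
    if pA.taxa != pB.taxa:
        raise InputError("partitions cover different taxon sets")
    b_lookup = {g: j for j, g in enumerate(pB.groups)}
    groups: list[frozenset[str]] = []
    prov: list[dict] = []
    for i, g in enumerate(pA.groups):
        if g in b_lookup:
            groups.append(g)
            prov.append({"a": [i], "b": [b_lookup[g]], "relation": "identical"})
        elif mode == "compat":
            inside = [j for j, h in enumerate(pB.groups) if h <= g]
            covered = frozenset().union(*(pB.groups[j] for j in inside)) if inside else frozenset()
            if covered == g and len(inside) > 1:
                groups.append(g)
                prov.append({"a": [i], "b": inside, "relation": "b_refines_a"})
    return MutualGroupSet(tuple(groups), tuple(prov))


@dataclass
class MergeEvidence:
    """Evidence row for one candidate pair of mutual groups.

    ``sister_bpp`` is the posterior probability of the node joining the two
    groups on the tree; range adjacency and shell similarity are judgments
    the user supplies (from maps and specimens), not quantities the module
    derives.
    """

    pair: tuple[int, int]  # indices into the MutualGroupSet
    sister_in_tree: bool
    sister_bpp: float | None = None
    ranges_adjacent: bool | None = None
    morphology_similar: bool | None = None


def merge_candidate_pairs(
    groups: MutualGroupSet, tree: PhyloTree
) -> tuple[list[MergeEvidence], list[int]]:
    """Pairs of mutual groups whose MRCAs are sister nodes on the tree.

    Returns the candidate evidence skeletons (with the joining node's
    support attached) and the indices of groups that are not monophyletic
    on the tree (flagged and excluded from candidacy).
    """
    flagged: list[int] = []
    mrcas: dict[int, int] = {}
    for i, g in enumerate(groups.groups):
        node = tree.mrca(g)
        if tree.tipset_below(node) != g:
            flagged.append(i)
        else:
            mrcas[i] = node
    candidates: list[MergeEvidence] = []
    idx = sorted(mrcas)
    for a_pos, i in enumerate(idx):
        for j in idx[a_pos + 1:]:
            pi, pj = tree.parent[mrcas[i]], tree.parent[mrcas[j]]
            if pi == -1 or pi != pj:
                continue
            if len(tree.children[pi]) != 2:
                continue  # part of a polytomy: not a clean sister pair
            candidates.append(
                MergeEvidence(
                    pair=(i, j),
                    sister_in_tree=True,
                    sister_bpp=tree.node_support(pi),
                )
            )
    return candidates, flagged


@dataclass(frozen=True)
class MergeRule:
    """Conjunction rule for merging a sister pair into one species.

    The default minimum node support of 0.83 is the smallest sister support
    accepted for a merge in the motivating snail study.
    """

    min_bpp: float = 0.83


@dataclass(frozen=True)
class AssemblyResult:
    partition: Partition
    audit: tuple[dict, ...]
    table: pd.DataFrame  # taxon, species, sub_group

    def write_audit(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(list(self.audit), indent=2) + "\n")


def assemble_species(
    groups: MutualGroupSet,
    evidence: Sequence[MergeEvidence],
    rule: MergeRule = MergeRule(),
) -> AssemblyResult:
    """Assemble final species from mutual groups plus merge evidence.

    A candidate pair is merged iff its sister support reaches ``min_bpp``
    AND the ranges are adjacent AND the morphology is similar; merges are
    closed transitively.  Unmerged mutual groups pass through unchanged
    (a mutual group is a species by default).  Within a merged species the
    original mutual groups become sub-groups labelled I, II, ...
    """
    seen: dict[tuple[int, int], MergeEvidence] = {}
    for ev in evidence:
        key = tuple(sorted(ev.pair))
        if key in seen and (
            seen[key].ranges_adjacent != ev.ranges_adjacent
            or seen[key].morphology_similar != ev.morphology_similar
            or seen[key].sister_bpp != ev.sister_bpp
        ):
            raise InputError(f"conflicting evidence rows for pair {key}")
        seen[key] = ev
    g = nx.Graph()
    g.add_nodes_from(range(groups.n_groups))
    audit: list[dict] = []
    for (i, j), ev in sorted(seen.items()):
        merged = bool(
            ev.sister_in_tree
            and ev.sister_bpp is not None
            and ev.sister_bpp >= rule.min_bpp
            and ev.ranges_adjacent
            and ev.morphology_similar
        )
        audit.append(
            {
                "pair": [i, j],
                "sister_bpp": ev.sister_bpp,
                "ranges_adjacent": ev.ranges_adjacent,
                "morphology_similar": ev.morphology_similar,
                "min_bpp": rule.min_bpp,
                "merged": merged,
            }
        )
        if merged:
            g.add_edge(i, j)
    rows = []
    species_groups: list[set[str]] = []
    components = sorted(nx.connected_components(g), key=min)
    for comp in components:
        members = sorted(comp)
        species_id = f"species_{len(species_groups) + 1:02d}"
        merged_taxa: set[str] = set()
        for k, gi in enumerate(members):
            sub = ROMAN[k] if len(members) > 1 else ""
            for t in sorted(groups.groups[gi]):
                rows.append({"taxon": t, "species": species_id, "sub_group": sub})
            merged_taxa |= groups.groups[gi]
        species_groups.append(merged_taxa)
    partition = Partition(species_groups, method="consensus")
    table = pd.DataFrame(rows, columns=["taxon", "species", "sub_group"])
    return AssemblyResult(partition=partition, audit=tuple(audit), table=table)


def read_evidence_csv(path: str | Path) -> list[MergeEvidence]:
    """Evidence CSV with columns group_i, group_j, ranges_adjacent,
    morphology_similar (booleans as true/false or 1/0)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            MergeEvidence(
                pair=(int(row["group_i"]), int(row["group_j"])),
                sister_in_tree=True,
                sister_bpp=float(row["sister_bpp"]) if "sister_bpp" in row else None,
                ranges_adjacent=_to_bool(row["ranges_adjacent"]),
                morphology_similar=_to_bool(row["morphology_similar"]),
            )
        )
    return out


def _to_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"1", "true", "yes", "y"}
    return bool(x)
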