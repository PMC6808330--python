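"""Species-diagnostic nucleotide characters on the COI barcode frame.

A position is diagnostic for a focal species when every individual of that
species carries a determinate base (A/C/G/T) there, and none of the states
seen in the focal species is ever observed, determinately, in any of the
other labelled species.  Positions are reported 1-based on the 658-bp COI
barcode fragment, in the field's "position:state" notation (multi-state
private polymorphisms joined with "/", e.g. "214:G/C").
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .alignment import DETERMINATE, MultiLocusAlignment
from .exceptions import InputError


@dataclass(frozen=True)
class DiagnosticSet:
    """Ordered diagnostic sites of one species."""

    species: str
    sites: tuple[tuple[int, tuple[str, ...]], ...]  # (1-based position, states)

    def __post_init__(self) -> None:
        pos = [p for p, _ in self.sites]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise InputError("positions must be strictly increasing")
        if any(not (1 <= p <= 658) for p in pos):
            raise InputError("positions must lie in 1..658")
        if any(len(states) == 0 for _, states in self.sites):
            raise InputError("empty state set")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.sites)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species": self.species,
            "sites": [{"position": p, "states": list(st)} for p, st in self.sites],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DiagnosticSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            payload["species"],
            tuple((d["position"], tuple(d["states"])) for d in payload["sites"]),
        )


def _columns_with_positions(aln: MultiLocusAlignment) -> list[tuple[int, int]]:
    """(column, 1-based barcode position) pairs over the diagnostic frame."""
    if aln.coi_frame is not None:
        return list(aln.coi_frame)
    return [(i, i + 1) for i in range(min(aln.n_columns, 658))]


def diagnostic_sites(
    aln: MultiLocusAlignment,
    labels: Mapping[str, str],
    focal: str,
) -> DiagnosticSet:
    """Extract the diagnostic sites of ``focal`` against all other species
    named in ``labels`` (taxa absent from the label map are ignored — the
    comparison is between the characterised species only).

    Rule (a): every focal individual must carry a determinate base at the
    position (missing or ambiguous focal data disqualifies the site).
    Rule (b): the focal state set must be disjoint from the determinate
    states of every other labelled species; missing data in non-focal
    species is ignored.  States are reported by focal frequency, then
    alphabetically.
    """
    focal_taxa = [t for t, sp in labels.items() if sp == focal]
    if not focal_taxa:
        raise InputError(f"unknown focal species {focal!r}")
    other_taxa = [t for t, sp in labels.items() if sp != focal]
    focal_rows = [aln.row(t) for t in focal_taxa]
    other_rows = [aln.row(t) for t in other_taxa]
    sites: list[tuple[int, tuple[str, ...]]] = []
    for col, pos in _columns_with_positions(aln):
        focal_states = [r[col] for r in focal_rows]
        if any(c not in DETERMINATE for c in focal_states):
            continue
        counts = Counter(focal_states)
        other_states = {r[col] for r in other_rows if r[col] in DETERMINATE}
        if set(counts) & other_states:
            continue
        ordered = tuple(sorted(counts, key=lambda c: (-counts[c], c)))
        sites.append((pos, ordered))
    return DiagnosticSet(species=focal, sites=tuple(sites))


def format_diagnosis(ds: DiagnosticSet) -> str:
    """Render as in a taxonomic Diagnosis paragraph: "184:C, 325:C, ..."."""
    return ", ".join(f"{p}:{'/'.join(states)}" for p, states in ds.sites)


def parse_diagnosis(species: str, text: str) -> DiagnosticSet:
    """Inverse of :func:`format_diagnosis` (useful for checking published
    diagnoses against an alignment)."""
    sites = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        pos, states = token.split(":")
        sites.append((int(pos), tuple(states.split("/"))))
    return DiagnosticSet(species, tuple(sites))


@dataclass(frozen=True)
class SiteCheck:
    position: int
    claimed_states: tuple[str, ...]
    confirmed: bool
    reason: str = ""
    violator: str | None = None


def verify_diagnosis(
    aln: MultiLocusAlignment,
    labels: Mapping[str, str],
    claimed: DiagnosticSet,
) -> list[SiteCheck]:
    """Regression-check a claimed diagnosis against an alignment.

    Each claimed site is checked for rule (a) (all focal individuals
    determinate), rule (b) (no other species shares a focal state; the
    first violating taxon is named) and agreement of the observed focal
    state set with the claimed one.
    """
    focal_taxa = [t for t, sp in labels.items() if sp == claimed.species]
    if not focal_taxa:
        raise InputError(f"unknown focal species {claimed.species!r}")
    by_pos = {pos: col for col, pos in _columns_with_positions(aln)}
    checks: list[SiteCheck] = []
    for pos, states in claimed.sites:
        if pos not in by_pos:
            raise InputError(f"position {pos} outside the barcode frame")
        col = by_pos[pos]
        focal_obs = {t: aln.row(t)[col] for t in focal_taxa}
        bad = [t for t, c in focal_obs.items() if c not in DETERMINATE]
        if bad:
            checks.append(
                SiteCheck(pos, states, False, "indeterminate focal state", bad[0])
            )
            continue
        observed = set(focal_obs.values())
        if observed != set(states):
            checks.append(
                SiteCheck(
                    pos, states, False,
                    f"observed focal states {sorted(observed)} differ from claim",
                )
            )
            continue
        violator = None
        for t, sp in labels.items():
            if sp == claimed.species:
                continue
            c = aln.row(t)[col]
            if c in DETERMINATE and c in observed:
                violator = t
                break
        if violator is not None:
            checks.append(
                SiteCheck(pos, states, False, "state shared by another species", violator)
            )
        else:
            checks.append(SiteCheck(pos, states, True))
    return checks


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV (taxon, species), with or without a header row."""
    labels: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        taxon, species = line.split("\t")
        if i == 0 and taxon.lower() in {"taxon", "id", "specimen"}:
            continue
        labels[taxon] = species
    return labels
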