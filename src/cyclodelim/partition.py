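"""Taxon partitions: the common currency of the delimitation stages.

A :class:`Partition` is a set of disjoint, non-empty taxon groups whose union
covers the full taxon set under study.  Both the distance-based and the
tree-based delimitation stages emit partitions, and the consensus stage
consumes them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .exceptions import InputError


def _canonical_groups(groups: Iterable[Iterable[str]]) -> tuple[frozenset[str], ...]:
    fs = [frozenset(g) for g in groups]
    # deterministic order: by smallest member lexicographically
    return tuple(sorted(fs, key=lambda g: sorted(g)))


@dataclass(frozen=True)
class Partition:
    """Disjoint taxon groups covering a taxon set.

    Parameters
    ----------
    groups:
        Iterable of taxon-id collections.  Groups must be disjoint and
        non-empty.
    method:
        Free-text label of the producing method (e.g. ``"barcode_gap"``,
        ``"ml_ptp"``).
    support:
        Optional per-group support values in [0, 1], aligned with ``groups``
        after canonical sorting is applied to both.
    """

    groups: tuple[frozenset[str], ...]
    method: str = ""
    support: tuple[float, ...] | None = None

    def __init__(
        self,
        groups: Iterable[Iterable[str]],
        method: str = "",
        support: Mapping[frozenset[str], float] | Sequence[float] | None = None,
    ) -> None:
        raw = [frozenset(g) for g in groups]
        if any(len(g) == 0 for g in raw):
            raise InputError("empty group in partition")
        seen: set[str] = set()
        for g in raw:
            if seen & g:
                raise InputError(f"groups not disjoint: {sorted(seen & g)}")
            seen |= g
        canon = _canonical_groups(raw)
        sup: tuple[float, ...] | None = None
        if support is not None:
            if isinstance(support, Mapping):
                sup = tuple(float(support[g]) for g in canon)
            else:
                if len(support) != len(raw):
                    raise InputError("support length does not match group count")
                by_group = dict(zip(raw, support))
                sup = tuple(float(by_group[g]) for g in canon)
        object.__setattr__(self, "groups", canon)
        object.__setattr__(self, "method", method)
        object.__setattr__(self, "support", sup)

    @property
    def taxa(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.groups:
            out |= g
        return frozenset(out)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self, taxon: str) -> frozenset[str]:
        for g in self.groups:
            if taxon in g:
                return g
        raise InputError(f"unknown taxon {taxon!r}")

    def as_labels(self) -> dict[str, int]:
        """Map each taxon to the index of its group (canonical order)."""
        return {t: i for i, g in enumerate(self.groups) for t in g}

    def refines(self, other: "Partition") -> bool:
        """True if every group of ``self`` is contained in a group of ``other``."""
        if self.taxa != other.taxa:
            return False
        return all(any(g <= h for h in other.groups) for g in self.groups)

    @classmethod
    def from_labels(cls, labels: Mapping[str, object], method: str = "") -> "Partition":
        by: dict[object, set[str]] = {}
        for taxon, lab in labels.items():
            by.setdefault(lab, set()).add(taxon)
        return cls(by.values(), method=method)

    # ------------------------------------------------------------------ I/O
    def to_json(self, path: str | Path, params: dict | None = None) -> None:
        payload = {
            "method": self.method,
            "params": params or {},
            "groups": [sorted(g) for g in self.groups],
        }
        if self.support is not None:
            payload["support"] = list(self.support)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Partition":
        payload = json.loads(Path(path).read_text())
        return cls(
            payload["groups"],
            method=payload.get("method", ""),
            support=payload.get("support"),
        )

    def to_tsv(self, path: str | Path) -> None:
        """Flat two-column table: taxon <tab> group index."""
        lines = ["taxon\tgroup"]
        for i, g in enumerate(self.groups):
            for t in sorted(g):
                lines.append(f"{t}\t{i}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, method: str = "") -> "Partition":
        labels: dict[str, str] = {}
        rows = Path(path).read_text().splitlines()
        for row in rows[1:]:
            if not row.strip():
                continue
            taxon, group = row.split("\t")
            labels[taxon] = group
        return cls.from_labels(labels, method=method)
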