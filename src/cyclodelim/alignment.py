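"""Aligned multi-locus sequence data and pairwise genetic distances.

The barcode-gap stage of the pipeline works on a matrix of pairwise genetic
distances computed from an aligned DNA barcode fragment (a 658-bp stretch of
the mitochondrial COI gene in the motivating snail system).  This module
provides the alignment container, FASTA I/O, locus concatenation, haplotype
collapsing and the p / JC69 / K2P distance estimators.

Conventions
-----------
* Characters are upper-case; ``-`` is an alignment gap and ``?`` missing data.
* IUPAC ambiguity codes are retained on reading but can be masked to ``?``
  with :func:`mask_ambiguities` (heterozygous calls are treated as missing
  data downstream).
* Distances use pairwise deletion: a site contributes to a pair only when
  both sequences carry a determinate base (A/C/G/T) there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import AlignmentFormatError, InputError, UndefinedDistanceError

DETERMINATE = frozenset("ACGT")
AMBIGUITY = frozenset("RYSWKMBDHVN")
GAP = "-"
MISSING = "?"

#: integer encoding used by the distance kernels; purines are even, so a
#: substitution is a transition iff both codes share parity
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class Locus:
    """Half-open, 0-based column span of one locus inside an alignment."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(f"invalid locus span {self.name}: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MultiLocusAlignment:
    """Aligned character matrix with per-locus coordinate frames.

    ``coi_frame`` optionally maps alignment columns (0-based) to 1-based
    positions on the 658-bp COI barcode fragment; diagnostic-site reporting
    uses this frame.
    """

    taxa: tuple[str, ...]
    seqs: tuple[str, ...]
    loci: tuple[Locus, ...]
    coi_frame: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.seqs):
            raise InputError("taxa/sequence count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise InputError(f"duplicate taxon identifiers: {dupes}")
        if self.seqs:
            ncol = len(self.seqs[0])
            for t, s in zip(self.taxa, self.seqs):
                if len(s) != ncol:
                    raise AlignmentFormatError(
                        f"ragged alignment: {t!r} has length {len(s)}, expected {ncol}"
                    )
        spans = sorted(self.loci, key=lambda l: l.start)
        for a, b in zip(spans, spans[1:]):
            if a.end > b.start:
                raise InputError(f"overlapping loci {a.name} and {b.name}")
        if self.loci and self.seqs and spans[-1].end > self.n_columns:
            raise InputError("locus span exceeds alignment length")
        if self.coi_frame is not None:
            pos = [p for _, p in self.coi_frame]
            if any(b <= a for a, b in zip(pos, pos[1:])) or (pos and pos[-1] > 658):
                raise InputError("coi_frame must be strictly increasing and <= 658")

    # ------------------------------------------------------------ accessors
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def row(self, taxon: str) -> str:
        try:
            return self.seqs[self.taxa.index(taxon)]
        except ValueError:
            raise InputError(f"unknown taxon {taxon!r}") from None

    def locus(self, name: str) -> Locus:
        for l in self.loci:
            if l.name == name:
                return l
        raise InputError(f"unknown locus {name!r}")

    def slice_locus(self, name: str) -> "MultiLocusAlignment":
        l = self.locus(name)
        frame = None
        if self.coi_frame is not None:
            frame = tuple((c - l.start, p) for c, p in self.coi_frame if l.start <= c < l.end)
            frame = frame or None
        return MultiLocusAlignment(
            taxa=self.taxa,
            seqs=tuple(s[l.start:l.end] for s in self.seqs),
            loci=(Locus(l.name, 0, l.length),),
            coi_frame=frame,
        )

    def ambiguity_cells(self) -> list[tuple[str, int]]:
        """(taxon, column) pairs carrying an IUPAC ambiguity code."""
        out = []
        for t, s in zip(self.taxa, self.seqs):
            out.extend((t, i) for i, c in enumerate(s) if c in AMBIGUITY)
        return out

    @property
    def has_ambiguities(self) -> bool:
        return any(c in AMBIGUITY for s in self.seqs for c in s)

    def encoded(self) -> np.ndarray:
        """Integer matrix: A/C/G/T -> 0..3, anything else -> -1."""
        arr = np.full((self.n_taxa, self.n_columns), -1, dtype=np.int8)
        for i, s in enumerate(self.seqs):
            arr[i] = [_CODE.get(c, -1) for c in s]
        return arr


def default_coi_frame(n_columns: int) -> tuple[tuple[int, int], ...]:
    """Identity frame: column i is barcode position i+1 (capped at 658)."""
    return tuple((i, i + 1) for i in range(min(n_columns, 658)))


# ---------------------------------------------------------------------- I/O
def read_alignment(
    path: str | Path,
    format: str = "fasta",
    locus_name: str | None = None,
    coi_frame: bool = False,
) -> MultiLocusAlignment:
    """Read an aligned FASTA file into a :class:`MultiLocusAlignment`.

    All records must have the same aligned length; sequences are upper-cased.
    With ``coi_frame=True`` the identity barcode frame is attached (use for a
    COI-only alignment in reading frame from position 1).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise AlignmentFormatError(f"no records in {path}")
    taxa = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    name = locus_name or path.stem
    aln = MultiLocusAlignment(
        taxa=taxa,
        seqs=seqs,
        loci=(Locus(name, 0, len(seqs[0])),),
        coi_frame=default_coi_frame(len(seqs[0])) if coi_frame else None,
    )
    return aln


def write_alignment(aln: MultiLocusAlignment, path: str | Path, width: int = 60) -> None:
    """Write aligned FASTA (wrapped at ``width`` columns) plus behaviour-free
    locus metadata in a JSON sidecar ``<path>.loci.json``."""
    path = Path(path)
    with open(path, "w") as fh:
        for t, s in zip(aln.taxa, aln.seqs):
            fh.write(f">{t}\n")
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")
    sidecar = {
        "loci": [{"name": l.name, "start": l.start, "end": l.end} for l in aln.loci],
    }
    if aln.coi_frame is not None:
        sidecar["coi_frame"] = [list(x) for x in aln.coi_frame]
    path.with_suffix(path.suffix + ".loci.json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_loci_sidecar(aln: MultiLocusAlignment, path: str | Path) -> MultiLocusAlignment:
    payload = json.loads(Path(path).read_text())
    loci = tuple(Locus(d["name"], d["start"], d["end"]) for d in payload["loci"])
    frame = payload.get("coi_frame")
    return replace(
        aln,
        loci=loci,
        coi_frame=tuple(tuple(x) for x in frame) if frame else None,
    )


# ----------------------------------------------------------- transformations
def mask_ambiguities(aln: MultiLocusAlignment) -> MultiLocusAlignment:
    """Replace every IUPAC ambiguity code by ``?`` (missing data).

    Heterozygous or otherwise ambiguous base calls carry no reliable state
    information for distance estimation or diagnostic-site extraction, so
    they are treated as unobserved.  Gaps are left untouched.
    """
    table = str.maketrans({c: MISSING for c in AMBIGUITY})
    return replace(aln, seqs=tuple(s.translate(table) for s in aln.seqs))


def concatenate_loci(
    alns: Sequence[MultiLocusAlignment],
    fill_missing: bool = True,
) -> MultiLocusAlignment:
    """Concatenate single- or multi-locus alignments column-wise.

    Taxon order follows first appearance across the inputs.  A taxon absent
    from some locus gets a block of ``?`` there when ``fill_missing`` is on;
    otherwise the absence is an error.
    """
    if not alns:
        raise InputError("no alignments to concatenate")
    taxa: list[str] = []
    for a in alns:
        for t in a.taxa:
            if t not in taxa:
                taxa.append(t)
    loci: list[Locus] = []
    names_seen: set[str] = set()
    offset = 0
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    frame: list[tuple[int, int]] = []
    for a in alns:
        for l in a.loci:
            name = l.name
            k = 2
            while name in names_seen:
                name = f"{l.name}_{k}"
                k += 1
            names_seen.add(name)
            loci.append(Locus(name, offset + l.start, offset + l.end))
        if a.coi_frame is not None:
            frame.extend((offset + c, p) for c, p in a.coi_frame)
        present = set(a.taxa)
        for t in taxa:
            if t in present:
                parts[t].append(a.row(t))
            elif fill_missing:
                parts[t].append(MISSING * a.n_columns)
            else:
                raise InputError(
                    f"taxon {t!r} missing from a locus and fill_missing is off"
                )
        offset += a.n_columns
    return MultiLocusAlignment(
        taxa=tuple(taxa),
        seqs=tuple("".join(parts[t]) for t in taxa),
        loci=tuple(loci),
        coi_frame=tuple(frame) or None,
    )


def collapse_haplotypes(
    aln: MultiLocusAlignment,
) -> tuple[MultiLocusAlignment, dict[str, list[str]]]:
    """Keep one representative per identical aligned row.

    Identity is strict character-for-character equality (including gaps and
    ``?``); mask ambiguities first if heterozygous calls should not break
    identity.  The representative is the first taxon in input order; the
    returned mapping sends each representative to all taxa it stands for.
    """
    if aln.n_taxa == 0:
        raise InputError("cannot collapse an empty alignment")
    mapping: dict[str, list[str]] = {}
    rep_of: dict[str, str] = {}
    keep: list[int] = []
    for i, (t, s) in enumerate(zip(aln.taxa, aln.seqs)):
        if s in rep_of:
            mapping[rep_of[s]].append(t)
        else:
            rep_of[s] = t
            mapping[t] = [t]
            keep.append(i)
    collapsed = replace(
        aln,
        taxa=tuple(aln.taxa[i] for i in keep),
        seqs=tuple(aln.seqs[i] for i in keep),
    )
    return collapsed, mapping


# ------------------------------------------------------------------ distances
@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise genetic distances with model metadata."""

    taxa: tuple[str, ...]
    d: np.ndarray
    model: str
    deletion: str = "pairwise"

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise InputError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise InputError("nonzero diagonal in distance matrix")
        if np.any(~np.isfinite(self.d)) or np.any(self.d < 0):
            raise InputError("distances must be finite and non-negative")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def value(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.d[i, j])

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances (i<j) as a flat vector."""
        iu = np.triu_indices(self.n_taxa, k=1)
        return self.d[iu]

    def submatrix(self, taxa: Sequence[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return DistanceMatrix(tuple(taxa), self.d[np.ix_(idx, idx)], self.model, self.deletion)

    def reordered(self, taxa: Sequence[str]) -> "DistanceMatrix":
        if set(taxa) != set(self.taxa):
            raise InputError("reordering must use the same taxon set")
        return self.submatrix(taxa)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=self.taxa, columns=self.taxa).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, model: str = "unknown") -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(tuple(str(t) for t in df.index), df.to_numpy(dtype=float), model)

    def to_phylip(self, path: str | Path) -> None:
        lines = [f"{self.n_taxa}"]
        for t, row in zip(self.taxa, self.d):
            lines.append(t + "  " + "  ".join(f"{x:.6f}" for x in row))
        Path(path).write_text("\n".join(lines) + "\n")


def pairwise_distances(
    aln: MultiLocusAlignment,
    model: str = "k2p",
    saturate_cap: float | None = None,
) -> DistanceMatrix:
    """Pairwise genetic distances under the p, JC69 or K2P model.

    Sites where either sequence lacks a determinate base are excluded for
    that pair (pairwise deletion); ambiguity codes therefore never enter the
    transition/transversion counts.  When a distance correction is undefined
    (logarithm of a non-positive number, i.e. saturation) the pair is an
    error unless ``saturate_cap`` supplies a ceiling value to report instead.
    """
    if model not in {"p", "jc69", "k2p"}:
        raise InputError(f"unknown distance model {model!r}")
    if aln.n_taxa < 2:
        raise InputError("need at least two taxa for a distance matrix")
    enc = aln.encoded()
    n = aln.n_taxa
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        a = enc[i]
        for j in range(i + 1, n):
            b = enc[j]
            valid = (a >= 0) & (b >= 0)
            m = int(valid.sum())
            if m == 0:
                raise UndefinedDistanceError(
                    f"no comparable sites between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
                )
            diff = valid & (a != b)
            p = diff.sum() / m
            if model == "p":
                dij = p
            elif model == "jc69":
                arg = 1.0 - 4.0 * p / 3.0
                dij = _corrected(-0.75, arg, None, None, aln.taxa[i], aln.taxa[j], saturate_cap)
            else:  # k2p
                ts = diff & ((a & 1) == (b & 1))  # A<->G, C<->T share parity
                P = ts.sum() / m
                Q = p - P
                dij = _k2p(P, Q, aln.taxa[i], aln.taxa[j], saturate_cap)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(aln.taxa, d, model)


def _corrected(coef, arg, coef2, arg2, ta, tb, cap):
    if arg <= 0 or (arg2 is not None and arg2 <= 0):
        if cap is not None:
            return cap
        raise UndefinedDistanceError(
            f"saturated distance between {ta!r} and {tb!r} (set saturate_cap to bound it)"
        )
    val = coef * np.log(arg)
    if coef2 is not None:
        val += coef2 * np.log(arg2)
    return float(val)


def _k2p(P: float, Q: float, ta: str, tb: str, cap: float | None) -> float:
    return _corrected(-0.5, 1.0 - 2.0 * P - Q, -0.25, 1.0 - 2.0 * Q, ta, tb, cap)
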