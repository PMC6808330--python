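"""Seeded synthetic-data generators for every pipeline stage.

These generators produce inputs with the statistical structure the analysis
assumes — clustered barcode alignments with planted diagnostic sites, trees
whose branch lengths follow two exponential rate classes around a true
species partition, closed shell outlines with group-specific shape and
size, and caliper-measurement tables spanning the three morphotype classes
— together with the generating truth, so that recovery can be tested end to
end without any external data.  All generators are pure functions of their
configuration: the same seed yields byte-identical output.

The sequence simulator uses a simple symmetric (Jukes-Cantor-like)
substitution process; divergence levels are parameterized directly as
expected pairwise proportions of differing sites, which is what the
distance-based stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment import Locus, MultiLocusAlignment, default_coi_frame
from .diagnostics import DiagnosticSet
from .exceptions import InputError
from .morphometrics import (
    MORPHOTYPES,
    Outline,
    SpecimenRecord,
    classify_morphotype,
)
from .partition import Partition
from .trees import PhyloTree, read_newick

_BASES = "ACGT"


# ------------------------------------------------------------- sequences
@dataclass(frozen=True)
class SeqSimConfig:
    """Clustered barcode-alignment simulation.

    ``pi_within``/``pi_between`` are expected pairwise proportions of
    differing sites within and between species; ``m_diagnostic`` private
    (diagnostic) sites are planted per species, constant within the focal
    species and absent elsewhere.
    """

    n_species: int = 3
    n_per_species: int = 5
    length: int = 658
    pi_within: float = 0.01
    pi_between: float = 0.15
    m_diagnostic: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.pi_within < self.pi_between <= 0.75):
            raise InputError("need 0 <= pi_within < pi_between <= 0.75")
        if self.m_diagnostic * self.n_species > self.length:
            raise InputError("too many planted sites for the sequence length")


def gen_species_sequences(
    cfg: SeqSimConfig,
) -> tuple[MultiLocusAlignment, dict[str, str], dict[str, DiagnosticSet]]:
    """Simulate a species-clustered COI-like alignment with planted
    diagnostic sites; returns (alignment, true labels, planted truths)."""
    rng = np.random.default_rng(cfg.seed)
    K, n, L = cfg.n_species, cfg.n_per_species, cfg.length
    planted = np.sort(rng.choice(L, size=cfg.m_diagnostic * K, replace=False))
    root = rng.integers(0, 4, size=L)

    def mutate(seq: np.ndarray, p: float, protect: np.ndarray) -> np.ndarray:
        out = seq.copy()
        mask = rng.random(L) < p
        mask[protect] = False
        shifts = rng.integers(1, 4, size=int(mask.sum()))
        out[mask] = (out[mask] + shifts) % 4
        return out

    # species centroids: independent divergence from the root so that the
    # expected centroid-pair difference is ~ pi_between
    centroids = [mutate(root, cfg.pi_between / 2.0, planted) for _ in range(K)]
    species = [f"sp{s + 1:02d}" for s in range(K)]
    truths: dict[str, DiagnosticSet] = {}
    for s in range(K):
        my_sites = planted[s * cfg.m_diagnostic:(s + 1) * cfg.m_diagnostic]
        sites = []
        for pos in my_sites:
            shared = int(rng.integers(0, 4))
            private = (shared + int(rng.integers(1, 4))) % 4
            for z in range(K):
                centroids[z][pos] = private if z == s else shared
            sites.append((int(pos) + 1, (_BASES[private],)))
        truths[species[s]] = DiagnosticSet(species[s], tuple(sites))
    matrix = np.empty((K, n, L), dtype=np.int64)
    for s in range(K):
        for i in range(n):
            matrix[s, i] = mutate(centroids[s], cfg.pi_within / 2.0, planted)
    ambiguous = np.zeros((K, n, L), dtype=bool)
    # Independent centroid divergence leaves incidental fixed private states
    # at background sites; an ambiguous base call (as real chromatograms
    # have) removes their diagnostic status without touching the
    # pairwise-deletion distances much, so the planted sites are the only
    # diagnostic characters.  The calls rotate across individuals so no
    # single sequence loses a meaningful number of comparable sites.
    planted_mask = np.zeros(L, dtype=bool)
    planted_mask[planted] = True
    flip_counter = np.zeros(K, dtype=int)
    for col in range(L):
        if planted_mask[col]:
            continue
        state_sets = [set(matrix[s, :, col].tolist()) for s in range(K)]
        for s in range(K):
            others = set().union(*(state_sets[z] for z in range(K) if z != s))
            if not (state_sets[s] & others):
                ambiguous[s, flip_counter[s] % n, col] = True
                flip_counter[s] += 1
    taxa: list[str] = []
    rows: list[str] = []
    labels: dict[str, str] = {}
    for s in range(K):
        for i in range(n):
            chars = [_BASES[b] for b in matrix[s, i]]
            for col in np.nonzero(ambiguous[s, i])[0]:
                chars[col] = "N"
            name = f"{species[s]}_{i + 1:02d}"
            taxa.append(name)
            labels[name] = species[s]
            rows.append("".join(chars))
    aln = MultiLocusAlignment(
        taxa=tuple(taxa),
        seqs=tuple(rows),
        loci=(Locus("COI", 0, L),),
        coi_frame=default_coi_frame(L),
    )
    return aln, labels, truths


# ------------------------------------------------------------------ trees
@dataclass(frozen=True)
class TreeSimConfig:
    """Two-rate-class tree simulation: a Yule-style species topology with
    Exponential(lambda_sp) branch lengths, and per-species coalescent-style
    subtrees with Exponential(lambda_co) branch lengths."""

    n_species: int = 4
    n_per_species: int = 5
    lambda_sp: float = 1.0
    lambda_co: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_sp <= 0 or self.lambda_co <= 0:
            raise InputError("rates must be positive")
        if self.n_species < 2:
            raise InputError("need at least two species")


def _random_join_topology(items: list[str], rng: np.random.Generator, rate: float) -> str:
    """Random binary topology by sequential pairwise joining; every created
    edge gets an Exponential(rate) length."""
    nodes = list(items)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        li, lj = rng.exponential(1.0 / rate, size=2)
        merged = f"({nodes[i]}:{li:.10f},{nodes[j]}:{lj:.10f})"
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


def gen_ptp_tree(cfg: TreeSimConfig) -> tuple[PhyloTree, Partition]:
    """Simulate a tree with planted species; returns (tree, true partition)."""
    rng = np.random.default_rng(cfg.seed)
    species_blocks: list[str] = []
    groups: list[list[str]] = []
    for s in range(cfg.n_species):
        tips = [f"sp{s + 1:02d}_{i + 1:02d}" for i in range(cfg.n_per_species)]
        groups.append(tips)
        if len(tips) == 1:
            species_blocks.append(tips[0])
        else:
            species_blocks.append(_random_join_topology(tips, rng, cfg.lambda_co))
    newick = _random_join_topology(species_blocks, rng, cfg.lambda_sp) + ";"
    tree = read_newick(newick)
    return tree, Partition(groups, method="truth")


# --------------------------------------------------------------- outlines
@dataclass(frozen=True)
class OutlineGroupConfig:
    """Shape/size parameters of one synthetic shell population.

    ``aspect`` is the height/breadth ratio of the apertural-view outline;
    ``spire`` skews the upper half of the curve (a taller spire); breadth is
    drawn Normal(breadth_mean_mm, breadth_sd_mm)."""

    name: str
    aspect: float = 0.85
    spire: float = 0.15
    breadth_mean_mm: float = 31.0
    breadth_sd_mm: float = 1.0
    n: int = 10


@dataclass(frozen=True)
class OutlineSimConfig:
    groups: tuple[OutlineGroupConfig, ...]
    noise_sd_mm: float = 0.0
    n_points: int = 240
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_mm < 0:
            raise InputError("noise sd must be >= 0")
        if any(g.n < 1 for g in self.groups):
            raise InputError("each group needs n >= 1")


def gen_outlines(
    cfg: OutlineSimConfig,
) -> tuple[list[Outline], dict[str, str], list[SpecimenRecord]]:
    """Simulate closed shell outlines; returns (outlines, labels, records).

    Each outline is a low-order Fourier perturbation of an ellipse: the
    spire coefficient adds a sin(2θ) term that raises the upper contour.
    Height and breadth are measured from the generated curve's bounding box
    and the morphotype label is assigned by the interval classifier.
    """
    rng = np.random.default_rng(cfg.seed)
    theta = np.linspace(0.0, 2.0 * np.pi, cfg.n_points, endpoint=False)
    outlines: list[Outline] = []
    labels: dict[str, str] = {}
    records: list[SpecimenRecord] = []
    for g in cfg.groups:
        for i in range(g.n):
            breadth = max(1.0, rng.normal(g.breadth_mean_mm, g.breadth_sd_mm))
            height = g.aspect * breadth
            x = 0.5 * breadth * np.cos(theta)
            y = 0.5 * height * (np.sin(theta) + g.spire * np.sin(2.0 * theta))
            pts = np.column_stack([x, y])
            if cfg.noise_sd_mm > 0:
                pts = pts + rng.normal(0.0, cfg.noise_sd_mm, size=pts.shape)
            sid = f"{g.name}_{i + 1:03d}"
            outlines.append(Outline(sid, pts))
            labels[sid] = g.name
            h = float(pts[:, 1].max() - pts[:, 1].min())
            b = float(pts[:, 0].max() - pts[:, 0].min())
            rec = SpecimenRecord(sid, h, b)
            records.append(
                SpecimenRecord(sid, h, b, morphotype=classify_morphotype(rec))
            )
    return outlines, labels, records


# ------------------------------------------------------------ measurements
def gen_measurement_table(
    mix: Mapping[str, int] | Sequence[int],
    seed: int = 0,
) -> list[SpecimenRecord]:
    """Sample (height, breadth) uniformly within each morphotype class's
    defining region; the classifier recovers the requested counts exactly.

    ``mix`` is either a {morphotype: count} mapping or a (widespread,
    slightly_deviating, deviating) triple.
    """
    if not isinstance(mix, Mapping):
        mix = dict(zip(MORPHOTYPES, mix))
    unknown = set(mix) - set(MORPHOTYPES)
    if unknown:
        raise InputError(f"unknown morphotype classes: {sorted(unknown)}")
    if any(c < 0 for c in mix.values()):
        raise InputError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    boxes = {  # sampling boxes; rejection enforces the exact class
        "widespread": ((23.0, 31.0), (28.0, 35.0)),
        "slightly_deviating": ((21.0, 33.0), (26.0, 37.0)),
        "deviating": ((12.0, 42.0), (16.0, 46.0)),
    }
    records: list[SpecimenRecord] = []
    i = 0
    for cls in MORPHOTYPES:
        (hlo, hhi), (blo, bhi) = boxes[cls]
        for _ in range(mix.get(cls, 0)):
            while True:
                h = rng.uniform(hlo, hhi)
                b = rng.uniform(blo, bhi)
                rec = SpecimenRecord(f"SIM{i + 1:04d}", round(h, 1), round(b, 1))
                if classify_morphotype(rec) == cls:
                    break
            records.append(
                SpecimenRecord(rec.specimen_id, rec.height_mm, rec.breadth_mm, morphotype=cls)
            )
            i += 1
    return records
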