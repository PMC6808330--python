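"""Poisson-tree-processes (PTP) species delimitation on a rooted tree.

Model: conditional on a partition of the tips into species, every branch of
the tree belongs to one of two classes — *speciation* branches (between
species) and *coalescent* branches (inside a species' spanning subtree) —
and the lengths within each class are i.i.d. exponential with a class-
specific rate.  The rates are profiled out by their maximum-likelihood
estimates (rate = branch count / summed length), so the log-likelihood of a
partition is a closed form of the two class sums.

Two searches are provided: a deterministic greedy maximum-likelihood search
over clade partitions, and a Metropolis-Hastings sampler (flat prior over
clade partitions) that yields per-species posterior support as the
frequency with which exactly that tip set is sampled as a species.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, InputError, NonConvexPartitionError
from .partition import Partition
from .trees import PhyloTree

#: floor applied to branch lengths before rate estimation, so zero-length
#: branches (soft polytomies) do not produce an infinite rate
EPS = 1e-9


# ------------------------------------------------------------------ classes
@dataclass(frozen=True)
class BranchClassification:
    """Per-branch class assignment, indexed by the branch's child node."""

    classes: tuple[str | None, ...]  # "speciation" | "coalescent"; None at root

    @property
    def n_coalescent(self) -> int:
        return sum(c == "coalescent" for c in self.classes)

    @property
    def n_speciation(self) -> int:
        return sum(c == "speciation" for c in self.classes)


def classify_branches(tree: PhyloTree, partition: Partition) -> BranchClassification:
    """Assign every branch to the speciation or coalescent class.

    A branch is coalescent for species S iff the tips of S are split across
    the two sides of the branch (the branch then lies inside the minimal
    spanning subtree of S).  If two species both claim a branch the
    partition is not convex on the tree, which is an error.
    """
    tips = frozenset(tree.tips)
    if partition.taxa != tips:
        raise InputError("partition must cover exactly the tree's tips")
    n = tree.n_nodes
    owner = np.full(n, -1, dtype=int)  # species index claiming the branch
    tip_idx = tree.tip_index()
    for s, group in enumerate(partition.groups):
        if len(group) < 2:
            continue
        cnt = np.zeros(n, dtype=int)
        for t in group:
            cnt[tip_idx[t]] = 1
        for v in range(n):  # postorder node ids: children precede parents
            for c in tree.children[v]:
                cnt[v] += cnt[c]
        size = len(group)
        for v in range(n):
            if v == tree.root:
                continue
            if 0 < cnt[v] < size:
                if owner[v] != -1:
                    raise NonConvexPartitionError(
                        f"branch shared by species {owner[v]} and {s}: "
                        "partition is not convex on the tree"
                    )
                owner[v] = s
    classes: list[str | None] = []
    for v in range(n):
        if v == tree.root:
            classes.append(None)
        else:
            classes.append("coalescent" if owner[v] != -1 else "speciation")
    return BranchClassification(tuple(classes))


# ----------------------------------------------------------------- likelihood
@dataclass(frozen=True)
class PTPFit:
    logL: float
    lambda_sp: float | None
    lambda_co: float | None
    n_sp: int
    n_co: int


def _class_term(m: int, s: float) -> tuple[float, float | None]:
    if m == 0:
        return 0.0, None
    lam = m / s
    return m * np.log(lam) - m, lam


def ptp_loglik(tree: PhyloTree, partition: Partition) -> PTPFit:
    """Profile log-likelihood of a partition under the two-rate model.

    Rates are the exponential MLEs per class; branch lengths are floored at
    ``EPS``.  A class without branches contributes nothing (the model
    degrades to a single exponential class).
    """
    if np.all(tree.branch_lengths == 0):
        raise DegenerateInputError("all branch lengths are zero")
    cls = classify_branches(tree, partition)
    fl = np.maximum(tree.edge_len, EPS)
    m_co = s_co = m_sp = s_sp = 0.0
    for v in range(tree.n_nodes):
        if cls.classes[v] == "coalescent":
            m_co += 1
            s_co += fl[v]
        elif cls.classes[v] == "speciation":
            m_sp += 1
            s_sp += fl[v]
    ll_co, lam_co = _class_term(int(m_co), s_co)
    ll_sp, lam_sp = _class_term(int(m_sp), s_sp)
    return PTPFit(float(ll_co + ll_sp), lam_sp, lam_co, int(m_sp), int(m_co))


# ------------------------------------------------- clade-partition machinery
class _Clades:
    """Cached quantities for fast likelihood of clade partitions.

    A clade partition is represented by its set of species-root nodes: an
    antichain whose subtrees tile the tips.  All branches strictly below a
    species root are coalescent; everything else is speciation.
    """

    def __init__(self, tree: PhyloTree) -> None:
        self.tree = tree
        n = tree.n_nodes
        fl = np.maximum(tree.edge_len, EPS)
        fl[tree.root] = 0.0
        self.fl = fl
        self.fsum_below = np.zeros(n)
        for v in range(n):
            for c in tree.children[v]:
                self.fsum_below[v] += self.fsum_below[c] + fl[c]
        self.cnt_below = tree.cnt_below
        self.total_cnt = tree.n_branches
        self.total_sum = float(fl.sum())

    def stats(self, roots: frozenset[int]) -> tuple[int, float]:
        m = sum(int(self.cnt_below[v]) for v in roots)
        s = sum(float(self.fsum_below[v]) for v in roots)
        return m, s

    def loglik(self, m_co: int, s_co: float) -> float:
        ll_co, _ = _class_term(m_co, s_co)
        ll_sp, _ = _class_term(self.total_cnt - m_co, self.total_sum - s_co)
        return float(ll_co + ll_sp)

    def rates(self, m_co: int, s_co: float) -> tuple[float | None, float | None]:
        _, lam_co = _class_term(m_co, s_co)
        _, lam_sp = _class_term(self.total_cnt - m_co, self.total_sum - s_co)
        return lam_sp, lam_co

    def partition(self, roots: frozenset[int], method: str) -> Partition:
        return Partition([self.tree.tipset_below(v) for v in roots], method=method)

    def splits(self, roots: frozenset[int]) -> list[int]:
        return sorted(v for v in roots if not self.tree.is_tip[v])

    def merges(self, roots: frozenset[int]) -> list[int]:
        counts: dict[int, int] = {}
        for v in roots:
            p = self.tree.parent[v]
            if p != -1:
                counts[p] = counts.get(p, 0) + 1
        return sorted(p for p, c in counts.items() if c == len(self.tree.children[p]))

    def apply_split(self, roots: frozenset[int], v: int) -> frozenset[int]:
        return (roots - {v}) | set(self.tree.children[v])

    def apply_merge(self, roots: frozenset[int], p: int) -> frozenset[int]:
        return (roots - set(self.tree.children[p])) | {p}


@dataclass(frozen=True)
class DelimitationResult:
    partition: Partition
    logL: float
    lambda_sp: float | None
    lambda_co: float | None
    method: str
    support: dict[frozenset[str], float] | None = None
    seed: int | None = None
    n_generations: int | None = None
    low_samples: bool = False
    #: sampled-partition relative frequencies (MCMC only)
    sample_freqs: dict[tuple[frozenset[str], ...], float] | None = None

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        payload = {
            "method": self.method,
            "logL": self.logL,
            "lambda_sp": self.lambda_sp,
            "lambda_co": self.lambda_co,
            "seed": self.seed,
            "n_generations": self.n_generations,
            "partition": [sorted(g) for g in self.partition.groups],
        }
        if self.support is not None:
            payload["support"] = [
                {"species": sorted(g), "support": s} for g, s in self.support.items()
            ]
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def ml_ptp_search(tree: PhyloTree) -> DelimitationResult:
    """Deterministic greedy ML search over clade partitions.

    Starting from the single-species partition, the split (replacing one
    species by the clades of its root's children) that most improves the
    log-likelihood is applied until no split strictly improves; a merge pass
    then hill-climbs in the opposite direction.  Ties break on the lowest
    node index, making the search a pure function of the tree.
    """
    if tree.n_tips < 3:
        raise InputError("need at least three tips")
    cl = _Clades(tree)
    roots = frozenset({tree.root})
    ll = cl.loglik(*cl.stats(roots))
    best_roots, best_ll = roots, ll
    # descent phase: follow the best split all the way to singletons (even
    # through likelihood valleys) and remember the best state visited
    while True:
        cands = cl.splits(roots)
        if not cands:
            break
        step = max(
            ((cl.loglik(*cl.stats(cl.apply_split(roots, v))), -v) for v in cands),
        )
        roots = cl.apply_split(roots, -step[1])
        ll = step[0]
        if ll > best_ll + 1e-12:
            best_roots, best_ll = roots, ll
    roots, ll = best_roots, best_ll

    def hill_climb(cands, apply) -> bool:
        nonlocal roots, ll
        improved = False
        while True:
            best = None
            for v in cands():
                ll2 = cl.loglik(*cl.stats(apply(roots, v)))
                if ll2 > ll + 1e-12 and (best is None or ll2 > best[0] + 1e-12):
                    best = (ll2, v)
            if best is None:
                return improved
            ll = best[0]
            roots = apply(roots, best[1])
            improved = True

    while True:  # alternate merge/split passes until neither improves
        any_merge = hill_climb(lambda: cl.merges(roots), cl.apply_merge)
        any_split = hill_climb(lambda: cl.splits(roots), cl.apply_split)
        if not (any_merge or any_split):
            break
    m, s = cl.stats(roots)
    lam_sp, lam_co = cl.rates(m, s)
    return DelimitationResult(
        partition=cl.partition(roots, "ml_ptp"),
        logL=ll,
        lambda_sp=lam_sp,
        lambda_co=lam_co,
        method="ml_ptp",
    )


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; defaults mirror the common server settings of
    500,000 generations with 10% burn-in."""

    n_generations: int = 500_000
    burnin_fraction: float = 0.10
    seed: int = 0
    thin: int = 100
    start: str = "null"  # "null" (one species) or "ml"

    def __post_init__(self) -> None:
        if not (0 <= self.burnin_fraction < 1):
            raise InputError("burnin_fraction must be in [0, 1)")
        if self.thin < 1 or self.n_generations < self.thin:
            raise InputError("need n_generations >= thin >= 1")


def bptp_mcmc(tree: PhyloTree, cfg: MCMCConfig = MCMCConfig()) -> DelimitationResult:
    """Metropolis-Hastings sampling over clade partitions, flat prior.

    Moves: split a uniformly chosen splittable species at its root, or
    merge the species under a uniformly chosen mergeable node; the Hastings
    ratio is the ratio of available-move counts.  Support of a tip set is
    the fraction of post-burn-in thinned samples in which exactly that set
    is a species; the returned partition is the most frequently sampled one.
    """
    cl = _Clades(tree)
    rng = np.random.default_rng(cfg.seed)
    if cfg.start == "ml":
        start_part = ml_ptp_search(tree).partition
        roots = frozenset(tree.mrca(g) for g in start_part.groups)
    else:
        roots = frozenset({tree.root})
    m, s = cl.stats(roots)
    ll = cl.loglik(m, s)
    burnin = int(cfg.burnin_fraction * cfg.n_generations)
    samples: dict[tuple[frozenset[str], ...], int] = {}
    species_counts: dict[frozenset[str], int] = {}
    n_samples = 0

    def record(roots: frozenset[int]) -> None:
        nonlocal n_samples
        groups = tuple(sorted((tree.tipset_below(v) for v in roots), key=sorted))
        samples[groups] = samples.get(groups, 0) + 1
        for g in groups:
            species_counts[g] = species_counts.get(g, 0) + 1
        n_samples += 1

    for gen in range(cfg.n_generations):
        splits = cl.splits(roots)
        merges = cl.merges(roots)
        moves = len(splits) + len(merges)
        if moves:
            k = int(rng.integers(moves))
            if k < len(splits):
                prop = cl.apply_split(roots, splits[k])
            else:
                prop = cl.apply_merge(roots, merges[k - len(splits)])
            m2, s2 = cl.stats(prop)
            ll2 = cl.loglik(m2, s2)
            moves2 = len(cl.splits(prop)) + len(cl.merges(prop))
            log_alpha = ll2 - ll + np.log(moves) - np.log(moves2)
            if log_alpha >= 0 or rng.random() < np.exp(log_alpha):
                roots, m, s, ll = prop, m2, s2, ll2
        if gen >= burnin and (gen - burnin) % cfg.thin == 0:
            record(roots)

    support = {g: c / n_samples for g, c in species_counts.items()}
    best_groups = max(samples.items(), key=lambda kv: (kv[1], kv[0]))[0]
    best_roots = frozenset(tree.mrca(g) for g in best_groups)
    mb, sb = cl.stats(best_roots)
    lam_sp, lam_co = cl.rates(mb, sb)
    part = Partition(
        best_groups, method="bptp", support={g: support[g] for g in best_groups}
    )
    return DelimitationResult(
        partition=part,
        logL=cl.loglik(mb, sb),
        lambda_sp=lam_sp,
        lambda_co=lam_co,
        method="bptp",
        support=support,
        seed=cfg.seed,
        n_generations=cfg.n_generations,
        low_samples=n_samples < 100,
        sample_freqs={g: c / n_samples for g, c in samples.items()},
    )


# ----------------------------------------------------------- exact reference
def enumerate_clade_partitions(tree: PhyloTree) -> list[frozenset[int]]:
    """All clade partitions (antichains of species roots) of a tree.

    Feasible only for small trees; used as the exhaustive reference for
    validating the sampler.
    """

    def expand(v: int) -> list[list[int]]:
        out = [[v]]
        if not tree.is_tip[v]:
            child_sets = [expand(c) for c in tree.children[v]]
            for combo in itertools.product(*child_sets):
                out.append([u for part in combo for u in part])
        return out

    return [frozenset(state) for state in expand(tree.root)]


def exhaustive_posterior(tree: PhyloTree) -> dict[tuple[frozenset[str], ...], float]:
    """Exact posterior over clade partitions under a flat prior."""
    cl = _Clades(tree)
    states = enumerate_clade_partitions(tree)
    lls = np.array([cl.loglik(*cl.stats(st)) for st in states])
    w = np.exp(lls - lls.max())
    w /= w.sum()
    out = {}
    for st, p in zip(states, w):
        groups = tuple(sorted((tree.tipset_below(v) for v in st), key=sorted))
        out[groups] = float(p)
    return out
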