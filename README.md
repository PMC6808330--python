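# cyclodelim

Integrative species delimitation for cryptic land snails — and for any
taxon where morphologically near-identical populations hide several
species. The package implements, as a tested and reusable pipeline, the
workflow used to untangle such complexes from DNA barcodes and shell form:

1. **Barcode-gap partitioning** (`cyclodelim.gapsplit`) — pairwise genetic
   distances (p / JC69 / K2P, pairwise deletion) are scanned for the
   discontinuity between intra- and interspecific divergence over a
   log-spaced series of prior limits *P*, with a relative gap width *X*;
   single-linkage groups under the detected threshold form putative
   species, refined recursively within groups.
2. **Poisson tree processes (PTP)** (`cyclodelim.ptp`) — on a rooted
   phylogeny, branch lengths follow two exponential classes (between- vs
   within-species rates λ_sp, λ_co); the profile log-likelihood of a
   partition is Σ_class m(ln(m/S) − 1). A deterministic ML search and a
   Metropolis-Hastings sampler (flat prior over convex partitions,
   per-species posterior support) are provided.
3. **Consensus and species assembly** (`cyclodelim.consensus`) — groups
   confirmed by both delimitations ("mutual groups") become species;
   sister pairs merge only when node support ≥ 0.83 AND ranges are
   adjacent AND shells are similar, with a replayable audit log.
4. **Diagnostic nucleotides** (`cyclodelim.diagnostics`) — positions on the
   658-bp COI barcode frame where every focal individual carries a state
   absent from all other species, formatted "217:A" / "214:G/C" as in
   taxonomic Diagnosis paragraphs.
5. **Shell morphometrics** (`cyclodelim.morphometrics`) — 200 equally
   spaced semi-landmarks per outline, generalized Procrustes
   superimposition, canonical variate analysis, polygon-area shell size,
   and the explicit morphotype interval rule on shell height/breadth
   (widespread: H 23–31 mm and B 28–35 mm).
6. **Synthetic data** (`cyclodelim.simulate`) — seeded generators for
   clustered barcode alignments with planted diagnostic sites, two-rate
   trees with a known species partition, parametric shell outlines and
   measurement tables, so every stage is testable against ground truth.

See `docs/methods.md` for the models, numerical choices and limitations.

## Worked example

Simulate three species (five individuals each, COI-like 658 bp), run both
delimitations and intersect them:

```python
import cyclodelim as cd

aln, labels, truths = cd.gen_species_sequences(
    cd.SeqSimConfig(n_species=3, n_per_species=5, seed=7))
dm = cd.pairwise_distances(cd.mask_ambiguities(aln), model="k2p")
scan = cd.scan_priors(dm)
print(scan.table.to_string(index=False))

tree, _ = cd.gen_ptp_tree(cd.TreeSimConfig(n_species=3, n_per_species=5, seed=7))
res = cd.ml_ptp_search(tree)
mg = cd.mutual_groups(scan.recursive, res.partition, mode="strict")
print("mutual groups:", mg.n_groups)
print("diagnosis sp02:", cd.format_diagnosis(cd.diagnostic_sites(aln, labels, "sp02")))
```

Output:

```
       P  n_initial  n_recursive
0.001000         11           11
0.001668         11           11
0.002783         11           11
0.004642         11           11
0.007743          8            8
0.012915          3            3
0.021544          3            3
0.035938          3            3
0.059948          3            3
0.100000          3            3
mutual groups: 3
diagnosis sp02: 449:T, 511:G
```

Reading the table: at small priors the gap scan oversplits (11 groups); at
priors inside the true barcode gap both the one-shot and the recursive
partition stabilise at the three planted species, and the scan selects the
largest such prior. The tree-based ML-PTP search independently finds three
species (fitted rates λ̂_sp ≈ 0.88, λ̂_co ≈ 19.9 against the generating
1 and 20), all three groups are mutual, and species sp02 is diagnosable by
its private states T at position 449 and G at position 511 — exactly the
sites the generator planted.

A command-line interface mirrors the library
(`cyclodelim simulate|distances|gapsplit|ptp|consensus|diagnose|morpho`);
run `cyclodelim --help`.

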