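# stratcong

Stratigraphic congruence indices for rooted cladograms.

When a phylogeny is laid against the fossil record, every sister pair implies
that both lineages existed by the time the older of the two first appears —
so any branch whose taxon shows up later than its clade's origin subtends a
**ghost range**. How large these implied gaps are, and how often taxa appear
in the order the tree predicts, is what stratigraphic congruence indices
measure. Good congruence is a prerequisite for using first-occurrence (FO)
dates to time-calibrate trees; distributions of these indices across many
cladograms underpin claims about the completeness of the fossil record.

`stratcong` is for palaeobiologists and systematists who need these indices
for single trees or for meta-analyses, and for anyone studying the biases of
the indices themselves.

## What it computes

With MIG the sum of ghost ranges over the tree, and the topology-free bounds
Gmin = FO<sub>oldest</sub> − FO<sub>youngest</sub> and
Gmax = Σ<sub>i</sub>(FO<sub>oldest</sub> − FO<sub>i</sub>):

* **SCI** — fraction of non-root internal nodes whose oldest supported
  terminal is no older than its sister's (ties consistent).
* **GER** = 1 − (MIG − Gmin)/(Gmax − Gmin).
* **MSM\*** = Gmin/MIG, equivalently the minimum over observed length
  (L<sub>m</sub>/L<sub>o</sub>) of an irreversible Sankoff character coding
  FO ages — the package carries both routes and checks them against each
  other.
* **GERt** — the GER form with Gmin/Gmax replaced by the permutation bounds
  Gt<sub>min</sub>/Gt<sub>max</sub> attainable on the *observed* topology.
* **GER\*** — the fraction of permuted MIG values exceeding the observed MIG
  (an inverse-P-value-like index with a 0.5 null median).

It also provides the standard per-dataset covariates (Colless imbalance,
percent resolution, FO center of gravity and its scaled form, gap
variability, percent extant / no-fossil, median taxonomic rank), hard/soft
polytomy resolution against stratigraphic order, and a permutation
simulation study of how every index behaves on stratigraphically random
data as a function of tree balance and the number and temporal distribution
of FO dates.

## Worked example

Four taxa with FO ages A=10, B=4, C=6, D=9 (unit intervals, larger = older)
on the tree `((A,D),(C,B))`:

```sh
stratcong compute --tree tree.nwk --fo fo.csv --reps 1000 --seed 42
```

```json
{
  "report": {
    "sci": 0.5,
    "ger": 0.8,
    "msm_star": 0.8571428571428571,
    "ger_t": 1.0,
    "ger_star": 0.828,
    "mig": 7.0,
    "g_min": 6.0,
    "g_max": 11.0,
    "gt_min": 7.0,
    "gt_max": 10.0
  }
}
```

Reading: the tree implies 7 intervals of ghost range (MIG), against a best
case of 6 (a perfect ladder) and a worst case of 11 (the oldest taxon nested
deepest), so GER = 1 − (7−6)/(11−6) = 0.8. Of the two non-root internal
nodes, the cherry (C,B) is consistent and (A,D) is not: SCI = 0.5. On this
*balanced* topology no assignment of these four dates can do better than
MIG = 7 (the exhaustive permutation bound Gt<sub>min</sub> = 7), so
GERt = 1.0 even though GER = 0.8 — the topological rescaling removes the
balance penalty. GER* = 0.828 says 83% of random assignments imply more gap
than observed.

The same library calls are available in Python:

```python
import stratcong as sc
tree = sc.parse_newick("((A,D),(C,B));")
fo = sc.FOTable.from_ages({"A": 10, "B": 4, "C": 6, "D": 9})
report = sc.index_report(tree, fo, reps=1000, seed=42)
```

Other entry points: `stratcong covariates` (one-row CSV of the dataset
covariates), `stratcong simulate` (the 30-condition null-distribution study,
YAML-configurable).

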