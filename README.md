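# gouania

Analysis toolkit for the integrative species delimitation of the
Mediterranean clingfish genus *Gouania* (Gobiesocidae): DNA-barcoding
statistics on one side, morphometric range diagnostics and a dichotomous
identification key on the other.

*Gouania* are tiny fishes living in the interstitial spaces of intertidal
pebble beaches. The genus comprises five species in two look-alike
morphotypes ("stout" and "slender"), several of them sympatric, so neither
barcodes nor morphology alone settles identification — the revision combines
both. This package provides that combined pipeline as reusable, tested code
for taxonomists and molecular ecologists working on this group (or any
similar barcode-plus-morphometrics delimitation problem):

* **K2P distances** with pairwise deletion:
  `d = -½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)`, with P and Q the transition and
  transversion proportions; saturated pairs are flagged, never imputed.
* **Barcoding gap** per individual: maximum intraspecific vs minimum
  interspecific divergence (in %), positive gap ⇒ barcode-separable.
* **Net between-group divergence** `d_net = d_XY − (d_X + d_Y)/2` with a
  site-bootstrap standard error (default 1000 replicates).
* **Lineage clustering**: single linkage cut at a distance threshold
  (default 5%, inside the genus' barcoding gap).
* **Range diagnostics**: characters (as %SL, at printed table precision)
  whose species ranges do not overlap; touching ranges count as overlap.
* **Identification key engine**: vote-based couplet evaluation tolerant of
  missing and conflicting characters, returning candidate sets.
* **Synthetic generators** for K2P-evolved barcode alignments on a species
  tree and for morphometric specimens drawn from published ranges, so the
  whole pipeline runs and is testable offline.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

```python
import gouania as g

table = g.load_table1_fixture()

# morphometric characters separating the slender Adriatic species from all
# three stout species by non-overlapping %SL ranges
chars = g.diagnostic_characters(
    "G. pigra", ["G. adriatica", "G. orientalis", "G. willdenowi"], table)
print(f"{len(chars)} diagnostic characters: {', '.join(chars)}")

# genus-wide disc size in "times in SL" convention
ratio = g.pct_to_sl_ratio(table.genus_extremes("Disc length"))
print(f"genus disc length: {ratio.lo}-{ratio.hi} in SL")

# synthetic 5-lineage barcode study: gap, clustering, net divergence
aln = g.simulate_alignment(g.SimulationConfig(seed=1))
labels = {r.id: r.species for r in aln.records}
matrix = g.pairwise_k2p(aln)
gap = g.barcoding_gap(matrix, labels)
print(f"barcoding gap positive for {int((gap['gap_pct'] > 0).sum())}/{len(gap)} individuals")
clusters = g.cluster_lineages(matrix, threshold=0.05)
print(f"lineages at 5% threshold: {len(set(clusters))}")
res = g.net_divergence_with_bootstrap(
    aln, labels, ("G. adriatica", "G. orientalis"), replicates=1000, seed=1)
print(f"net divergence adriatica vs orientalis: {res.net*100:.2f}% (SE {res.bootstrap_se*100:.2f}%)")
```

prints

```
5 diagnostic characters: Caudal fin length, Disc length, Head length, Pectoral fin length, Prepectoral-fin length
genus disc length: 5.0-9.8 in SL
barcoding gap positive for 50/50 individuals
lineages at 5% threshold: 5
net divergence adriatica vs orientalis: 7.95% (SE 1.15%)
```

Reading: exactly five published morphometric characters separate *G. pigra*
from every stout species with no range overlap; the genus diagnosis "disc
small, 5.0–9.8 in standard length" falls out of the table's disc-length
extremes; and on a simulated five-lineage barcode dataset every individual
is barcode-separable, threshold clustering recovers the five lineages, and
the sister-species pair shows ~8% net K2P divergence — the shallow end of
the divergence range reported for the genus.

The same stages are available from the shell:

```sh
gouania diagnose --focal "G. pigra" --against "G. adriatica,G. orientalis,G. willdenowi"
gouania simulate-coi --seed 1 --out sim.fasta
gouania cluster sim.fasta --threshold 0.05
gouania net-divergence sim.fasta --pair "G. adriatica" "G. orientalis" --reps 1000 --seed 1
gouania run --config my_pipeline.yaml
```

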