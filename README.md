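# ighrep

Clonal-landscape analysis of IgH B-cell-receptor repertoires from sorted
splenic B-cell subsets, for immunologists comparing how follicular B
cells (FoB), age-associated B cells (ABC), germinal-center B cells (GCB)
and plasmablasts/plasma cells (PB/PC) relate clonally within lupus-prone
and wild-type mice.

The package consumes annotated heavy-chain rearrangements (AIRR
Rearrangement TSV: V/J gene calls, junction/CDR3, copy counts, sample
metadata) and provides:

* **Clone inference.** Rearrangements are partitioned by (V gene, J
  gene, CDR3 nucleotide length) and single-linkage clustered at ≥ 85%
  CDR3 amino-acid identity — i.e. clones are the connected components of
  the pairwise-identity graph at the 0.85 threshold. Clones whose
  copy-weighted consensus CDR3 nucleotide sequences lie within Hamming
  distance 2 are then merged across V/J calls, absorbing spurious clones
  created by incorrect gene calls.
* **Repertoire metrics.** The D20 clonality index
  (Σ copies of the 20 largest clones / Σ all copies), replicate-library
  Jaccard overlap |A∩B|/|A∪B|, somatic-hypermutation fraction per subset
  (clone-level % mutated V positions vs germline, unweighted or
  copy-weighted), CDR3-length distributions, and row-normalized top-20
  VH usage matrices. Each clone counts once per (strain, subset)
  stratum; a clone spanning subsets gets a per-subset SHM value computed
  only from that subset's sequences.
* **Cross-subset overlap.** Within-mouse clone presence/abundance
  tables, pairwise Jaccard and abundance-weighted cosine similarity
  matrices, Venn region counts, and ordered clone-presence tracks.
* **A ground-truthed simulator.** Synthetic cohorts (4 strains × 6
  sorted subsets × duplicate libraries) with tunable clone-size skew,
  SHM gradient, cross-subset sharing (elevated ABC↔PB/PC), within-clone
  CDR3 variants and gene-call errors — so every stage is testable
  without sequencing data.

## Worked example

```python
import ighrep

cfg = ighrep.SimConfig(seed=1, strains=("DKO-F",), n_mice_per_strain=1)
records, truth, germlines = ighrep.simulate(cfg)
clone_set = ighrep.call_clones(records)          # 85% identity, 2-nt collapse
print(len(records), "records ->", len(clone_set), "clones")

result = ighrep.evaluate_recovery(clone_set, truth)
print("ARI vs ground truth:", round(result.adjusted_rand_index, 3))
print(ighrep.d20_table(clone_set).to_string(index=False))
```

prints

```
1717 records -> 716 clones
ARI vs ground truth: 0.995
strain mouse_id       subset  n_clones      d20
 DKO-F DKO-F-m1          ABC       202 0.415000
 DKO-F DKO-F-m1          FoB       201 0.221667
 DKO-F DKO-F-m1 GCB_CD11cneg       200 0.545000
 DKO-F DKO-F-m1 GCB_CD11cpos       201 0.575000
 DKO-F DKO-F-m1  PB_CD11cneg       201 0.673333
 DKO-F DKO-F-m1  PB_CD11cpos       201 0.668333
```

716 called clones against 710 simulated ones and an adjusted Rand index
of 0.995 mean the two-stage clustering recovered the true clonal
partition almost exactly despite 2% injected gene-call errors. The D20
column shows the designed oligoclonality gradient: the 20 largest FoB
clones carry ~22% of that subset's copies, rising monotonically to ~67%
in the PB/PC pool.

The same analysis is available from a shell:

```sh
ighrep simulate --seed 1 --out-dir sim/
ighrep all --input sim/rearrangements.tsv \
           --germline-v sim/germline_v.fasta --germline-j sim/germline_j.fasta \
           --out-dir run/
```

which writes clone tables, per-stratum metric TSVs, overlap matrices,
Venn counts, and a manifest of content hashes for reproducibility.

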