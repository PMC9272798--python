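# Methods

## Labeling metal-binding from structure geometry

A polymer chain is metal-binding when at least one of its heavy atoms
lies within a cutoff of a metal atom. Conventions:

- **Cutoff 5.0 Å, inclusive.** "Within 5 Å" is read as a closed
  interval; the boundary case is exercised explicitly in the tests.
  The cutoff is a parameter of `label_chains`.
- **Heavy atom** = any atom whose element is not H or D, in any
  residue of the polymer (backbone and side chains alike). Metal
  distances are measured to the *metal atoms* of a ligand only, not to
  the ligand's organic envelope — the iron of a heme, not its
  porphyrin ring.
- **Ion classes.** Ten classes are configured by default (Na, K, Ca,
  Mg, Mn, Fe, Co, Cu, Ni, Zn), ignoring oxidation state. A ligand map
  sends known iron prosthetic groups (heme variants, Fe–S clusters) to
  Fe; any other metal-containing ligand falls back to its metal's
  element class. Metal elements outside the configured set are skipped
  with a logged warning.
- **Alternate locations** resolve to the highest-occupancy conformer
  (ties: first in file order). Modified residues map to their parent
  one-letter code where tabulated, else X. Parsing (PDB and mmCIF) is
  done with gemmi.

## Redundancy reduction and cross-validation

Pairwise identity is defined as the maximum number of matched
positions achievable by a global alignment — the longest common
subsequence — divided by the shorter sequence's length. This is the
only alignment-identity variant that is uniquely defined without
fixing gap penalties and a traceback order, and it admits a simple
independent dynamic-programming oracle. It is an upper bound on any
penalized alignment's identity (for unrelated protein pairs it
saturates near 0.4 rather than 0.05), which is conservative for
clustering: near the 0.70 threshold, where decisions matter, it
behaves like conventional identity. Replicating CD-HIT's heuristics
bit-for-bit is a non-goal.

Greedy clustering visits records longest-first (ties by id), joining
the first cluster whose representative reaches the threshold, and a
letter-multiset upper bound prunes comparisons without changing the
outcome. Exact duplicate sequences are removed before clustering.
Cluster classes use a strict purity rule: positive (negative) iff
*more than* 98% of members are positive (negative), else MIXED; MIXED
clusters are excluded from training. The same rule is applied per ion,
where an ion's negatives are all sequences not labeled for that ion,
binding or not.

Folds are built at the cluster level: positive and negative clusters
are separately partitioned into k groups of near-equal sequence
counts (largest-first into the lightest group after a seeded
shuffle), and within each group negative clusters are down-sampled at
random until the negative sequence count does not exceed the
positive. No cluster member can therefore appear on both sides of any
fold.

## Features

Each sequence maps to a fixed-layout vector with three blocks:

1. **Composition (20):** fractions of the canonical residues among
   canonical positions; non-canonical letters (X/B/Z/U/O) are excluded
   from numerator and denominator.
2. **Physicochemical means (6):** sequence means of Kyte–Doolittle
   hydropathy, side-chain net charge at pH 7 (His counted 0.1),
   polarity indicator, residue molecular weight (Da), aromaticity
   indicator (F/W/Y/H), and a coarse count of side-chain hydrogen-bond
   donors+acceptors. The table is replaceable via TSV; the property
   order is recorded in the schema.
3. **Metal-site 5-mer counts (one per ion):** the number of sequence
   windows present in the ion's vocabulary, overlaps counted, raw (not
   length-normalized). The vocabulary is built from labeled training
   structures: for every residue with a heavy atom within the cutoff
   of a bound metal, the ±2-residue window is collected for that
   ion; windows that leave the sequence or contain a non-canonical
   letter are dropped. `k`, the flank, and a minimum occurrence count
   are exposed as parameters.

The schema (block order, property names, ion order) is embedded in
every trained model so alternative layouts remain loadable. The
feature dimension is therefore a parameter of the data, not a
constant of the code.

## The two-tier network

Both tiers are fully connected networks: two hidden ReLU layers whose
width equals the input dimension, dropout 0.2 on hidden activations
during training only, a single sigmoid output, binary cross-entropy
loss, and RMSprop (decay 0.9, epsilon 1e-7). Tier 1 consumes the base
feature vector; tier 2 trains one network per ion on the base vector
plus the tier-1 score (input dimension D+1), that ion's binders
against everything else, negatives down-sampled to balance. Ions with
fewer than two positives are skipped rather than zero-padded.

Implementation choices the architecture leaves open:

- **Numpy implementation.** Initialization (He normal), dropout masks
  and updates are driven by one seeded generator, so training is
  bit-reproducible and inference is a pure function of (model,
  sequence). No installed library exposes this exact configuration
  (scikit-learn's MLP lacks dropout and RMSprop), and scikit-learn
  remains available as an independent cross-check in the tests.
- **Feature standardization.** Columns are standardized to training
  mean/variance inside the model (stored with the weights): the
  blocks live on scales three orders of magnitude apart (composition
  ~0.05 vs molecular weight ~130), and standardization makes one
  learning rate serve all of them.
- **Learning rate.** Library default 5e-6 with 1000 epochs and no
  early stopping; the geometric search (0.5 divided by 10 down to
  5e-7, shortest-run loss decides, ties to the larger rate) is
  available as `lr_search`. Batch size: full batch up to 512 samples,
  else mini-batches of 32, recorded in the config.
- **Cutoffs.** Tier-1 calls default to score ≥ 0.4 (the F1-maximizing
  cutoff on a 0.01 grid, ties to the lowest), tier-2 to ≥ 0.5, with
  0.9 marking high-confidence tier-2 calls. Boundary scores count as
  positive.

Models serialize as a single zip (JSON metadata + npz weight arrays);
a save/load round trip reproduces scores to ≤1e-12.

## Evaluation

AUROC is the trapezoid area under the ROC curve; AUPRC uses step
interpolation (Σ ΔR·P), which never overstates the area between
observed points; both are computed via scikit-learn and checked
against exhaustive threshold-enumeration oracles in the tests. Zero
denominators in confusion metrics yield 0 with an explicit flag.
Cross-validation reports both per-fold metrics and metrics pooled
over the concatenated held-out scores; the two can differ and no
choice is hidden.

## Screening

Fragments are all windows of 50 residues at step 1 (L−49 per
sequence; shorter sequences yield none); per-protein aggregation of
fragment scores defaults to the maximum (mean and fraction-positive
selectable). Reads are translated in six frames with the bacterial
codon table. Two conventions are ours rather than prescribed:

- **Stops:** translations are split at stop codons and each stop-free
  segment is filtered independently (≥16 residues kept).
- **Partial codons:** a trailing 1–2 nt codon translates to X, like a
  codon containing N. Under this rule a stop-free 48 nt read yields
  six 16-residue peptides (one per frame) and a 45 nt read yields
  none, which is the intended boundary behavior of the ≤15-residue
  discard; translation is performed codon-by-codon over Biopython's
  codon-table data because `Seq.translate` resolves some N-ambiguous
  codons (GCN → A) instead of emitting X.

A sample's metal profile is, per ion, the fraction of evaluated
peptides with a positive tier-2 call (denominator: all peptides by
default; only metal-binding ones, or tier-1-gated calls, by flag).
Profiles use the fixed ion order (Ca, Co, Cu, Fe, K, Mg, Mn, Na, Ni,
Zn) and are compared by Euclidean distance. Read QC, assembly and ORF
calling are upstream concerns; the screening entry points accept
already-processed FASTA/FASTQ.

## Synthetic data

The generator produces the conditions the method assumes, not
realistic biology:

- **Sequences:** two balanced classes (default 1000+1000), lengths
  uniform on 80–160; positives cycle through three ion classes with
  disjoint planted 5-mers of coordinating residues (Zn: CHHCC, Fe:
  HEDEH, Cu: HMHCM; two non-overlapping copies each) plus a +0.03
  frequency shift toward C/H/D/E; negatives are uniform background,
  in which a motif still occurs at the chance rate of 20⁻⁵ per
  position. One seed determines every byte of output.
- **Structures:** glycine Cα atoms on a line at 3.8 Å spacing with the
  metal placed orthogonally at the target distance, making the true
  minimum heavy-atom distance exactly controllable.
- **Reads:** fixed-length samples from reverse-translated proteins
  (uniform synonymous codons), random strand, constant quality, with
  the protein of origin recorded.

What passing on this data shows: the pipeline recovers a known,
decodable signal (planted k-mers + composition shift) through the
full path — labeling, clustering, fold construction, both training
tiers, screening — and stays at chance under permuted labels. What it
does not show: performance on real proteins, where the signal is
weaker, vocabularies are large and noisy, homology structure is
deeper than the 70% threshold, and class balance is far from 1:1.
Published corpus-scale numbers are not reproducible at this scale and
are not asserted anywhere in the tests.

Desk-scale training conditions used by the test-suite and
`scripts/acceptance.py`: 2000 sequences, 3 ions, 10 folds, 120
epochs, learning rate 1e-2 (a stable mid-range rate for standardized
features at this data size; the search protocol favors the largest
candidates on this cleanly separable data). Full-scale defaults
(1000 epochs, lr 5e-6) remain the library defaults.

## Known limitations

- The LCS-based identity is generous for unrelated pairs; clustering
  of real, highly diverse sets may merge slightly more than CD-HIT
  would at the same threshold.
- The greedy clustering is O(n²) in the worst case; the multiset
  prefilter helps only when compositions differ.
- The 5-mer vocabulary concretization (±2 window around contact
  residues) is one defensible reading of "metal-site 5-mers"; the
  feature dimension is kept parametric for alternatives.
- Crystallographic metals with no biological role are labeled binding
  by construction; no relevance filtering is attempted.
- Tier-2 models for ions with very few positives are skipped, so ion
  coverage depends on the training corpus.
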