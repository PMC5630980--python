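# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Transcript classification

Classification is a pure decision tree over per-transcript evidence; the
package never re-implements external predictors (CPC/CNCI-style tools,
BLAST, HMMER) but consumes their verdicts from an evidence table.

* **ORF criterion.** Longest ATG-to-stop ORF over all six frames, length
  in amino acids excluding the stop; an ORF must terminate inside the
  sequence. The gate is strict (`> 100 aa`). Ties between equally long
  ORFs resolve to the forward strand, lower frame, leftmost start, making
  reported coordinates deterministic. Codons containing `N` are treated
  as neither start nor stop.
* **Coding potential.** Logical OR over predictor votes; an empty vote
  set is non-coding. For runs without external tools a clearly-labelled
  internal stand-in votes "coding" when the longest ORF covers ≥ 50% of
  the transcript; it is never consulted when real votes are present.
* **Homology.** Inclusive thresholds mirroring BLAST flag semantics:
  e ≤ 1e-5, alignment length ≥ 90 columns, identity ≥ 80%; a Pfam hit
  passes by itself. Alignment length is interpreted as alignment-column
  count (the nt-vs-aa ambiguity for translated searches is upstream of
  this package).
* A contaminant hit (small-ncRNA homology) overrides everything.

## Expression and differential expression

FPKM is computed exactly as count / ((length/10³)·(library/10⁶)) with
library sizes defaulting to column sums. Activity is strict
(FPKM > 0.5 in ≥ 1 sample), so a transcript at exactly the threshold in
every sample is inactive; raising the threshold can only shrink the
active set.

The DE caller is deliberately self-contained rather than a wrapper
around an external package. Counts are rescaled to a common library
size; a common negative-binomial dispersion is estimated by the method
of moments, phi = median over transcripts of (var − mean)/mean², floored
at zero. Group sums then follow NB distributions with shared per-sample
size 1/phi, and a two-sided exact test conditions on the pooled total,
summing the probabilities of all splits at most as likely as the one
observed. When the data show no overdispersion (phi ≈ 0) the test falls
back to Fisher's exact test on pooled counts against library totals.
log₂ fold change uses per-million normalized group means with a
pseudo-count of 1, which keeps sample-specific transcripts finite. The
DE gates are inclusive: p ≤ 0.001 and |log₂FC| ≥ 2 (the fold-change-4
formulation is the same threshold). Swapping the groups negates the fold
change and leaves p unchanged by construction. TMM-style normalization,
FDR correction and replicate-aware GLMs are out of scope: the gate
operates on raw p-values.

## miRNA discovery

* **Scan.** Hamming distance (no indels) ≤ 1 against both strands; an
  antisense hit is an occurrence of the reverse complement on the
  forward strand. U/T are equivalent everywhere.
* **Precursor windows.** A ladder of symmetric flanks, 10–110 nt per
  side in steps of 10, clipped at transcript ends and required to retain
  ≥ 15 nt beyond the mature — window lengths 42–242 nt for a 22-nt
  mature. Antisense hits are evaluated on the reverse-complemented
  window so a candidate always carries its mature 5'→3'.
* **Folding engine.** An engine interface with two implementations. The
  default is a bundled maximum-weighted-pairing folder (Nussinov-style
  dynamic program; pair weights AU = 1, GC = 2, GU = 1; minimum loop 3;
  traceback prefers pairing the outer bases, then 5'-most moves), whose
  "MFE" is the negated pairing weight. It is exactly reproducible across
  platforms, which the planted-truth experiments rely on. A ViennaRNA
  adapter (`engine="vienna"`) provides thermodynamic folding when the
  bindings are installed; precomputed dot-bracket + MFE tables can also
  be supplied through the structure-TSV reader.
* **Star inference.** The star span mirrors the full mature span through
  the median pairing diagonal (robust to small bulges) and the reported
  star sequence carries the conventional 2-nt 3' overhang. Criteria are
  evaluated on the overhang-free core: the overhang is unpaired by
  definition and would otherwise fail the cut-site check unconditionally.
* **Validation criteria.**
  - c1: unpaired positions (per-position, so bulges count each base)
    within the mature ≤ 4 and within the star core ≤ 6;
  - c2: the first and last base of the mature and of the star core must
    pair into the partner arm. The window is 1 nt per end by default and
    configurable (`cut_site_width`) since the biological cut-site width
    is not sharply defined;
  - c3: exactly one hairpin loop lies between the two arms. A single
    branch stem between the arms is an interior extension of the stem
    (one hairpin loop on the path) and passes; two or more branches form
    a true multi-loop and fail;
  - c4: neither arm overlaps the head of the hairpin, defined as the
    terminal loop *plus its closing pair*. Including the closing pair
    means a mature whose last pair closes the terminal loop fails c4
    while still passing c2 — the two criteria stay independent, which
    the planted-violation experiments require.
* **MFEI/GC gates.** AMFE = MFE/length·100 and MFEI = AMFE/GC% are
  always reported; numeric gates on them default to off because no
  defensible universal threshold exists for the bundled energy scale.
* **Window selection.** Among passing windows: lowest MFEI, then
  shortest precursor, then 5'-most window start. A rejected hit reports
  its most nearly passing window (fewest failed criteria, same
  tie-breaks), which is what the per-criterion violation diagnostics
  read.
* **Attribution.** An accepted mature inherits the union of the
  active-expression patterns (strict FPKM > 0.5 per sample group) of its
  precursor transcripts.

## Target prediction

Both filter profiles run on the package's own scoring machinery — the
published tools behind the two-profile idea are not numerically
reproducible from their descriptions, and the analysis-defining
computation is the threshold-and-intersect logic.

* **Alignment score (profile B).** Local antiparallel complementarity
  alignment: Watson-Crick +5, G:U +2, mismatch −3, affine gaps
  (−9 open, −4 extend), substitution scores ×4 at miRNA seed positions
  2–8. A 22-nt perfect complement scores 4·(7·5) + 15·5 = 215. Ties
  resolve to the 5'-most target site. Gates: score ≥ 140 and energy of
  the best-scoring site ≤ −25 kcal/mol, both inclusive.
* **Duplex energy (profile A).** Minimum-energy intermolecular duplex
  under a simplified nearest-neighbor model: stacking energy
  −0.85·(s(p)+s(q)) for adjacent pairs with s(CG) = 2.0, s(AU) = 1.1,
  s(GU) = 0.5; interior loops/bulges cost 3.0 + 0.9·(unpaired nt), at
  most 6 unpaired per side per loop. The energy is ≤ 0 by construction
  and 0 when nothing pairs. The scale is calibrated to the conventional
  −25 kcal/mol gate: a perfect ~20-bp duplex lands in the −40…−65 range,
  random 22-mers almost never pass. Gate: best-site energy ≤ −25.
* **Consensus.** Pair-level set intersection; site coordinates need not
  agree between profiles. Sub-site details (all passing sites of a pair)
  stay in the hit records.
* **Plant mode.** psRNATarget-style penalty expectation: mismatch 1.0,
  G:U 0.5, indel 2.0, doubled at miRNA positions 2–13; global in the
  miRNA, local in the CDS; hit iff expectation ≤ 3.0 (inclusive). The
  parameters are conventions of plant small-RNA targeting practice, not
  fitted values.

## Networks

Undirected graphs with typed nodes; edges only between a miRNA and a
target, one edge per consensus pair, so |edges| equals the summed pair
counts after deduplication. An id occurring as both mRNA and lncRNA is
an error rather than a silent retype. ceRNA candidates are all
(lncRNA, mRNA) pairs with a non-empty shared miRNA neighbor set, sorted
by shared-set size then lexically. Sample subnetworks are induced on the
miRNAs attributed to a group plus their targets; filtering targets by
their own activity is available behind an optional argument but off by
default. Exports: SIF (`mirna targets target`) and GraphML with node
type and sample-pattern attributes.

## Synthetic data

The generator emulates the *downstream products* of a pooled multi-sample
assembly — never reads, adapters or assembly errors.

* **Transcriptome.** Trinity-style ids over `n_genes` genes with a
  geometric isoform count (cap 6); lognormal lengths (median ≈ 700 bp)
  floored at 201 bp; bases drawn to a target GC of 0.41. Isoforms of a
  gene share a sequence prefix. Class labels (default 30% mRNA, 50%
  lncRNA, 15% unknown, 5% contaminant) and the mixed criterion patterns
  of `unknown` transcripts are assigned by largest remainder — exact
  counts, not samples. mRNA-class transcripts get a planted
  110–400-aa ORF (their length floor rises to 350 bp so the ORF fits);
  all other classes have chance ORFs broken by in-frame stop insertion
  until none exceeds 100 aa. Evidence tables are synthesized to realize
  each transcript's criterion pattern exactly, with ORF lengths always
  recomputed from the emitted sequence, so classification on noise-free
  evidence recovers the planted classes exactly.
* **Hairpins.** A planted pre-miRNA is an inverted repeat
  mature + spacer(5) + loop(6–9 A) + rc(spacer) + rc(mature) replacing a
  same-length slice of the host; ~40% are inserted reverse-complemented
  to exercise antisense discovery. Violation constructs are minimal
  edits: 5 scattered unpairable star bases (c1), one unpairable base at
  a duplex end (c2), two branch stems between the arms (c3), or no
  spacer so the mature closes the terminal loop (c4). Because a
  maximum-pairing fold can sometimes absorb an intended defect through
  an alternative structure, every insertion is verified by running the
  discovery evaluation over *all* scan hits on the host (the star arm is
  itself found as an opposite-strand hit) and retried with fresh random
  choices until a violation-free construct passes and a violation fails
  with exactly its designed criterion on every path. Insertions also may
  not flip the host's ORF criterion.
* **Counts.** Gene-level baseline means are lognormal (median = the
  `depth_mean` parameter, default 100); counts are negative-binomial
  with common dispersion 0.05 (biological CV ≈ 0.22, typical for
  laboratory RNA-seq and consistent with the generator's contract that a
  null simulation at n = 1000 shows a median |log₂FC| below 0.2).
  Eight samples in four groups (larva, male, female, other) mirror a
  pooled multi-stage design; DE transcripts differ between larva and all
  adult groups by 2^`true_log2fc` with alternating direction; a
  configurable fraction is silenced (all-zero) to exercise the activity
  filter. FPKM is derived through the expression module from the
  simulated counts.
* **What passing tests do not show.** The generator produces no
  misassemblies, chimeras, partial ORFs, sequencing noise in the
  evidence tables, composition bias, or realistic homology between
  planted matures and non-precursor loci. Recovery rates on it certify
  the decision logic and structure evaluation, not robustness to noisy
  real evidence.

## Numerical and scale choices

Problem sizes in the test suite and the acceptance script are chosen to
exercise every code path at desk scale: ~150-hairpin recovery
experiments, 1,000-transcript DE simulations over 10 seeds,
≤ 200-nt targets for exhaustive-site oracles, ~500-node random networks.
Percentages are recomputed from integer counts with half-up rounding at
report time; nothing caches a rounded float. All randomness flows
through seeded numpy generators; identical seeds give byte-identical
outputs, including FASTA/TSV/JSON files.

## Limitations

* The bundled folder maximizes weighted pairings, not free energy; its
  MFE/AMFE/MFEI values are on an engine-specific scale and should not be
  compared against thermodynamic thresholds from the literature. Use the
  ViennaRNA engine for thermodynamically meaningful values.
* The duplex energy model omits dangling ends, terminal AU penalties and
  coaxial stacking; its −25 kcal/mol gate is calibrated within this
  package only.
* The exact NB test enumerates the pooled total and slows for very deep
  counts (totals ≫ 10⁵ per transcript); the DE surface here targets
  threshold logic and recovery, not inference at extreme depth.
* Star inference assumes a single dominant duplex register; pathological
  structures with a mature pairing into two distant regions are rejected
  rather than resolved.
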