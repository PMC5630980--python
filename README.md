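# lncmir

Annotation of a de novo insect transcriptome into coding and long
non-coding RNA, homology-guided microRNA discovery with hairpin-structure
validation, miRNA target prediction under a two-profile consensus rule,
and construction of miRNA–lncRNA–mRNA (ceRNA) interaction networks.

The package is written for transcriptomics of non-model organisms — the
motivating system is the Wheat Stem Sawfly (*Cephus cinctus*), a wheat
pest whose larval and adult stages differ sharply in their coding and
non-coding expression programs — but every stage runs on any assembled
transcriptome with Trinity-style `cNN_gG_iK` identifiers. A synthetic-data
module generates transcriptomes with planted ground truth (classes, ORFs,
pre-miRNA hairpins, differential expression) so the whole pipeline is
testable end to end without any external data.

## The analysis

**Transcript classification.** Each assembled transcript (> 200 bp) is
screened against three criteria: longest six-frame ORF strictly longer
than 100 aa; a "coding" verdict from at least one coding-potential
predictor; and homology to known coding sequences (BLAST hit with
e ≤ 1e-5, alignment length ≥ 90 and identity ≥ 80%, or a Pfam domain).
Transcripts matching a small-ncRNA contaminant screen are eliminated;
transcripts passing all three criteria are mRNAs, transcripts failing all
three are lncRNAs, and mixed evidence is left `unknown`.

**Expression.** Abundance is FPKM
(count / ((length/10³)·(library/10⁶))); a transcript is *actively
expressed* when FPKM > 0.5 in at least one sample. Differential
expression between sample groups uses an exact negative-binomial count
test with a method-of-moments common dispersion; a transcript is DE when
p ≤ 0.001 and |log₂FC| ≥ 2 (fold change ≥ 4).

**miRNA discovery.** Reference mature miRNAs are scanned against both
strands of every transcript allowing at most one mismatch. Each hit is
extended into a ladder of candidate precursor windows, folded, and the
stem-loop is validated: ≤ 4 unpaired positions in the mature and ≤ 6 in
the star (c1); paired duplex ends at the Dicer-like cut sites (c2); no
multi-loop between the arms (c3); neither arm reaching the hairpin head
(c4). MFE, AMFE = MFE/len·100 and MFEI = AMFE/GC% are reported per
precursor.

**Targets and networks.** miRNA–target duplexes are scored by a seeded
complementarity alignment (miRanda-like scale) and a nearest-neighbor
duplex energy; profile A requires energy ≤ −25 kcal/mol, profile B
requires score ≥ 140 *and* energy ≤ −25, and only pairs reported by both
profiles are kept (the consensus). Consensus pairs over mRNA and lncRNA
target sets form an undirected tripartite network; (lncRNA, mRNA) pairs
sharing a miRNA neighbor are ceRNA (target-mimicry) candidates, and
per-stage subnetworks are induced from the sample attribution of each
miRNA's precursor transcripts. A plant-mode scanner (psRNATarget-style
penalty expectation, cutoff 3.0) supports cross-species screens of
insect miRNAs against host-plant coding sequences.

## Worked example

```python
from lncmir import simulate, classify, expression, hairpin, targets, network

cfg = simulate.SimConfig(n_genes=60, n_planted_hairpins=6, seed=42)
bundle = simulate.simulate_study(cfg)

classes = classify.classify_all(bundle.evidence)
print(classes["class"].value_counts().to_dict())
# {'lncRNA': 49, 'mRNA': 29, 'unknown': 15, 'contaminant': 5}

active = expression.active_filter(bundle.fpkm)      # FPKM > 0.5 anywhere
print(len(bundle.transcripts), len(active))         # 98 93

res = hairpin.discover(bundle.transcripts, bundle.reference_matures,
                       fpkm=bundle.fpkm, groups=bundle.config.groups)
print(len(res.accepted_matures))                    # 6
row = res.table[res.table["accepted"]].iloc[0]
print(row["mature"], row["transcript_id"], row["strand"],
      row["precursor_len"], round(row["mfei"], 2))
# syn-miR-1 c37_g1_i1 sense 142 -1.4
```

All six planted violation-free hairpins validate (their precursor windows
pass c1–c4); the MFEI of −1.4 is the hairpin-quality index of the
selected 142-nt precursor window. Feeding the validated matures to both
target profiles and intersecting:

```python
mirnas = {m: bundle.reference_matures[m] for m in res.accepted_matures}
cons = targets.consensus(targets.scan_profile_a(mirnas, target_seqs),
                         targets.scan_profile_b(mirnas, target_seqs))
g = network.build_network(cons_mrna, cons_lncrna)
network.cerna_candidates(g)   # (lncRNA, mRNA, shared-miRNA set) triples
```

A command-line interface mirrors the library
(`lncmir simulate|de|classify|discover|targets-scan|targets-consensus|network-build|network-cerna|report-summary`);
networks export to SIF/GraphML for Cytoscape.

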