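# Methods

## Model and assumptions

The package treats drug repositioning as a network-coverage problem: a drug is
a plausible candidate for a patient when the signaling machinery it perturbs
(its mechanism-of-action network) covers a large part of the patient's
dysregulated signaling network. Both networks are built the same way — map a
set of *source* genes, the *activated transcription factors*, and the TFs'
*up-regulated target genes* onto a protein–protein interactome, link every
(source, TF) pair by a shortest path, and hang each up-regulated target off
its TF as a regulatory edge. The construction assumes:

- **Signal flows through short PPI chains.** Shortest paths over the
  undirected, unweighted interactome are taken as a proxy for signal
  transduction routes. Edge direction, confidence weights and path
  multiplicity beyond the retained shortest paths are ignored.
- **TF activity is readable from its targets.** A TF is called activated when
  its most responsive targets are strongly up-regulated — the mean of the top
  three target fold changes (all targets when it has fewer than three) at an
  inclusive threshold T = 2.0. Down-regulation (repression) is not scored.
- **z-scores can stand in for fold changes.** Drug-instance differential
  expression comes as z-score profiles; the identical activation and
  up-regulation rules run on them, with the same default cutoff 2.0. Whether
  the top-3 rule is exactly right for z-scores is an assumption, not a fact;
  the cutoff is a config knob (`zscore_threshold`).

## Parameters

| parameter | default | meaning |
|---|---|---|
| TF activation threshold T | 2.0 (unitless fold change / z) | inclusive cutoff on the activation score |
| up-regulation cutoff | 2.0 | inclusive cutoff for a TF target to join the network |
| top-k targets averaged | 3 | targets entering the activation score when available |
| instance filter | 24 h, "10 uM" | treatment time and dose label kept for scoring; dose labels compared verbatim |
| excluded cell line | none | set to the patient's own line to avoid circular scoring |
| tie-break | lexicographic | shortest-path choice among equal-length paths (`all` keeps every one) |
| max path length | none | optional cap on retained path length |
| active cutoff multiplier | 1.5 | growth-rate cutoff at mean − 1.5·SD (sample SD; `ddof=0` gives population SD) |
| evaluation ks | 30, 50, 70, 100 | top-k depths for enrichment |

Fold change is a plain ratio, not a log-ratio: the thresholds above read as
ratios, and all cutoffs are inclusive (≥). Duplicate expression rows collapse
by arithmetic mean (configurable to max).

## Numerical and design choices

- **Dijkstra ≡ BFS.** Edges are unweighted, so shortest paths are computed by
  breadth-first search. Weighted or confidence-scored variants are out of
  scope.
- **Deterministic tie-breaking.** Equal-length shortest paths are resolved by
  taking the lexicographically smallest node sequence (greedy minimal-neighbor
  descent over a BFS distance map from the destination). Two runs on the same
  inputs produce byte-identical network files. An `all`-paths mode exists for
  sensitivity analysis. Because the true tie-break used in any published
  network is generally unknowable, exact node/edge counts of published
  networks are not reproducible in general; the package reports PPI and
  regulatory edge counts separately so either counting convention can be
  inspected.
- **One path per (source, TF) pair** in the default mode; unreachable pairs
  contribute nothing, and a source unreachable from every TF is excluded
  rather than kept isolated. TF→target regulatory edges are inserted even when
  the pair is not an interactome edge; an edge that is both on a retained path
  and regulatory keeps its `ppi` flag.
- **Overlap counts genes, not edges**, and a gene with several roles counts
  once. The score normalizer |Pnet| is the fixed patient-network node count,
  not an instance-specific quantity.
- **Ties at the 3rd-largest target** are broken lexicographically; the score
  is unaffected (tied values are equal), only the reported contributing
  targets are.
- **Strict readers.** Malformed input is a fatal, located error; benign
  normalisations (self-loop removal, duplicate collapsing, unmapped-gene
  drops, skipped instances) are logged with counts and echoed in the run
  manifest. No gene-symbol alias resolution is attempted: identity is the
  trimmed, case-sensitive symbol string, so symbols must be harmonised across
  the interactome, TF map, catalog and expression inputs upstream. The
  interactome reader applies no organism or interaction-type filter; any such
  subsetting is the caller's responsibility.

## The synthetic universe

`moarank.synthetic` generates a miniature, fully self-consistent input set
with planted ground truth, used by the test suite and the acceptance script.

- **What it emulates.** The topology of the real problem: a hub-connected
  interactome scaffold in which every (source, TF) shortest path is unique and
  known, planted activated TFs whose top targets have fold change 4 against a
  background of 1, drugs whose catalog targets are chosen so that their MoA
  networks overlap the patient network by an exact planted fraction, instance
  z-score profiles that activate one drug-private TF through private marker
  genes (so instances never cross-activate each other's TFs), and a screening
  table with a small strongly-suppressed active tail against an inactive bulk
  near growth rate 80, so the mean − 1.5·SD rule separates exactly the planted
  actives. Filler genes (preferential attachment by default, Erdős–Rényi
  optionally) attach only to the hub or each other, which preserves the
  uniqueness of the planted paths.
- **What it does not emulate.** Realistic transcriptomic count distributions,
  probe-level noise structure, correlated expression, hub promiscuity of real
  interactomes, symbol ambiguity, or the scale of real inputs (default: 10
  disease genes, 20 TFs, 10 drugs × 2 instances, |Pnet| = 31, ~180 genes).
  Passing the planted-truth tests therefore shows the pipeline computes its
  defined quantities exactly and deterministically — not that the method's
  biological assumptions hold on real data.
- **Noise model.** `noise_sd` adds Gaussian noise to per-sample fold-change
  multipliers and to z-scores (and, scaled, to screening rates). In noise-free
  mode recovery is exact: each pipeline score equals round(f·|Pnet|)/|Pnet|.
  At noise_sd = 0.25 the planted-vs-recovered rank correlation stays above
  0.8 (a seeded property test); a zero-overlap drug can drop out when noise
  fails to activate its private TF.
- All randomness flows from the single `seed` through one numpy generator;
  identical specs produce byte-identical directories.

## Problem sizes in tests and the acceptance script

The brute-force shortest-path oracle runs on 200 random connected graphs of
4–12 nodes; the Monte-Carlo check of the random baseline uses 100,000
hypergeometric draws at (402, 26, 30); end-to-end recovery uses the default
synthetic universe above. The worked-example enrichment is recomputed on a
reconstructed 402-drug ranking whose ten top-30 actives sit at their published
ranks with their published scores and growth rates, the remaining 16 actives
placed beyond rank 300, and filler drugs given interpolated scores — for
top-30 metrics only the positions of actives at ranks ≤ 30 and the totals
(26 actives among 402) matter, and those are fixed by the published table.

## Known limitations

- No statistical significance machinery: no permutation p-values for TF
  activation, no hypergeometric test on enrichment — only the expectation
  baseline.
- The score ignores *how* networks overlap (which roles, which pathways);
  two drugs covering different halves of the patient network with equal
  coverage tie.
- Down-regulated signaling and reverse-signature (connectivity-map-style)
  evidence are not used; combining them with the coverage score is an obvious
  extension.
- Scoring is only as good as the drug-target catalog and instance profiles;
  drugs without targets or without surviving instances are silently (but
  loggedly) absent from the ranking.
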