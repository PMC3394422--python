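# phytomir

Integrated plant miRNA target prediction, filtering and benchmarking.

Plant miRNAs silence their targets through near-perfect antisense
complementarity, most often by guiding cleavage within the coding
region of the mRNA. That makes rule-based prediction workable — scan
transcripts for antisense hits of each mature miRNA — but the classic
predictors disagree substantially because they weigh the same duplex
features differently: mismatch/G:U/gap counts, the seed (miRNA
positions 2–8), the central region (9–11, where cleavage-competent
duplexes must pair), the core (2–12), the hybridization-energy ratio,
and target-site accessibility. `phytomir` puts the whole workflow in
one offline package:

* **one shared scan** finds candidate sites by minimum-penalty gapped
  antiparallel alignment (mismatch 1.0, G:U 0.5, gap 2.0, all doubled
  in the core 2–12; lower is better, a perfect site scores 0);
* **four engine rule sets** (WMD3-like, UEA-like, TAPIR-like,
  psRNATarget-like) accept or reject each candidate, including the
  G:U-counts-as-a-mismatch rule (cutoff 5), the no-central-mismatch
  rule, weighted-score cutoffs, the energy-ratio ≥ 70% gate, and
  cleavage-vs-translation classification by central mismatches;
* **an energy layer** computes duplex energy (G:C −3, A:U −2, G:U −1
  kcal/mol), the ratio against the perfect reverse complement, and
  target-site accessibility = opening energy (Nussinov-style pairing
  DP over ≤ 100 nt flanks) + duplex energy, with a pluggable backend
  contract for rigorous thermodynamic engines;
* **four filters** — multi-method consensus over ≥ 90%-overlap site
  groups, site multiplicity (default ≥ 2 groups per pair),
  accessibility (default ≤ −15.87 kcal/mol), degradome support
  (default score ≤ 4.5 at the mRNA level);
* **benchmark metrics**: PM/VM/CM counts, additional prediction
  AP = 100·(PM−VM)/PM, true-positive rate TP = 100·CM/N_ref, filter
  ratio and filter power (geometric mean of filter ratio and AP),
  pairwise predictor agreement, and per-region attribution tables;
* **a seeded synthetic generator** that plants coordinate-known
  (optionally edited) target sites into random transcripts and emits
  every input the pipeline needs: miRNA/transcript FASTA, reference
  and degradome TSV, and a ground-truth table.

## Worked example

```bash
phytomir synth --seed 5 --out demo --n-mirnas 3 --n-transcripts 4 \
    --min-length 300 --max-length 450
phytomir predict -m demo/mirnas.fasta -t demo/transcripts.fasta -o demo/pred.tsv
phytomir filter demo/pred.tsv -o demo/filtered.tsv --multi-method 2
phytomir evaluate demo/filtered.tsv --reference demo/reference.tsv
```

prints (filter log to stderr, evaluation to stdout):

```
INFO phytomir: multi-method >= 2: removed 13 (ratio 0.765)
INFO phytomir: kept 4 of 17 site records -> demo/filtered.tsv
PM=4	VM=4	CM=4	AP=0.00%	TP=100.00%
```

The generator planted 4 perfect sites (one per transcript). The four
engines produced 17 site records (one per accepting engine, plus a
stray single-engine background hit); consensus filtering collapsed
each planted site's records into one group supported by all four
engines and discarded the rest. All 4 site groups match the reference
(VM = PM ⇒ AP = 0.00%), and all 4 reference pairs are recovered at
mRNA level (TP = 100.00%). `demo/pred.tsv` is a stable 13-column TSV
(coordinates are 0-based half-open; `score` is the weighted penalty;
`energy_ratio` ∈ [0,1]), and `phytomir extract`/`phytomir sort` slice
and reorder it.

The same workflow is available as library calls
(`run_all_engines`, `filter_multi_method`, `benchmark`, …) on typed
in-memory objects.

## Layout

```
src/phytomir/
  datamodel.py   core types, coordinate conventions, mRNA-level collapse
  align.py       pair taxonomy, weighted scoring, sliding scan
  energy.py      duplex/perfect energy, ratio, flanks, Nussinov opening energy
  engines.py     the four rule sets and the combined runner
  filters.py     overlap grouping and the four filters
  evaluate.py    PM/VM/CM, AP/TP, filter power, agreement, region tables
  synth.py       seeded fixture generator with planted ground truth
  io.py, cli.py  FASTA/TSV readers and writers, result rows, CLI
docs/methods.md  model, parameters, assumptions, limitations
```
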