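# plmvep

Variant effect prediction with a protein language model scorer backend:

- **Missense LLR matrices** — per-position log-likelihood-ratio scores for
  all 20×L substitutions, computed in a single scoring pass.
- **Sliding-window tiling** — proteins longer than the backend limit
  (1,022 residues) are tiled into fixed-length windows with ≥ 511-residue
  overlap (≤ 3 windows per residue); per-window scores are combined by a
  sigmoid-edge-weighted average (plain mean/min/max also available).
- **In-frame indel scoring** — pseudo-log-likelihood ratios (PLLR) between
  mutated and wild-type sequences in vanilla, length-weighted and
  absolute-value modes, with a 1,022-residue context window (511 upstream
  residues) for over-length proteins.
- **Stop-gain scoring** — minimum missense LLR over the lost region, plus
  residues-lost baselines and the 50 bp nonsense-mediated-decay rule.
- **Isoform analysis** — scoring the same variant across alternative
  isoforms; isoform-sensitive calls (max > −7, min < −8, gap > 4) and
  high-variance flags (s.d. > 2).
- **VUS mixture decomposition** — two-component Gaussian EM fit of
  unlabeled score distributions, and a fixed-class mixture that freezes
  the labeled benign/pathogenic densities and estimates one mixing weight.
- **Evaluation statistics** — global and gene-average ROC-AUC, balanced
  PRC-AUC over repeated class-balanced downsamples, TPR at fixed FPR,
  permutation tests for method differences, bootstrap AUC s.d., nested
  (per-assay → per-gene → overall) Spearman summaries for deep
  mutational scanning data, and edit-distance / alignment-score baselines.

The whole pipeline runs without model weights through a deterministic
**synthetic backend**: seeded k-mer hashing produces log-normalized,
context-sensitive per-position amino-acid log-probabilities, with
optional planted low-tolerance "domain" regions (positional intervals or
content-based motifs that survive windowing and sequence edits). An
optional adapter (`plmvep.esm_adapter`, requires `torch` + `fair-esm`)
plugs a real transformer model behind the same contract.

## Command line

```bash
# reproducible synthetic fixture bundle (FASTA, variant/benchmark TSVs,
# isoform maps, junctions, DMS table, backend.json, manifest)
plmvep make-fixtures --seed 3 --out-dir fixtures/

# scoring (use --backend fixtures/backend.json to reuse planted domains)
plmvep score-missense --fasta fixtures/proteins.fasta --variants variants.tsv \
    --out scores.tsv --rejects rejects.tsv --seed 3
plmvep score-indel    --fasta fixtures/proteins.fasta --variants indels.tsv \
    --out indel_scores.tsv --mode vanilla
plmvep score-stopgain --fasta fixtures/proteins.fasta --variants stops.tsv \
    --out stop_scores.tsv

# isoform sensitivity scan
plmvep isoform-scan --fasta fixtures/isoforms.fasta \
    --map fixtures/isoform_map.tsv --junctions fixtures/junctions.tsv \
    --backend fixtures/backend.json --out profiles.tsv

# mixture decomposition of unlabeled scores
plmvep fit-vus-mixture --scores vus_scores.txt --out fit.json

# benchmark statistics (AUCs, balanced PRC, permutation test, DMS)
plmvep evaluate --benchmark fixtures/benchmark.tsv --dms fixtures/dms.tsv \
    --out report.json
```

Variant notation follows HGVS.p with one- or three-letter residue codes:
`p.Arg123Cys`, `R123C`, `p.Val600del`, `p.Lys10_Leu12delinsTrp`,
`p.Lys10_Thr11insAla`, `p.Gln25Ter`. Frameshifts are rejected as
unsupported.

## Layout

```
src/plmvep/
  backend.py     scorer contract + deterministic synthetic backend
  tiling.py      window tiling, sigmoid edge weights, score aggregation
  scoring.py     missense LLR, indel PLLR, stop-gain, NMD rule
  isoforms.py    cross-isoform profiles and sensitivity classification
  mixture.py     two-component GMM and fixed-class mixture fits
  evaluation.py  benchmark metrics, resampling statistics, baselines
  hgvs.py        variant-notation parsing/formatting
  io.py          FASTA/TSV/JSON readers and writers
  fixtures.py    seeded synthetic fixture bundles
  config.py      run configuration with published default constants
  cli.py         command-line interface
  esm_adapter.py optional real-model adapter (not used in tests)
```
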