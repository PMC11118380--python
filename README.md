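# phdecon

Tools for dissecting how an environmental signal (acidic pH) reshapes a
stimulus-driven transcriptional program, plus a proteome-wide screen for the
protein feature that can mediate such pH sensing.

The package has three analysis stages and a synthetic-data generator that
provides planted ground truth for all of them:

- **`phdecon.simulate`** — synthetic four-condition
  (`pH74`, `pH74_LPS`, `pH65`, `pH65_LPS`) count matrices with planted
  (LPS, pH, INT) log2 components and multiplicative noise, and synthetic
  proteomes with planted histidine clusters in proline/glutamine-rich
  disordered context (with a per-residue disorder-score sidecar).
- **`phdecon.deconvolution`** — per-gene linear deconvolution of the five
  pairwise condition contrasts (`Y = X @ beta + eps`, `beta = (LPS, pH, INT)`),
  one-sided t-tests against a shifted null (effects within 1.5-fold are null),
  and classification into 20 regulatory-logic groups and merged categories
  (`pH_insensitive`, `pH_antagonistic`, `pH_synergistic`, `pH_only`, ...).
  Includes sample normalization to 10 million counts and a
  fold-change/BH-adjusted-p/mean-expression prefilter.
- **`phdecon.screen`** — histidine delta-charge profiling with a truncated
  unit-peak Gaussian kernel (FWHM 5, span 20, sigma 2.12), strict `> 1` peak
  calling, 50-residue flank extension, per-side disorder gating (`> 0.3`),
  P/Q-enrichment scoring, and residue arithmetic (H runs, H→A mutagenesis,
  net charge, amino-acid composition enrichment).
- **`phdecon.io` / `phdecon.cli`** — TSV/FASTA/JSON readers and writers and
  the `phdecon` command-line interface.

## CLI

```sh
# synthetic inputs with planted truth
phdecon simulate expression --n-genes 5000 --noise-sd 0.25 --seed 1 --out sim/
phdecon simulate proteome --n-proteins 100 --seed 1 --out prot/

# expression deconvolution (results.tsv + summary.json)
phdecon deconvolve --counts sim/counts.tsv --design sim/design.tsv \
    --pseudocount 2 --beta0 1.5 --beta-min 2 --p-max 0.05 --r2-min 0.8 \
    --out decon/

# proteome screen (candidates.tsv + summary.json)
phdecon screen --fasta prot/proteome.fasta --disorder prot/disorder.tsv \
    --fwhm 5 --span 20 --charge-min 1 --flank 50 --disorder-min 0.3 \
    --out screen/
```

Every run writes its resolved configuration, seed and input hashes so it can
be reproduced exactly.  A YAML config file can be passed with `--config`;
precedence is CLI flag > config file > built-in default.  Exit codes: 0
success, 2 validation error, 1 internal error.

## Conventions

- log2 scale throughout; fold changes use a pseudocount of 2.
- Residue coordinates are 1-based inclusive.
- The smoothing kernel has unit peak amplitude, so the delta-charge profile
  reads in histidine-equivalents and the strict `> 1` peak threshold means
  "more than one histidine's worth of charge in a ~20-residue window".
- The 20-group regulatory-logic table is shipped as versioned package data
  (`phdecon/data/group_table.tsv`); the merged categories are the primary
  output.
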