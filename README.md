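# unipseudo

Genome-wide discovery of unitary pseudogenes (gene losses) from a reference
proteome and one or more query genome assemblies, with a synthetic-genome
benchmark generator for end-to-end validation.

The pipeline mirrors the classic comparative-genomics screen:

1. **map** — seeded translated search locates candidate orthologous loci for
   each reference protein (dual evidence: empirical E-value ≤ 1e-3 AND a
   colinear hit chain), extracted with 5,000 bp flanks.
2. **align** — a frameshift- and intron-aware protein-to-genome dynamic
   programme (codon match / codon indel / 1–2 nt frameshift / intron with
   canonical GT..AG bonus / penalised stop traversal).
3. **call** — ORF disruptions (premature stops, frame-breaking indels) are
   extracted and loci classified putative-pseudogenic / intact / unalignable.
4. **filter** — the unitary-status cascade (gene-family exclusion,
   predicted/intronless annotation, functional redundancy from copy chains
   covering ≥ 80% of the protein, conserved genomic position) followed by
   false-positive removal (terminal disruptions with > 90% intact protein,
   exon-boundary-adjacent or low-identity windows (< 40% over ±30 bp), read
   support, TSL/CCDS annotation support, compensatory frameshift pairs).
   Every decision is logged to a per-gene filter trail.
5. **relax** — per-gene codon alignments (masked Gblocks-style: gap columns
   + 6 bp flanks, low-conservation windows, ≥ 150 bp survivor length),
   foreground/background dN/dS by ancestral parsimony + Nei–Gojobori
   counting, selection intensity k = ln ω_fg / ln ω_bg, retention gate
   ω_fg > ω_bg and k < 1 (bootstrap p is advisory).
6. **stats** — convergent-loss overlap (hypergeometric), species-pair Fisher
   comparisons, keyword-driven GO functional-group enrichment with BH-FDR,
   and conserved-gene-set false-positive validation.

The `simulate` module builds reference + query genomes with planted losses,
duplicated/retro copies, assembly-error sites with low read support,
compensatory frameshift pairs, and codon sequences evolved under a
Muse–Gaut-style process with a selection-intensity parameter — all with a
machine-readable truth table.

## CLI

```sh
# generate a synthetic bundle (reference, query, control, truth, config)
unipseudo simulate --outdir demo --seed 7 --n-genes 60

# run the whole pipeline (or any prefix: map | call | filter | relax)
unipseudo run-all --config demo/pipeline.cfg --outdir demo/run

# overlap stats between final call lists
unipseudo stats --universe 16000 runA/final_calls.tsv runB/final_calls.tsv
```

Exit codes: 0 ok, 2 configuration error, 3 data error.  The run directory
contains `loci.tsv`, `alignments.tsv`, `disruptions.tsv`,
`cascade_report.tsv` (per-stage counts), `filter_trail.tsv`, `relax.tsv`
and `final_calls.tsv`.

Configuration is a flat `key = value` file; unknown keys are rejected.  All
thresholds (flank, E-value, copy coverage, truncation, identity window,
masking, k threshold, FDR alpha, …) are exposed with contract defaults; see
`unipseudo/pipeline/config.py`.

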