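# termtte

Genome-wide transcription termination analysis from Term-seq 3′-end
coverage, built around the archaeal two-in-one termination model in which an
intrinsic terminator U-tract and a trans-acting termination factor
(aCPSF1/FttA) jointly set how completely each transcription unit (TU)
terminates.

Term-seq maps exposed RNA 3′ ends at single-nucleotide resolution. Read
counts drop sharply across the four nucleotides flanking a termination site
(TTS): the *TTS quadruplet* −2, −1, +1, +2 (the TTS is −1; there is no
position 0). `termtte` takes strand-specific per-base 3′-end count tracks
(bedGraph), a genome (FASTA) and a gene annotation (GFF3), and computes:

* **TTS calls** — within 200 nt downstream of each stop codon, positions
  where the −1/+1 read ratio exceeds 1.1 and the read difference exceeds 5,
  required in both replicates; the strongest site per TU is its primary TTS.
* **Termination efficacy** — `TTE = 1 − reads[+2]/reads[−2]`, grouped
  high (> 60 %), medium (30–60 %), low (< 30 %).
* **Factor dependency** — with a factor-depletion condition,
  `TQRR = (WT[+2]/WT[−2]) / (dep[+2]/dep[−2])`; TQRR < 1 means termination
  of that TU depends on the factor (classes: highly ≤ 0.6, moderately
  0.6–1, non ≥ 1).
* **Terminator U4-tracts** — maximal runs of ≥ 4 uridines in the RNA-sense
  window −31..−1 of each primary TTS, grouped 0/1/2/>2, plus a −30..+5
  position-frequency/information matrix for sequence logos.
* **Group statistics** — Spearman correlation of U4-tract number with TTE,
  pairwise Wilcoxon rank-sum tests (exact by enumeration for small samples),
  per-group medians/quartiles, and the fraction of TUs with TQRR < 1.

A synthetic Term-seq generator (`termtte.synthetic_data`) plants terminators
with known U4-tract counts, efficacies and depletion sensitivities into a
simulated genome and draws Poisson 3′-end counts, so the entire pipeline is
testable — with exact truth tables — without any external data.

## Worked example

Simulate a dataset and run the full pipeline from Python:

```python
from termtte.pipeline import RunConfig, run_full

summary = run_full(RunConfig({
    "sim": {"n_tus": 200, "depth_lambda": 500.0, "seed": 1},
    "outdir": "out", "seed": 1,
}))
sp = summary["stats"]["spearman_u4_tte"]
print(f"rho = {sp['rho']:.3f}  ({sp['p_text']})")
print(f"fraction TQRR<1 = {summary['stats']['fraction_tqrr_lt1']:.3f}")
print(f"recall = {summary['recovery']['recall']:.3f}")
```

prints

```
rho = 0.784  (< 2.2e-16)
fraction TQRR<1 = 0.990
recall = 1.000
```

meaning: across 200 simulated TUs the number of terminator U4-tracts
correlates positively with estimated TTE (Spearman ρ = 0.78), 99 % of TUs
show factor-dependent termination (readthrough increases on depletion), and
every planted TTS was recovered at the exact nucleotide. `out/` contains
`tts.tsv`, `metrics.tsv`, `contexts.tsv`, `motif.json`, `summary.json` and
`recovery.json`.

The same stages run from the shell on real files:

```sh
termtte call-tts --genome g.fa --gff a.gff3 \
    --wt-plus WT_rep1_plus.bedgraph WT_rep2_plus.bedgraph \
    --wt-minus WT_rep1_minus.bedgraph WT_rep2_minus.bedgraph \
    --dep-plus dep_rep1_plus.bedgraph dep_rep2_plus.bedgraph \
    --dep-minus dep_rep1_minus.bedgraph dep_rep2_minus.bedgraph \
    --out tts.tsv
termtte quantify --tts tts.tsv --out metrics.tsv
termtte motif --genome g.fa --tts tts.tsv --out contexts.tsv --matrix motif.json
termtte stats --metrics metrics.tsv --out stats.json
```

`termtte simulate`, `termtte evaluate` and `termtte run` cover simulation,
truth-table scoring and the one-shot pipeline.

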