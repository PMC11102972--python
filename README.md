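# cdloop

Chromatin loop calling from Hi-C contact maps with a prior-conditioned
classification diffusion model and density-peaks clustering.

Chromatin loops appear in a Hi-C contact matrix as focal enrichments
("dots") at bin pairs whose genomic anchors are held together in space.
`cdloop` scores every candidate bin pair `(i, j)` in the 30 kb – 3 Mb band
by: (1) a LeNet5-style classifier on the 28×28 window around the pair,
whose softmax output `f(x)` is a *prior*; (2) a classification diffusion
model whose forward process ends at `N(f(x), I)` instead of `N(0, I)` —

    q(y_t | y0, f) = N( √ᾱ_t·y0 + (1−√ᾱ_t)·f, (1−ᾱ_t)·I )

— and whose learned reverse chain is run repeatedly to give a loop score
`s(i, j)` with a 95% CI and a t-test against 0.5; and (3) density-peaks
clustering of the score field (local density ρ within Chebyshev radius 2,
separation δ to the nearest denser candidate), keeping peaks with δ ≥ 5
as the final loops.  A synthetic Hi-C generator with planted loops makes
the whole pipeline trainable and testable on one CPU without downloads.

The package is aimed at people working on 3-D genome structure who want a
self-contained, fully reproducible implementation of diffusion-based loop
calling: every stage (simulate → build samples → train prior → train
diffusion → call → evaluate) is a library function and a CLI subcommand.

## Worked example

Run the full desk-scale pipeline — a 1200-bin synthetic chromosome at 5 kb
with 60 planted loops of amplitude 8 — then evaluate against the planted
truth (about 4 minutes on one CPU):

```sh
cdloop -v run --out runs/demo --seed 1
```

which logs, stage by stage:

```
simulate: 1200 bins, 60 planted loops
build: 404 positive pixels, 0 all-zero negatives dropped
build: 3151 samples after augmentation (1616 positive / 1535 negative)
train-prior: final train acc 0.986
train-diff: final eps-MSE 0.1649
call: prefiltered: 10345
call: scored: 10345
call: score_cutoff: 886
call: non_isolated: 141
call: final: 30
evaluate: precision 1.000 recall 0.500 f1 0.667
```

Reading the numbers: 10,345 bin pairs pass the prefilters (distance band,
interaction frequency ≥ 1, < 200 zero window entries); 886 score above 0.5;
141 survive the isolated-prediction filter (≥ 15 candidates in their 5×5
square); density-peaks clustering reduces these blobs to 30 loops, every
one within ±1 bin of a planted loop (precision 1.0) and covering half of
the 60 planted loops (recall 0.5, F1 0.667).  `runs/demo/loops.bedpe` holds
the calls with scores; `loops_stats.tsv` adds CI, t-test p, ρ and δ per
loop; `report.json` holds the evaluation.

Individual stages are also exposed, e.g.

```sh
cdloop simulate --out runs/sim --seed 3
cdloop call --cool matrix.cool --chrom chr15 --prior prior.npz --eps eps.npz \
            --out chr15_loops --min-dist 30000 --max-dist 3000000 --draws 10
cdloop evaluate --pred chr15_loops.bedpe --ref ctcf_chiapet.bedpe --tol 5000
cdloop apa --cool matrix.cool --chrom chr15 --loops chr15_loops.bedpe
```

Contact matrices may be single-resolution `.cool` files, 3-column sparse
text (`bin_i bin_j count`) or dense text.

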