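# nsslink

Bipartite link prediction with structural negative sample selection and
biased matrix factorization.

Supervised link prediction on bipartite networks usually has no ground
truth for *absent* links: an unobserved pair may simply be an interaction
nobody has recorded yet. Training matrix factorization with every
unobserved pair as a negative sample therefore teaches the model to
suppress exactly the links one wants to find. `nsslink` mitigates this in
two stages:

1. **Negative sample selection.** All maximal bi-cliques of the observed
   network are enumerated as formal concepts by a canonical depth-first
   search. Pairs of comparable concepts whose component sizes (≥ `alpha`)
   and overlap rates (≥ `rho`) are non-trivial delimit *structural holes* —
   unlinked node pairs that are likely future links. Hole pairs are marked
   as unsafe, and negative training samples are drawn uniformly from the
   remaining unobserved pairs at a configurable `sample_rate`.
2. **Biased MF.** A factor model with per-node biases and a global mean is
   trained by per-sample SGD on the observed links (label 1) plus the
   selected negatives (label 0); every remaining unobserved pair receives a
   confidence score `mu + b_i + b_j + p_i·q_j`.

The package also ships the unsupervised comparators (common neighbors,
Jaccard, Adamic–Adar, preferential attachment, random walk with restart),
rank-based AUC / average-precision AUPR evaluation, and a seeded generator
of planted-bi-clique benchmarks so the whole pipeline runs with no
external data.

## Command line

```sh
# generate a planted benchmark (target + input edge lists + manifest)
nsslink simulate --n-left 60 --n-right 80 --n-blocks 6 \
    --hole-link-fraction 1.0 --seed 1 --out-dir sim/

# enumerate maximal bi-cliques
nsslink enumerate sim/input.tsv --out concepts.txt

# pick negative training samples (fca = structural marking, random = none)
nsslink select-negatives sim/input.tsv --alpha 2 --rho 0.25 \
    --sample-rate 0.5 --selection fca --out negatives.tsv

# score unobserved pairs (methods: mf-nss, mf, cn, jc, aa, pa, rwr);
# --nodes-from adds nodes that have no observed links in the input
nsslink predict sim/input.tsv --method mf-nss --rho 0.25 \
    --nodes-from sim/target.tsv --out pred.tsv --manifest manifest.json

# AUC / AUPR against the labeled target network
nsslink evaluate --predictions pred.tsv --input sim/input.tsv \
    --target sim/target.tsv --out metrics.json

# sample-rate grid over selection modes
nsslink benchmark --rates 0.2,0.5,0.8 --seeds 5 \
    --selection fca --selection random --selection none --out bench.tsv
```

Input formats: 2- or 3-column TSV edge lists (third column 1/0 for
present/absent), Burmeister `.cxt` formal contexts, and dense 0/1
bi-adjacency CSV. Exit codes: 0 success, 2 usage, 3 data error, 4 numeric
failure.

## Library

```python
from nsslink import (
    NSSParams, MFParams, read_edgelist, mask_positives,
    marked_pairs_for_network, select_negatives, build_training_set,
    train, score_all_unobserved, evaluate_scores,
)

net = read_edgelist("input.tsv")
nss = NSSParams(alpha=2, rho=0.25, sample_rate=0.5, seed=0)
marked = marked_pairs_for_network(net, nss)          # unsafe pairs
negatives = select_negatives(net, marked, nss)       # label-0 samples
model = train(build_training_set(net, negatives), MFParams(seed=0))
scores = dict(score_all_unobserved(model, net))
```

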