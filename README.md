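# onebitmc

One-bit matrix completion for bipartite association prediction.

Curated biological association resources — microbe–disease, drug–target,
gene–disease — record which pairs have been validated, not how strongly
every pair interacts. `onebitmc` treats such a table as a p×q matrix **A**
with entries +1 (association), −1 (observed non-association) or unknown,
models it as a one-bit observation of a low-rank latent matrix **X**
through a probit link,

    P(a_ij = +1) = Φ(x_ij / σ),        a_ij = sign(x_ij + z_ij),  z_ij ~ N(0, σ²),

and recovers **X** by maximizing the probit log-likelihood

    F(X) = Σ_{(i,j)∈Ω} log Φ(a_ij x_ij / σ)    s.t.   ‖X‖* ≤ √(r·p·q)

over the observed set Ω with a nonmonotone spectral projected gradient
method; the projection onto the nuclear-norm ball is exact singular-value
soft-thresholding. The recovered x̂_ij rank candidate pairs for follow-up.
The package is aimed at computational biologists screening large
microbe–disease (or similar bipartite) pair spaces, and ships the full
evaluation protocol around the estimator: LOOCV and k-fold CV, standalone
AUC/AUPR, (σ, rank) grid tuning, a truncated-SVD baseline, and a synthetic
generator matching the model's assumptions. See `docs/methods.md` for the
model, solver and protocol details.

## Worked example

```sh
# 1. simulate a 60x30 association matrix (rank 3, sigma 0.2, 80% observed)
onebitmc simulate --p 60 --q 30 --rank 3 --noise-sigma 0.2 \
    --obs-frac 0.8 --seed 1 --out matrix.tsv

# 2. recover latent scores and rank the top candidate pairs
onebitmc fit --input matrix.tsv --format dense --sigma 0.2 --r 3 \
    --top-k 5 --output scores.tsv

# 3. cross-validated evaluation (5-fold over all observed entries)
onebitmc cv --input matrix.tsv --format dense --sigma 0.2 --r 3 \
    --scheme kfold --k 5 --seed 1 --blind-set all_observed \
    --metrics metrics.json
```

`scores.tsv` after step 2:

```
microbe_id	disease_id	score	observed
m53	d12	1.0772	1
m7	d17	1.05502	1
m57	d6	1.05015	1
m8	d22	0.966905	1
m25	d22	0.966446	1
```

and `metrics.json` after step 3 contains

```json
"auc": 0.879032415258367,
"aupr": 0.8873947695554718,
```

AUC is the probability that a random true association outranks a random
non-association; AUPR is the area under the precision–recall curve, the
stricter summary when positives are rare. Both are computed from the
pooled cross-validated scores, with per-fold means reported alongside.

The same steps work on real data: a TSV pair list with header
`microbe_id  disease_id  [label]` (`--format list`), with unlisted pairs
treated as observed negatives (`--unknown-as negative`, the link-prediction
convention) or as unknown. `onebitmc tune` grid-searches (σ, r) by
cross-validated AUPR, and `--method svd` swaps in the truncated-SVD
imputation baseline everywhere.

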