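# dedumi

Probabilistic UMI deduplication and molecular abundance estimation for
amplicon sequencing.

Amplicon experiments (viral quasispecies, microbial communities, immune
repertoires, engineered barcodes) tag each sample molecule with a unique
molecular identifier (UMI) before PCR so that amplification duplicates can
be recognized and pre-PCR molecular counts recovered. Naive counting by UMI
identity is distorted in two directions: PCR and sequencing errors in the
UMI or the sample sequence inflate the number of apparent molecules and
variants, while *UMI collisions* — two distinct molecules receiving the
same tag — hide molecules and undercount. `dedumi` is for researchers who
need accurate haplotype calls **and** accurate deduplicated (molecular)
abundances from UMI-tagged single-end amplicon reads, including when
collisions occur between highly similar sequences.

## Model

Read *i* is an observed UMI `b_i` plus sample sequence `r_i`, modeled as an
independent draw from a one-step hidden Markov chain over a pool of `N`
candidate true UMIs `U = {u_1..u_N}` and `K` candidate haplotypes
`H = {h_1..h_K}`: a true UMI `u_s` is drawn with mixing proportion `η_s`, a
haplotype `h_k` attaches with transition probability `γ_sk`, and both
sequences are emitted with sequencing error. The observed log likelihood

```
ℓ(θ) = Σ_i log Σ_{s,k} η_s · Pr(b_i | u_s) · γ_sk · Pr(r_i | h_k)
```

is maximized by EM after subtracting the sparsity penalty
`ρ · Σ_{s,k} log(1 + γ_sk/ω)` with `ω = 1e-20`, which acts like an ℓ0
penalty: the transition for molecule `(u_s, h_k)` survives only when its
expected amplified read count exceeds roughly `ρ`. A UMI with two surviving
transitions is a detected collision. Emissions follow a quality-aware error
model: per-base substitution probabilities conditioned on PHRED scores
(estimated from UMI-defined read clusters, with a PHRED-consistent default)
and a truncated-Poisson number of indel events along the read/candidate
alignment (UMIs are treated as indel-free).

The deduplicated abundance of haplotype `h_k` is
`Σ_s 1{n·η̂_s ≥ 1} · 1{γ̂_sk > 0}` — the number of retained UMIs that link
to it, i.e. the pre-PCR molecule count. With `--ncollision`, each UMI is
instead assigned to its single best haplotype (`argmax_k γ̂_sk`).

The penalty weight ρ is selected automatically: observed candidate-UMI
abundances are fit with a Galton–Watson branching process (per-cycle
duplication efficiency λ, binomial read-sampling, error escape) by
Kolmogorov–Smirnov minimization, and ρ is the 5th percentile of the fitted
count distribution given detection. `--rho` overrides manually.

The package ships a faithful simulator of the assumed data-generating
process (power-law haplotype abundances, multinomial molecule sampling,
optional UMI collision by resampling tags with replacement, per-cycle PCR
substitutions, quality-driven sequencing noise) with complete truth tables,
plus the evaluation metrics (Jaccard, Ruzicka, precision/recall,
homogeneity/completeness, random-bipartition consistency) and a naive
UMI-identity consensus baseline.

## Worked example

Simulate a collision-prone dataset and fit it:

```bash
$ dedumi simulate --preset sim3 --n-reads 5000 --seed 42 --out-dir sim
wrote 5000 reads and truth tables to sim

$ dedumi fit --umi-length 9 --seed 42 --out-dir fit sim/reads.fastq
33 haplotypes, 372 molecules, rho=3.0 -> fit

$ dedumi evaluate --truth-haplotypes sim/truth_haplotypes.tsv \
    --out-dir eval fit/haplotypes.fasta
{
  "jaccard": 0.6363636363636364,
  "ruzicka": 0.8737864077669902,
  "precision": 0.6363636363636364,
  "recall": 1.0,
  "n_estimated": 33,
  "n_true": 21
}
```

The fit auto-selected `ρ = 3` from the UMI abundance distribution, retained
253 true UMIs (400 molecules were tagged with collisions, so only 253
distinct tags exist) and recovered every one of the 21 sampled haplotypes
(recall 1.0) with 372 deduplicated molecules; the abundance-weighted
agreement with truth (Ruzicka) is 0.87. The extra called haplotypes are
strongly amplified early-cycle PCR errors — molecules whose expected counts
genuinely exceed ρ. `fit/haplotypes.fasta` carries the deduplicated
abundance of each haplotype in its header (`>H1;size=36`), and
`fit/assignments.tsv` lists each retained UMI's haplotype links with
expected amplified counts and transition weights; `fit/fit_summary.json`
records iterations, convergence, the penalized log likelihood and the
detected collisions.

The same pipeline is available in Python:

```python
from dedumi import load_fastq, run_pipeline

reads = load_fastq("sim/reads.fastq", umi_length=9)
res = run_pipeline(reads, seed=42)          # rho auto-selected
print(res.rho, res.abundance_profile())     # haplotype -> molecule count
```

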