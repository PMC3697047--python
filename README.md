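# tetractivity

Weighted degenerate-tetranucleotide sequence–activity modelling for
small RNAs: a library and CLI for finding and applying quantitative
sequence–activity relationships (QSAR) between mature miRNA sequences
and per-sequence activities such as cellular abundance or
Argonaute-binding affinity.

## Who this is for

Researchers asking "which short degenerate motif, weighted by where it
sits in the molecule, predicts this measured property?" for sets of
fixed-length RNA fragments — e.g. miRNA abundance in a tissue, or the
preference of a miRNA for loading into Ago2 versus Ago3.

## The model

The feature of a degenerate tetranucleotide `z1z2z3z4` (IUPAC codes,
15 per position, 15⁴ = 50 625 patterns) under a position-weight profile
F in a fragment ξ₁…ξ_L is

    [z1z2z3z4]_F = Σ_{i=1..L−3}  1[ξᵢξᵢ₊₁ξᵢ₊₂ξᵢ₊₃ ∈ z1z2z3z4] · F(i),

with 0 ≤ F(i) ≤ 1: every matching window contributes its positional
weight. A built-in library of 360 profiles (180 S-shaped logistic
ramps, 180 U-shaped Gaussian peaks/valleys) gives 360 × 15⁴ =
18 225 000 candidate features.

Each candidate is scored against the activity X by the **Ξ score**: in
7 data subsets (all records, and the ⌈n/2⌉ with the lowest/highest/
mean-nearest feature and activity values), 11 statistical criteria are
evaluated — Pearson, Spearman, Kendall, chi-square and Fisher exact on
the median-split table, plus six regression-applicability diagnostics
(uniformity of both variables, normality and independence of both
directed regressions' residuals). Each significance level α maps to a
utility υ(α) ∈ [−1, 1] with υ(0.05) = 0, and

    Ξ = (1/77) Σ υ(α_kq).

The winner (highest Ξ > 0) is challenged by a permutation test:
activities are reshuffled and the search repeated; recurrence of the
winning feature (or any ≥ 0.8-correlated one) across 100 cycles is
judged by the binomial law at p = 0.05.

The package also ships the published constant models built on such
features: plant miRNA abundance from [WRHW]_F1 and [DRYD]_F2; human
Ago2/Ago3 ln-affinities from [RHHK]_F3 and [YRHB]_F4 (with the Σ/Δ
half-sum/half-difference decomposition); the inverse-problem reduction
to HEK293T abundance under normal growth and actinomycin-D arrest
(availability heuristic κ·X₂ − X₃ plus parameter-free range
calibration); and the limiting-stage estimator
exp(min(Ago2, Ago3 linear forms)).

## Worked example

Library use, on the packaged training tables:

```python
>>> from tetractivity import load_table1, sigma_delta, predict_arabidopsis, limiting_stage
>>> from tetractivity.stats import pearson
>>> t1 = load_table1()                       # 17 Arabidopsis miRNAs, 20-nt fragments
>>> r = pearson(t1.annotations["wrhw_f1"], t1.activity)
>>> round(r.statistic, 2), round(r.alpha, 4)
(0.67, 0.0033)
>>> sigma_delta(7.81, 4.85)                  # Ago2/Ago3 ln-affinities -> (Σ, Δ)
(6.33, 1.48)
>>> round(predict_arabidopsis(0.97, 2.08), 4)   # ln-abundance from feature values
3.6315
>>> round(limiting_stage(2.37, 0.50), 4)     # limiting-stage abundance estimate
1.7907
```

The Pearson r of 0.67 (α ≈ 0.003) is the training correlation between
the centre-weighted WRHW feature and ln-abundance; Δ = 1.48 > 0 marks a
strong Ago2-preferring miRNA; 3.63 is its predicted ln-abundance from
the two feature values.

End to end with the CLI — plant a signal, then let the engine find and
verify it (the search below screens 4.6 M variants and runs 60
permutation cycles; allow a few minutes):

```bash
$ tetractivity simulate --n 24 --len 22 --tetra RHHK \
    --profile U:peak:c=0.5:w=0.2:floor=0 --slope 2 --noise 0.4 --seed 7 --out sim
wrote dataset of 24 records to sim
$ tetractivity search --tsv sim/activity.tsv --top-k 20 --profile-stride 4 \
    --seed 1 --out ranked.tsv --permute-cycles 60
screening 4556250 variants ...
best: [RHHK]_U:peak:c=0.5:w=0.2:floor=0.0 Xi=0.1646
permutation: 0/60 recurrences, alpha=0.04607, verified
```

The engine recovers exactly the planted pattern and profile
(full-dataset r = 0.98), and the permutation test confirms the finding
does not recur once the sequence–activity pairing is destroyed.

## Layout

| module | contents |
| --- | --- |
| `alphabet` | IUPAC RNA codes, degenerate tetranucleotides, matching |
| `sequences` | records, datasets, Σ/Δ, FASTA/TSV I/O |
| `tables` | the two packaged training tables |
| `profiles` | the 360-profile position-weight library |
| `features` | the weighted-abundance feature and batch matrices |
| `stats` | the 11 per-subset statistical criteria |
| `engine` | subsets, υ/Ξ scoring, search, permutation verification |
| `models` | published constant models + OLS fitting |
| `inverse` | availability heuristic, range calibration, condition models |
| `cluster` | two-cluster single-linkage control analysis |
| `simulate` | planted-signal synthetic data generator |

See `docs/methods.md` for the modelling choices and their rationale.
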