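# p53lcm

Latent class analysis of multiple fallible categorical tests — no gold
standard required — built around the p53 codon 72 genotyping problem.

## The problem

The codon 72 polymorphism of *p53* (rs1042522) has three genotypes
(Arg/Arg, Arg/Pro, Pro/Pro) and can be typed by several laboratory
methods — DHPLC, dot-blot hybridization (DBH), and two RFLP digests
(RFLP-1, RFLP-2) — that disagree for roughly 10% of samples.  None of
them is error-free, so empirical estimates of the association between
genotype and cervical cytology outcome (squamous intraepithelial
lesions, SIL) are biased, and different methods give different odds
ratios.  This package estimates each method's accuracy and a
misclassification-corrected genotype–disease association *without*
assuming any method is a reference standard.

## The model

A subject's true genotype is a latent class `X ∈ {1..C}` with
prevalences `π_c`.  Test `t` reports category `r` with classification
probability `θ_t[r|c] = P(test t calls r | X = c)`, conditionally
independent across tests given `X` (the Hui–Walter paradigm, which
identifies the model when `T ≥ 3`).  A subject with calls `r_1..r_T`
(missing slots skipped) contributes

```
L = Σ_c π_c · Π_t θ_t[r_t | c]
```

to the likelihood, maximized by EM with random restarts.  The
outcome-augmented model adds a per-class Bernoulli outcome risk `ρ_c`
(two-year cumulative SIL risk) inside the class sum, giving corrected
odds ratios `OR_c = [ρ_c/(1−ρ_c)] / [ρ_ref/(1−ρ_ref)]` against the
Pro/Pro reference.  Extensions: equal-accuracy constraint, accuracy
stratified by outcome, and a log-linear within-class agreement term for
flagged test pairs, all compared by likelihood ratio tests.  Pairwise
crude agreement and Cicchetti–Allison weighted kappas cover the
descriptive side.

The study's joint 4-way table was never published — only the six
pairwise cross-tabulations.  `p53lcm.fixtures` ships a subject-level
panel reconstructed once by integer programming to match every
published pairwise margin exactly (synthetic completion: agreement and
empirical analyses on it are exact; latent-class fits on it
characterize the reconstruction, not the original fit).

## Worked example

```python
from p53lcm import load_study_panel, crosstab_pair, cohen_kappa
from p53lcm import LcmSpec, fit_lcm_outcome

panel = load_study_panel()                      # 911 women, 4 tests + cytology
res = cohen_kappa(crosstab_pair(panel, "DHPLC", "DBH")[0])
print(round(res.crude, 3), round(res.kappa, 2), round(res.kappa_weighted, 2))
# 0.955 0.93 0.92   -> 95.5% crude agreement, kappa 0.93, weighted kappa 0.92

fit = fit_lcm_outcome(panel, LcmSpec(3, panel.test_names), ref_class=3)
for c, label in enumerate(panel.category_labels):
    print(label, round(fit.rho[c], 3), round(fit.odds_ratios[c + 1].odds_ratio, 2))
# Arg/Arg 0.089 1.86
# Arg/Pro 0.054 1.08
# Pro/Pro 0.05 1.0
```

The last three lines are the per-genotype two-year SIL risks and the
error-corrected odds ratios: Arg/Arg women carry the highest risk
(OR 1.86 vs Pro/Pro on the reconstructed panel), while Arg/Pro is only
marginally elevated — one corrected estimate in place of four
conflicting empirical ones (which range from 1.95 to 2.43 for Arg/Arg).

The numbered scripts under `analysis/` walk the full study: panel
reconstruction, agreement, empirical association, latent-class
accuracy, corrected risk, and robustness (equal accuracy, conditional
dependence with a Bonferroni screen, outcome-stratified accuracy,
two-category regrouping).  Each writes its tables under `results/`.

A CLI mirrors the same stages:

```sh
p53lcm agree --fixture
p53lcm simulate --n 1000 --seed 1 --out sim.csv
p53lcm fit-lcm --data sim.csv --out fit.json
```

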