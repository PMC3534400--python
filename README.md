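# hurdlecall

Probabilistic homopolymer base-calling for flow-cycle pyrosequencing
(454-style), built on a weighted Hurdle Poisson additive model.

## The problem

In flow-cycle sequencing the four nucleotide solutions are flowed over the
plate in a fixed order; a flow incorporates `n` identical nucleotides — the
homopolymer length (HPL), with `n = 0` when the flowed base does not match
the template.  Base-calling is the classification of each flow's signals
into an HPL.  Two features dominate the data: an excess of zero flows
(roughly half of all flows miss), and strong *underdispersion* of the
positive counts given the signals.  Because the signal increase per
incorporated base attenuates at long homopolymers, insertion and deletion
errors (overcalls and undercalls) rise sharply with HPL — the
characteristic error mode of this technology.  Conventional pipelines round
preprocessed flowgram values and assign quality scores afterwards, so the
score says nothing about whether an undercall or an overcall is the likelier
error.

## The model

For nucleotide `b` in cycle `c`, the count `N_bc` follows a hurdle mixture

    Pr{N = 0} = 1 - pi
    Pr{N = n} = pi * f_ZTWP(n; lambda, theta),   n >= 1

where `f_ZTWP` is a zero-truncated *weighted* Poisson density with
exponential distance weights `w_n = exp(-theta (lambda - n)^2)`; `theta > 0`
shrinks the variance below the mean (underdispersion), and `theta = 0`
recovers the zero-truncated Poisson.  Both per-flow parameters are additive
models of flow-level covariates (current flowgram value, log2 raw intensity
with read-specific normalization, cumulative signal sums, and flowgram
values 1/4/8 flows away):

    logit(pi)   = beta_0  + sum_j f_j(x_j)
    log(lambda) = gamma_0 + sum_j g_j(y_j)

with centered cubic B-spline smooths fitted by penalized IRLS; the global
`theta` is estimated by profile likelihood.  The call for a flow is the HPL
with maximal estimated probability, and the same probability vector yields
quality scores:

    QS_overcall(k)  = -10 log10 P(HPL < k)
    QS_undercall(k) = -10 log10 P(HPL > k)
    QS_signed(k)    = I_dir * round(min(QS_undercall, QS_overcall))

with `I_dir = -1` when an undercall is the likelier error.  Per-base Phred
scores carry `QS_overcall` trimmed to 0..40 and are emitted as FASTQ; the
signed scores go to a TSV sidecar.

## Worked example

The signed score distinguishes error directions where a plain Phred score
cannot.  Consider a flow whose estimated HPL distribution puts 0.83 on
HPL 4, 0.17 on HPL 5 and 7.4e-9 on HPL 3 (an undercall-prone AAAA call):

```python
>>> import numpy as np
>>> from hurdlecall import quality
>>> probs = np.array([1e-15, 1e-15, 1e-15, 7.4e-9, 0.83, 0.17, 6.3e-11])
>>> [quality.qs_signed(probs, k) for k in range(2, 7)]
[0, 0, -8, 1, 0]
```

The fourth base scores **-8**: the magnitude is Phred-like
(`-10 log10 0.17 ≈ 7.7`), and the negative sign says a *fifth* base is the
likely correction — an undercall.  An overcall-prone flow (0.29 on HPL 2,
0.71 on HPL 3) instead gives `+5` at its top base, and a zero call with
0.25 residual mass at one base gives `-6` at the no-base position.

The full pipeline runs from the shell:

```bash
hurdlecall simulate --reads 1000 --seed 7 --out scratch/run
hurdlecall train    --flows scratch/run.flows.tsv --model-out scratch/model.json
hurdlecall call     --flows scratch/run.flows.tsv --model scratch/model.json --out scratch/called
hurdlecall evaluate --flows scratch/run.flows.tsv --model scratch/model.json --out scratch/eval
```

`simulate` writes a flow table and truth FASTA (here: 122592 flows for
1000 reads); `train` prints the fitted summary —

    {'n_flows': 122592, 'n_reads': 1000, 'n_positive': 60267,
     'max_ref_hpl': 14, 'theta': 11.11302955198403}

(`theta` is large because the simulator's positive counts are nearly
determined by the flowgram: strong underdispersion); `call` emits
FASTA/FASTQ plus the probability matrix and signed-score sidecars; and
`evaluate` reports `overall error rate: 0.219%` for this self-evaluation
on the training reads, alongside error-by-HPL, calibration and
cumulative-score tables.

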