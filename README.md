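# pulsetree

Did a clade pass through a mass-extinction bottleneck that its fossil record
cannot show?  `pulsetree` implements the two complementary lines of evidence
used to ask that question for Madagascar's terrestrial vertebrates — and for
lemurs in particular — around the Eocene–Oligocene (E–O) boundary at 34 Ma:

1. **Fossil clade-table calculus.**  Comparing extinct and extant vertebrate
   families of Paleocene/Eocene continental Africa (2×2 exact tests,
   projection of unobservable early colonizers, an upper bound on end-Eocene
   disappearance) and tallying when Madagascar's Holocene clades arrived,
   with a constant arrival/extinction survival model as a null.
2. **Diversification modeling on time-calibrated phylogenies.**
   Birth–death likelihoods on a reconstructed ultrametric tree — constant,
   exponentially time-varying, environment-coupled (temperature or its rate
   of change), and *pulse* models in which a Normal-PDF covariate centred on
   a candidate age perturbs the extinction (or speciation) rate through an
   exponential link — compared by AICc and Akaike weights over a grid of
   candidate extinction times; plus a Bayesian profile that scores a single
   instantaneous mass-extinction event (per-lineage survival `s` with a Beta
   prior) by 2 ln Bayes factors from quadrature marginal likelihoods.

The package is written for phylogeneticists and paleobiologists: trees are
plain newick (ages in Ma, present = 0), covariates are two-column CSVs, and
every stage has a synthetic-data generator so the full pipeline runs without
any external downloads.

## The model

For branching times x₁ (crown) > x₂ ≥ … ≥ x₍ₙ₋₁₎ of a reconstructed tree
with sampling fraction ρ, writing E(t) for the probability that a lineage
alive at age t leaves no sampled descendant and q(t) = (1−E(t))² e^{−R(t)}/ρ
with R(t) = ∫₀ᵗ (λ−μ), the likelihood conditioned on the crown age and on
survival of both crown lineages is

    L = q(x₁)² / (1−E(x₁))² · ∏_{i≥2} λ(x_i) q(x_i),

with E solving dE/dt = μ(t) − (λ+μ)E + λE² backwards from E(0) = 1−ρ.
Pulse models set μ(t) = μ₀·exp(α·φ_c(t)) where φ_c is the Normal PDF with
mean c and sd 0.5 Myr (variance 0.25); a mass-extinction event at age t_e
instead thins every lineage by an independent Bernoulli survival s.  Model
support uses AICc = −2 logL + 2k + 2k(k+1)/(n−k−1), Akaike weights
w_i ∝ exp(−ΔAICc_i/2) (ΔAICc ≤ 4 indistinguishable, 4–10 moderate, > 10
strong), and 2 ln BF (> 2 moderate, > 6 strong).

## Worked example

`analysis/` holds the numbered pipeline.  On the packaged fossil tables and
a simulated 115-tip tree (crown 50 Ma, ρ = 0.74) carrying a 95%-kill event
at 34 Ma (`--seed 0` throughout):

```text
$ python analysis/01_fossil_record.py
African Paleocene/Eocene clades: 75 (50 extinct, 25 extant)
Known early colonizers of Madagascar: 11 (14.7% of all clades, 44% of extant clades)
Projected extinct early colonizers: 22 -> 33 total, so evidence of 22/33
  colonizing clades has been lost
Up to 52% of clades may have disappeared around the end of the Eocene (39 of 75)
Malagasy Holocene clades: 23 arrived before the E-O boundary, 48 after

$ python analysis/04_fit_diversification.py
constant-constant      k=2 logL= -316.083 AICc=  636.274
tv-lambda-constant     k=3 logL= -314.378 AICc=  634.972
constant-tv-mu         k=3 logL= -313.721 AICc=  633.659
tv-lambda-tv-mu        k=4 logL= -312.634 AICc=  633.631
max dAICc across the four models: 2.64 (indistinguishable)

$ python analysis/05_pulse_scan.py
best model: pulse_28; Akaike-weight mode over pulse ages: 28 Ma
null dAICc = 6.67 (moderate)
evidence ratio, best pulse (pulse_28) vs null: 28.1x
temperature: dAICc 2.64
temperature_roc: dAICc 2.92
pulse candidates within dAICc < 4 of the best model: 11

$ python analysis/06_bf_profile.py
prior mean survival 0.05 (CI 0.01-0.1): peak at 27.5 Ma, 2lnBF 7.18 (strong)
prior mean survival 0.25 (CI 0.07-0.5): peak at 27.5 Ma, 2lnBF 4.53 (moderate)
prior mean survival 0.75 (CI 0.48-0.94): peak at 27.5 Ma, 2lnBF 1.05 (none)
```

Reading: smooth time-varying rate models cannot tell themselves apart on a
tree like this, and neither temperature nor its rate of change beats the
null — but a localized extinction pulse in the mid-Cenozoic is moderately
better than no pulse (an evidence ratio of ~28×), with a plateau of
near-equivalent candidate ages above the onset of the post-bottleneck
radiation.  The Bayesian profile agrees and, as expected, the support fades
when the prior allows only mild extinctions.  The profile peaks a few Myr
*below* the true event age; see `docs/methods.md` on this recovery-lag bias,
which the method inherits from the data rather than from the
implementation.

A `pulsetree` command exposes the same steps
(`pulsetree tree assemble`, `sim tree`, `sim temp`, `fit bd`,
`scan pulses`, `scan bf`, `fossil`, `fixtures`); all outputs embed the seed
and a config checksum.

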