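# rateshift

Tools for asking whether a genomic region changed its substitution rate
after two datable events — a chromosomal inversion and the birth of a new
gene — using the exons of flanking genes as a built-in molecular clock.

The motivating system is a mouse locus where a pair of antisense long
non-coding RNAs (a *Pldi*-like sense transcript and its antisense partner)
arose de novo from intergenic sequence after the mouse–rat split, inside a
region that was rearranged by inversion earlier on the rodent lineage.
The package provides, for the four-species phylogeny
`(((mouse, rat), human), dog)`:

- the **normalized-rate model** (`rateshift.ratemodel`): stage rates
  relative to a flanking-exon reference, their estimation from pairwise
  distances, qualitative ordering calls, and algebraic recovery of the
  stage rates over a grid of event timings;
- **alignment handling** (`rateshift.alignments`): FASTA I/O, a
  deterministic column-curation filter, and reference-exon concatenation;
- **distances and trees** (`rateshift.distances`): p/JC69/K80 pairwise
  distances with pairwise deletion, distance matrices, neighbor joining;
- **region mapping** (`rateshift.regionmap`): inversion calling from
  strand-flipped MAF block chains, per-species feature coverage,
  RepeatMasker `.out` parsing, shared-transposable-element filtering,
  TE/feature composition tables, and ORF scanning;
- a **synthetic-data generator** (`rateshift.synthetic`) that simulates
  every input the pipeline consumes, so the whole analysis is testable
  without any downloads.

## The model

Three constant substitution rates describe the test region: r₀ before the
inversion, r₁ between inversion and gene birth, r₂ afterwards; the
reference exons evolve at a single rate r_R. With t_MR < t_HR < t_HD the
pairwise divergence times, k₁ the elapsed fraction of t_HR since the
inversion and k₂ the elapsed fraction of t_MR since gene birth, expected
distances are

```
d_test_HD = 2 r0 t_HD                                d_ref_XY = 2 rR t_XY
d_test_HR = (1+k1) r0 t_HR + (1-k1) r1 t_HR
d_test_MR = (1+k2) r1 t_MR + (1-k2) r2 t_MR
```

and the normalized average rates are the test/reference distance ratios

```
r_averHD = ρ0        r_averHR = [(1+k1) ρ0 + (1-k1) ρ1] / 2
r_averMR = [(1+k2) ρ1 + (1-k2) ρ2] / 2          with  ρi = ri / rR .
```

`r_averHR < r_averHD` implies r₁ < r₀ (rate reduced after the inversion);
a depressed `r_averMR` implies a reduced post-birth rate r₂. Given
measured ratios, the ρᵢ are recovered exactly for any assumed (k₁, k₂)
and tabulated over a grid, since only a time interval — not an exact
event time — is identifiable.

## Worked example

Simulate a locus whose rate was doubled before the inversion, equal to
the reference in between, and halved after gene birth
(r₀=2, r₁=1, r₂=0.5, r_R=1, k₁=k₂=0.5, 10⁵ sites), then run the pipeline:

```python
from rateshift import (FilterPolicy, RateParams, SpeciesTree,
                       run_rate_analysis, simulate_locus)

tree = SpeciesTree(t_mr=0.05, t_hr=0.2, t_hd=0.25)
params = RateParams(r0=2.0, r1=1.0, r2=0.5, r_ref=1.0, k1=0.5, k2=0.5)
locus = simulate_locus(tree, params, 100_000, 100_000, seed=1)
report = run_rate_analysis(locus.test_alignment, [locus.ref_alignment],
                           policy=FilterPolicy(min_window_identity=0.0),
                           model="jc69")
nr = report.normalized
print(f"{nr.r_aver_hd:.4f} {nr.r_aver_hr:.4f} {nr.r_aver_mr:.4f}")
print(report.call.inversion_effect, report.call.birth_effect)
print(report.scan.at(0.5, 0.5))
```

prints

```
1.9901 1.7559 0.8751
reduced reduced
RateRatioSolution(rho0=1.9901, rho1=1.0534, rho2=0.3402, k1=0.5, k2=0.5, feasible=True)
```

The measured ratios sit on the analytic expectation (2.0, 1.75, 0.875);
the ordering call recovers the planted history (rate reduced at the
inversion and again at gene birth), and the solution at the true timing
recovers the planted ρ = (2, 1, 0.5) up to sampling noise (the inversion
of the MR equation amplifies distance noise into ρ₂, which is why the
scan reports intervals rather than a point).

The numbered drivers under `analysis/` run the full study —
`01_simulate_locus.py` through `05_orf_scan.py` — each printing what it
found and writing its tables under `results/`.

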