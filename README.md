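# m6adyn

Kinetic modeling of N6-methyladenosine (m6A) mRNA dynamics, and the
measurement-side indices used to read m6A out of sequencing data.

m6A is an internal mRNA modification that promotes cytoplasmic decay of the
transcripts carrying it. A recurring puzzle in epitranscriptomics is that
measured m6A levels shift — across subcellular compartments, after drug
treatments, during stress — without any apparent targeting of the writer or
eraser machinery. `m6adyn` is built around a *semi-passive* explanation:
if methylated transcripts are simply degraded faster in the cytoplasm,
then ordinary mRNA metabolism (production, export, decay) is enough to
move measured m6A levels around.

The package is for computational biologists who want to simulate that
model, test which of its qualitative predictions survive alternative
assumptions, and benchmark the standard m6A indices (IP/input enrichment,
deamination scores, fractionation fold-changes) against known ground truth.

## The model

Each gene has two transcript species — unmethylated (`A`) and methylated
(`m6A`) — produced in the nucleus, exported, and degraded in the cytoplasm:

    dNuc/dt = α − (β + δ)·Nuc        Nuc* = α/(β+δ)
    dCyt/dt = β·Nuc − γ·Cyt          Cyt* = β·Nuc*/γ

with per-species rates (α^A, β^A, γ^A) and (α^m6A, β^m6A, γ^m6A), and an
optional nuclear decay δ (default 0). The baseline assumption is shared
export (β^m6A = β^A) and selective cytoplasmic decay (γ^m6A = S·γ^A,
S = 10). From the four steady-state pools the package derives the gene
level, the methylated fraction of the nuclear / cytoplasmic / whole-cell
pools, and the Nuc:Cyt localization ratio.

On top of the kinetic core sit:

- **cohorts** — populations of genes with Gamma(1, 1)-sampled rates,
  binned/correlation summaries, and model variants (nuclear decay,
  export-facilitated, export-inhibited, writer knockout);
- **perturbations** — named scenarios (`actd` α=0, `cpt` α→10%,
  `ythdf_ko` γ^m6A:=γ^A, `export_block` β→10%, `hs_induction` α×10) run
  from the pre-perturbation steady state;
- **half-life estimation** — log-linear fits of shutoff courses with the
  negative-slope, p < 0.05 filter and HL = ln 2 / (−k);
- **metrics** — m6A-GI/SI (IP vs input), GLORI-GI (deamination site
  scores), TMM normalization, nuclear:cytoplasmic log fold-changes, PC1
  loadings of gene × sample index matrices;
- **synthetic data** — negative-binomial count generators (MeRIP pairs,
  fractionation pairs, deamination site tables, decay courses) with
  ground truth attached, so every estimator is testable end to end.

## Worked example

```python
from m6adyn import (RateSet, steady_state, derive_indices,
                    sample_rates, cohort_steady_state, association)
from m6adyn.perturbation import ko_comparison

# one gene, all rates 1, selective decay S=10
r = RateSet.baseline(alpha_A=1.0, alpha_m6A=1.0, beta=1.0, gamma_A=1.0, S=10.0)
idx = derive_indices(steady_state(r))
print(f"m6A level={idx.m6a_level:.4f}  nuclear={idx.nuc_m6a_level:.4f}  "
      f"cytoplasmic={idx.cyt_m6a_level:.4f}")
print(f"Nuc:Cyt ratio={idx.nuc_cyt_ratio:.4f}")

# a 2000-gene cohort: localization and decay trends
coh = sample_rates(2000, seed=11)
states = cohort_steady_state(coh)
out = association(states["m6a_level"], states["nuc_cyt_ratio"], method="spearman")
print(f"Spearman(m6A level, Nuc:Cyt) = {out['coefficient']:.3f} (n={out['n']})")

kc = ko_comparison(coh)           # writer knockout: gamma_m6A := gamma_A
ok = kc["hl_ratio"].notna()
out2 = association(kc["m6a_level"][ok], kc["hl_ratio"][ok], method="spearman")
print(f"Spearman(m6A level, KO/WT half-life ratio) = {out2['coefficient']:.3f}")
```

prints

```
m6A level=0.3548  nuclear=0.5000  cytoplasmic=0.0909
Nuc:Cyt ratio=1.8182
Spearman(m6A level, Nuc:Cyt) = 0.617 (n=2000)
Spearman(m6A level, KO/WT half-life ratio) = 0.684
```

Reading the numbers: with selective decay the cytoplasmic methylated pool
is depleted tenfold (0.09 vs the 0.50 nuclear fraction), so whole-cell m6A
sits between the two (0.35) and the gene looks relatively nuclear (ratio
1.82). Across a cohort, genes that live more in the nucleus are sheltered
from selective decay and carry more m6A (ρ = 0.62), and genes with more
m6A gain more stability when selective decay is knocked out (ρ = 0.68) —
the two population-level signatures the model exists to explain.

A thin CLI covers the same workflows (`m6adyn perturb`, `m6adyn synth`,
`m6adyn halflife`, `m6adyn gi|si|glori-gi|nc-lfc|pc1`); see `m6adyn --help`.

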