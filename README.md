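# ihmburden

Regional burden statistics for cardiomyopathy variants on the myosin
interacting-heads motif (IHM).

In relaxed striated muscle, pairs of β-cardiac myosin heads fold back into
the IHM: the *blocked* head docks onto its own S2 tail and the *free* head
docks onto the blocked head, producing the energy-saving super-relaxed
(SRX) state. `ihmburden` is a small analysis library for asking whether
disease variants concentrate on the residues that build this structure. It
targets clinical-genetics and muscle-biophysics workflows that have: a
table of missense variants per cohort, residue-level region definitions
(IHM interactions, motor-domain functional sites, the mesa), case/control
carrier counts, and — on the biophysics side — head-orientation fractions
and scattering profiles.

The core statistic is elementary and exact. For `n` variant events on a
protein of length `L` and a region of `m` residues, the null is uniform
placement, `p0 = m/L`; the observed in-region count `k` yields a fold
enrichment `(k/n)/p0` and a two-sided exact binomial p-value
(minimum-likelihood convention). Around it sit: charge-change (Δq)
annotation with an exhaustive 9-per-codon SNV expectation; carrier odds
ratio `OR = (a/(n1−a))/(b/(n0−b))` with etiologic fraction
`EF = (OR−1)/OR`; the duty-cycle model `D_s = 2/(1+R)`,
`SRX/DRX = (2−D_s)/D_s` linking head orientation to SRX populations; and
the SAXS goodness of fit `χ = sqrt((1/M) Σ ((Iexp−c·I)/σ)²)`.

The package ships transcriptions of the published HCM/DCM cohort tables
and a reconstructed region fixture that reproduces every published region
size (see `docs/methods.md` for the reconstruction rules and their
assumptions), so the full published analysis can be re-run end to end.

## Worked example

```python
from ihmburden import fixtures
from ihmburden.enrichment import enrich, enrichment_table, format_table
from ihmburden.regions import SELECTORS

rs = fixtures.load_regions()
hcm = fixtures.annotated_hcm(rs=rs)           # 135 MYH7 PV+LPV events

r = enrich(hcm, rs, SELECTORS["ihm_all"])
print(r.n_obs, r.n_total, round(r.rate, 3), r.printed_ratio, f"{r.p_value:.3g}")
print(format_table(enrichment_table(hcm, rs)))
```

prints

```
73 135 0.541 2.34 7.95e-15
Specified site          Variants within site  Rate   Amino acids within site  Expected rate  Rate ratio  P-value
IHM Interactions (All)  73                    0.541  447                      0.2310         2.34        7.95e-15
Priming                 17                    0.126  113                      0.0584         2.16        0.00264
Anchoring               24                    0.178  156                      0.0806         2.21        2.11e-04
Stabilizing             48                    0.356  189                      0.0977         3.64        5.37e-16
Scaffolding             24                    0.178  120                      0.0620         2.87        2.97e-06
MD Functional           39                    0.289  194                      0.1000         2.89        7.87e-10
```

Reading the first line: 73 of the 135 HCM variant events (54%) alter IHM
interaction residues, which cover only 23% of the 1935-residue heavy chain
— a 2.34-fold enrichment the uniform null would essentially never produce
(p ≈ 8×10⁻¹⁵). Stabilizing interactions — the contacts that hold the free
head onto the blocked head — are the most enriched (3.64-fold). Running the
same table on the 27 DCM variants gives 1.12-fold overall (p = 0.66): DCM
variants sit on motor-domain functional sites instead. The charge side:

```python
from ihmburden.charge import charge_change_fraction
pv = fixtures.annotated_hcm(("PV",), rs=rs)
ihm_pv = [a.record for a in pv if a.matches(SELECTORS["ihm_all"])]
print(charge_change_fraction(ihm_pv))         # (22, 31, 0.7097)
```

— 71% of IHM-altering pathogenic variants change side-chain charge, versus
a 49% transcript-wide expectation, consistent with electrostatic disruption
of the head-head interfaces.

Each capability has a narrative script under `examples/`
(`enrichment_tables.py`, `charge_expectation.py`, `clinical_burden.py`,
`srx_duty_cycle.py`, `saxs_fit.py`, `simulate_recovery.py`), and a thin CLI
mirrors the stages:

```
ihm-burden enrich --cohort HCM --classes PV,LPV
ihm-burden burden
ihm-burden srx --parallel 0.70
ihm-burden run-all --outdir report/
```

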