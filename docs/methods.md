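# Methods

`ihmburden` reimplements, as a tested library, the statistical analysis
showing that hypertrophic-cardiomyopathy (HCM) variants in the β-cardiac
myosin genes concentrate on residues of the interacting-heads motif (IHM) —
the folded-back conformation of paired myosin heads that underlies the
energy-saving super-relaxed (SRX) state — while dilated-cardiomyopathy
(DCM) variants do not. This note records the models, the reconstruction of
the packaged fixtures, the numerical conventions, and the limits of what
the tests demonstrate.

## Regional enrichment model

A cohort contributes `n` missense variant events on a protein of length
`L = 1935` residues (β-myosin heavy chain; light-chain variants are
annotated but excluded from heavy-chain denominators). For a region of
interest comprising `m` residues, the null hypothesis is uniform placement:
each event falls in the region with probability `p0 = m/L`. The observed
count `k` is scored two ways:

* **rate ratio** `(k/n) / p0` — fold enrichment;
* **exact binomial p-value**, two-sided by the minimum-likelihood
  convention (the sum of `P(X=i)` over all outcomes with
  `P(X=i) ≤ P(X=k)·(1+1e-7)`), computed by `scipy.stats.binomtest`. A
  one-sided (`greater`) variant is available by flag. No multiple-testing
  correction is applied by default (a Bonferroni column can be requested);
  the published tables applied none.

Counting conventions that matter:

* The counting unit is the **nucleotide event**, not the distinct
  substitution: one pathogenic substitution is encoded by two distinct DNA
  variants, so the HCM cohort has 135 events from 134 distinct
  substitutions (see *Fixture reconstruction*).
* Table rows are **not disjoint**: a variant whose position participates in
  several interactions counts once in every row it matches, and once only
  in the overall IHM row (set union, never a sum over sub-regions).
* A variant "matches" a row if its position lies in the union of the
  region cells the row's selector picks out; head-context rows (blocked /
  free / tail) select by the context tag of the cell.

### Printed-table rounding

The published tables round before deriving: rate to 3 decimals, expected
rate to 3 significant figures, and the printed rate ratio is the ratio of
those rounded values re-rounded to 3 significant figures. The library keeps
full precision in `EnrichmentResult` and reproduces the published rendering
via `printed_ratio`/`format_table`. This convention is not cosmetic: the
motor-domain row (194/1935 = 0.10026) prints expected rate 0.1000 and ratio
2.89, which exact arithmetic (2.8815 → 2.88) would not reproduce.

## Fixture reconstruction

The residue-level interaction definitions exist only as a supplement that
is not distributed with this package, so the packaged `regions.tsv` is a
**synthetic reconstruction**, built by `synth.build_fixture_regions` under
constraint satisfaction:

1. every variant position carries exactly the interaction, motor-domain and
   mesa memberships its published table row prints;
2. filler residues — positions untouched by any tabulated variant of any
   cohort, taken lowest-first in a fixed cell order (`synth.FILL_PLAN`) —
   pad each region so that **all** published sizes hold simultaneously:
   class unions (priming 113, anchoring 156, stabilizing 189, scaffolding
   120, overall IHM 447), head-context unions (blocked 362, free 171, tail
   69 — the sizes that reproduce both the printed expected rates 19%/8.8%/
   3.6% and the printed context p-values exactly), motor-domain sets
   (nucleotide 39 + actin 60 + converter 68 + relay 27 = 194; the DCM
   table's extended definition 210), and the mesa (277 residues, 126 of
   them shared with IHM cells, reproducing the published 4.1-fold mesa∩IHM
   enrichment).

The filler counts in `FILL_PLAN` are the exact solution of the linear
size/overlap constraints, not tuned values; the builder re-verifies every
published union on each run and refuses inconsistent inputs. Three
reconstruction assumptions were forced by the published aggregates and are
worth knowing:

* **The duplicated substitution.** The tables do not say which pathogenic
  substitution is encoded by two nucleotide variants. Requiring every
  published aggregate (31/40 pathogenic variants at IHM residues,
  stabilizing 48, anchoring 24, priming 17, motor-domain 39 with 16
  pathogenic, 22/31 charge-changing with 9 gains and 13 losses) to hold
  simultaneously leaves exactly one admissible choice: E483K carries
  multiplicity 2.
* **One scaffolding membership.** A literal transcription yields 23
  scaffolding variants against the published 24; the fixture additionally
  places V763M (converter, flanked by scaffolding-annotated neighbours) in
  the ELC-scaffolding set on the free head, the only single addition that
  restores 24 without disturbing any other count.
* **Motor-domain sub-annotations.** The published motor-domain aggregates
  (39 of 135 HCM over 194 aa; 7 of 27 DCM) are arithmetically inconsistent
  with counting every row that prints a converter/actin annotation. The
  fixture keeps the aggregates (the quantities the tables actually test)
  and omits the motor-domain annotation of four HCM converter rows (P731A,
  K740N, L749Q, F758C) and two DCM actin rows (R369Q, N597K); their
  interaction and charge annotations are untouched.

One transcription correction: the printed charge change "0" for R453S is
transcribed as −2, the value implied by every other printed arginine
substitution (R453C prints −2 at the same position).

Because fillers are synthetic, only statistics that depend on *variant*
positions and *region sizes* are faithful; the identity of non-variant
region residues is not meaningful and must not be interpreted
biologically.

## Charge-change analysis

The integer side-chain charge scale is **inferred**, not copied: the scale
R=+2, K=+1, H=+1, D=E=−1 (others 0) is the unique integer assignment
reproducing all 170+ printed per-substitution charge changes, and a
regression test pins it. A conventional scale (R=K=+1, H=0) ships as an
alternative. Δq is `q(alt) − q(ref)`; the observed fraction of
charge-changing substitutions among IHM-altering variants (22/31 HCM
pathogenic, 5/7 DCM) is compared with a codon-level expectation by the same
binomial machinery.

The expectation comes from exhaustive single-nucleotide mutagenesis:
for each of the 1935 codons, all nine single-base changes (17,415 events)
are classified against the standard genetic code — synonymous, nonsense
(stop gained), or missense with a Δq sign. The terminal stop codon is
stripped before enumeration (1935 × 9 = 17,415 matches the protein length
exactly, so the stop was not enumerated); internal stops are an error by
default. The published 49% charge-changing expectation derives from the
real transcript's codon usage; the package does not ship that sequence, so
tests pin the event count and validate the enumerator against a
mutate-and-retranslate oracle, while the 49% value is used as a stated
constant where the observed/expected comparison is reproduced. A uniform
random-codon sequence gives ≈ 41%, illustrating how strongly composition
matters (myosin is unusually rich in charged residues).

## Case/control burden

With carrier counts `a/n1` in cases and `b/n0` in a reference population
(one rare variant per individual assumed; the reference cohort size is the
median number genotyped per site, 33,364), the odds ratio is
`(a/(n1−a))/(b/(n0−b))`; `b = 0` with `a > 0` flags an infinite OR (a
Haldane 0.5 correction is available but off by default — the published
zero-cell regions report EF = 1.0, consistent with no correction). The
etiologic fraction is `(OR−1)/OR`, mapping the infinite flag to 1.0 and
protective ORs to negative values. Prevalence is compared with the same
exact binomial test at `p0 = b/n0`. Rows of a counts table are treated
independently (whether individuals carrying variants in two regions are
double-counted is not specified in the source). A Woolf log-OR interval is
provided as a clearly-labelled extension; no intervals are reported by
default because none are published.

## SRX/DRX duty-cycle model

Each myosin contributes a blocked head (docked, parallel to the filament
axis in relaxed muscle) and a free head that sways for a fraction `D_s` of
the time. With `N` molecules, parallel heads number `(2−D_s)N` and
perpendicular heads `D_s·N`, so the measured orientation ratio
`R = f_par/f_per` gives `D_s = 2/(1+R)` and `SRX/DRX = (2−D_s)/D_s`.
Validity requires `f_par ≥ 0.5`. For skeletal muscle (70%/30%) this yields
`D_s = 0.60`, SRX/DRX = 7/3 ≈ 2.3. Cardiac orientation data are ambiguous,
so the cardiac estimate `D_s = 0.8` (SRX/DRX = 1.5) is an **assumed input**
— the library exposes both the orientation-derived and assumed-D_s paths
and does not attempt to reconcile them; applying the formula to roughly
equal cardiac fractions would give `D_s ≈ 1`. Relative relaxed ATP turnover
uses a 5-fold SRX inhibition: `(1−s) + s/5` for SRX head share
`s = (2−D_s)/2`.

## SAXS χ

`χ = sqrt((1/M) Σ ((Iexp(q_i) − c·I(q_i))/σ(q_i))²)` over the `M`
experimental points, with the model linearly interpolated onto the
experimental grid (extrapolation refused). The scale `c` is fitted in
closed form when requested (`c = Σ Iexp·I/σ² / Σ I²/σ²`); a "profile
offset" can be fitted jointly with the scale by weighted least squares,
off by default. No q-range cut is applied unless `q_max` is given (the
published fits do not state one). The published χ values for deposited
structural models (1.5 and 1.85) require external scattering data and a
profile calculator and are out of scope; the statistic is validated on
synthetic data where `Iexp = I + N(0, σ)` concentrates χ near 1.

## Synthetic-data generators

All generators are pure functions of `(SimSpec, seed)`; a single integer
seed drives independent sub-streams (variants / cohorts / CDS / profiles)
so adding one generator never perturbs another. Defaults encode the study
conditions: protein length 1935, 135 cohort variants, 6112 cases vs 33,364
controls at a 1.35% control carrier rate, duty cycle 0.8, 500-point
profiles at 2% relative noise.

* `gen_variants` places each variant in the region with probability
  `f·m/L` (uniform within strata), so the expected rate ratio equals the
  enrichment factor `f` exactly — the relative-rate convention that makes
  "factor 3 recovers mean ratio 3" a calibration identity rather than an
  approximation. Factors with `f·m/L ≥ 1` are rejected.
* `gen_cohorts` draws carrier counts binomially with case odds = control
  odds × OR.
* `gen_cds` draws uniform random sense codons (no stops), so a 1935-codon
  draw always yields 17,415 enumeration events.
* `gen_profile` produces a Guinier-like decay with proportional errors and
  Gaussian noise.

What the generators deliberately do **not** emulate: mutational spectrum
(transition/transversion or CpG bias), codon usage of real transcripts,
per-variant allele frequencies, linkage between carriers, or 3-D clustering
of variants. Passing parameter-recovery tests therefore shows the
estimators are correctly calibrated under the stated sampling models, not
that real cohorts satisfy those models.

## Numerical choices and degenerate inputs

* Binomial `p0 = 0`: `k = 0` gives p = 1 (degenerate null holds), `k > 0`
  gives p = 0.
* Odds ratio with all cases carriers is an error unless the Haldane
  correction is enabled; EF of a non-positive OR is an error.
* Region files: duplicate positions collapse; same-name rows merge by
  union; descending ranges, unknown classes/contexts and out-of-range
  positions are parse errors naming the row. The writer emits canonical
  sorted ranges, making parse∘write∘parse the identity.
* Substitution tokens: slashed forms expand per alternate allele; HGVS
  three-letter names map to one-letter; stop-gain and frameshift notation
  are rejected (missense only).
* Ties in the two-sided binomial follow the `(1+1e-7)` tolerance of the
  minimum-likelihood convention, matching the R implementation family.

## Known limitations

* The region fixture is a constraint-satisfying reconstruction, not the
  true residue lists; analyses that depend on *which* non-variant residues
  pad a region (e.g. spatial clustering) are meaningless on it.
* The DCM motor-domain row uses the published 210-residue definition; the
  published expected rate (0.1090) and ratio (2.380) correspond to that
  row's own rounding conventions as described above.
* The abstract-level p-value for the 54%-vs-23% comparison (2.6e-19) is not
  reproducible from the printed counts under any binomial convention tried;
  the package targets the main-table convention (7.95e-15).
* Per-region clinical carrier counts beyond the whole-gene row and the
  zero-control example are not in the main text and are not packaged.
* No homology modelling, interface detection from structures, or profile
  computation from atomic coordinates: region files and scattering profiles
  are consumed as data.
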