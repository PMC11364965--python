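# Methods

## Scope and model

This package annotates untargeted positive-mode LC-MS peak tables with
putative phytohormone identities. The underlying model is deliberately
simple and transparent: a catalogue of known hormones, precursors,
metabolites and conjugates is expanded into a set of theoretical m/z values
by applying small-moiety mass shifts, and observed features are matched to
those values within a mass tolerance, then ranked by agreement between the
observed retention time and a predicted retention time for the parent
compound. Matches are putative identifications at MSI level 3 (two
orthogonal physicochemical properties, no reference standard); the
biotransformation screen in particular is a hypothesis generator, not a
confirmation method — a predicted glycoside is only plausible if the parent
chemistry admits glycosylation, which the code does not check.

## Mass-shift calculus

A shift rule is a signed multiset of moieties written `M±[k]X...` over the
vocabulary H, H2, OH, CH3, NH2, NH3, NH4, COOH, C6H12O6, H2O, CH3OH, Li, K.
Moiety and compound masses are sums of IUPAC monoisotopic atomic masses
(C = 12 exactly, H = 1.00782503207, N = 14.0030740048, O = 15.9949146196,
S = 31.97207100, K, Li, Cl, ... to ≥ 8 decimals), so theoretical m/z is
reliable well below the 4-decimal precision at which screens are read.

Two m/z conventions are supported. The default, `neutral_shift`, reports
parent mass + net moiety delta, which is the convention the documented
worked examples follow (e.g. abscisic acid, C15H20O4 = 264.1362 Da, under
M−OH+CH3 gives 262.1569). The `protonated` flag adds one proton
(1.007276 Da) for peak tables of M+H ions. Ionic adducts (M+Li, M+NH4,
M+K, M+H) use neutral-moiety masses without subtracting the electron mass
(~0.00055 Da, negligible at the tolerances involved but kept as a named
constant). The methanol adduct is implemented exactly as published
(M+CH3OH−H, net +31.018390 Da); the chemically common alternative
M+CH3OH+H is noted in the source but not in the default set.

Four built-in rule sets mirror the searchable databases of the web
workflow: the identity rule (`PGR_Monoisotopic`), the single protonation
rule (`PGR_MplusH`), 7 electrospray adducts (`PGR_Adducts`), and 27
synthetic biotransformations (`PGR_Biotransformations`) covering
(de)methylation, (de)hydroxylation, (de)glycosylation, (de)amination,
(de)carboxylation and their pairwise exchanges. Expansion is order-stable
(catalogue order × rule order); combinations yielding a non-positive mass
(removing a glucosyl moiety from a parent lighter than glucose) are
rejected with a warning.

## Compound catalogue

The catalogue CSV requires `name,class,monoisotopic_mass` and optionally
formula, SMILES, InChI and predicted RT. Names are trimmed but never
case-folded (case is significant in names like "N-Acetylserotonin").
Catalogued masses are checked against formula-derived masses within
0.005 Da — generous enough for masses printed to 2 decimals, tight enough
to catch a wrong structure. The shipped fixture catalogue holds 32
compounds with 6-decimal formula-derived masses; the loader accepts any
user catalogue in the same format (including the full published catalogue,
which is distributed separately as a supplementary CSV).

## Matching, ranking, deduplication

Tolerances are ± Da (absolute) or ppm (relative, evaluated at the
theoretical m/z so each database entry has a deterministic window). The
boundary is inclusive. Matching uses a sorted-array window search that is
property-tested against an exhaustive pairwise comparison; all isobaric
hits for a feature are returned.

The %RT match is 100 × (1 − |RT_obs − RT_pred| / RT_pred), clipped to
[0, 100]. The published workflow does not state its formula; this choice is
consistent with the downstream meta-analysis thresholds (a 70% cutoff
corresponds to |ΔRT| ≈ 1.5 min for a mid-gradient analyte on the 25-min
method) and is isolated in a single replaceable function. Ranking groups
annotations by feature, descending %RT match, with unscored annotations
last and ties broken by |Δm/z| then compound name. Deduplication keeps the
best-ranked annotation per (compound, rule) pair — rule included, since the
same compound under different biotransformations is a distinct hypothesis.

## Retention-time model

RT prediction is a QSRR random forest (scikit-learn, 500 trees, fixed
seed) over a fixed panel of 18 RDKit 2-D descriptors (size, lipophilicity,
TPSA, H-bond donors/acceptors, flexibility, aromaticity, partial-charge
extremes). The shipped training table carries the 46 reference analytes of
the standardized 25-minute C18 gradient with their observed RTs, the
original model's predicted RTs, and hand-curated SMILES (best-effort
skeletons for the complex alkaloids and steroids, used for featurization
only). The exact descriptor stack and cross-validation splits of the
original model are not public, so its printed accuracy metrics are not
reproduction targets; instead the machinery is validated by parameter
recovery on synthetic descriptor→RT data (linear signal + Gaussian noise,
sd 0.3 min, n = 200, 80/20 split: held-out R² ≥ 0.8, RMSE ≤ 0.6 min).
Metrics: RMSE, MAE, R², and a 95% residual band defined as the 95th
percentile of |residuals| (1.96 × sd available via flag); the definition
used for the original printed confidence interval is unknown.

## Meta-analysis filtering

Per-study annotation lists are filtered by a gradient-trust rule before
class binning: same gradient and column as the reference method → keep
%RT match > 70; different → keep > 50; gradient not reported → keep
1 min < RT < column re-equilibration start; direct injection → keep all.
Thresholds are strict inequalities exactly as published. The default
re-equilibration start is 15.0 min: on the reference gradient the mobile
phase ramps back to initial conditions over 15–20 min, so later elution is
uninterpretable; it is configurable per study. Annotations lacking a %RT
match where a threshold applies are dropped with a warning. After
filtering, distinct compounds are counted per (class, study) with the
catalogue's per-class totals as the reference column; studies acquired in
both ionization modes are listed as two manifest rows.

## Synthetic data

The generator emulates the input contract only — a feature table of
(m/z, RT, intensities) rows — not chromatography or raw spectra. Spikes are
placed at the theoretical m/z of chosen (compound, rule) pairs with
Gaussian m/z noise and at the parent's predicted RT with Gaussian RT noise;
decoys are uniform over m/z 100–1000, rejection-sampled to stay at least a
chosen distance (default 0.05 Da) from the catalogue expanded under *all*
built-in rule sets, so any decoy annotation indicts the matcher, not the
generator. Intensities are log-normal (meanlog 10, sdlog 1) and carry no
information. All randomness flows from one seed through a single
`numpy` generator with documented draw order, so tables are exactly
reproducible. What passing synthetic tests shows: the matcher, ranking,
filtering and scoring are correct under the stated noise model. What they
do not show: performance on real data with correlated m/z error,
drifting RT, co-elution, or in-source fragmentation.

## Numerical choices and edge cases

- Tolerance boundary inclusive; ppm evaluated at theoretical m/z.
- Formula parsing is case-sensitive Hill notation; repeated element
  symbols accumulate; unknown symbols are errors naming the symbol.
- Peak tables over 10 MiB are refused by default (overridable), matching
  the web tool's upload ceiling; header-only tables return an empty result
  with a warning rather than an error.
- `rt_match_percent` is undefined (raises) for non-positive predicted RT.
- Screening CSV output rounds m/z to 4 decimals, RT to 2, %RT to 1; a
  full-precision flag disables rounding.
- Problem sizes in the test suite (32-compound catalogue, ≤ 1000 spiked
  features, 200 random matcher instances, 500-tree forests on 46–200
  samples) were chosen as the smallest sizes at which every property is
  statistically decisive.

## Known limitations

- No structure-aware feasibility checks on biotransformations, no MS/MS,
  no isotope envelopes, no charge states beyond +1, no negative-mode
  adduct set, no peak picking or alignment.
- The %RT-match formula is this package's choice, not a published one.
- RT predictions transfer only to chromatography resembling the reference
  gradient; the meta-analysis rules exist precisely because they usually
  do not.
- A handful of published worked-example rows are not derivable from the
  standard structures of their named parents (the original catalogue
  evidently stored different parent masses); those rows are documented but
  not asserted.
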