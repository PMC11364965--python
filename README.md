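# hormonomics

Phytohormone screening of untargeted LC-MS peak tables.

Hormones, their precursors, conjugates and metabolites are present at low
levels, are chemically labile, and are stored in many modified forms, which
makes them easy to miss in untargeted metabolomics. This package screens an
aligned peak table (m/z, retention time, per-sample intensities) against a
focused catalogue of plant growth regulators, expanded in silico by
electrospray adducts and plausible enzymatic modifications, to produce
putative annotations at MSI level 3 and hypotheses about novel hormone
metabolites. It is aimed at plant (and, more broadly, small-molecule
hormone) metabolomics researchers working from XCMS/MZmine/MetaboAnalyst-
style feature tables.

## The method

Each catalogued compound with monoisotopic mass *M* is expanded under a
rule set of signed moiety shifts. For a rule such as M−OH+CH3 the
theoretical m/z is

    m/z = M − m(OH) + m(CH3)            (neutral-shift convention)
    m/z = M + Σ sᵢ·kᵢ·m(Xᵢ) + m(H⁺)     (protonated mode)

with moiety masses summed from IUPAC monoisotopic atomic masses. Built-in
rule sets: the identity rule, M+H, 7 common positive-mode adducts
(M+H−2H2O, M+H−H2O, M+NH4−H2O, M+Li, M+NH4, M+CH3OH−H, M+K), and 27
synthetic biotransformations ((de)methylation, (de)hydroxylation,
(de)glycosylation, (de)amination, (de)carboxylation and their exchanges).

A feature at observed m/z matches an entry when |m/z_obs − m/z_theo| ≤ τ,
where τ is given in ± Da or ppm (ppm evaluated at the theoretical m/z).
Matches are ranked per feature by the retention-time agreement

    %RT = max(0, 100·(1 − |RT_obs − RT_pred| / RT_pred)),

where RT_pred comes from a random-forest QSRR model trained on 46 reference
analytes of a standardized 25-minute C18 gradient. A meta-analysis layer
filters per-study annotations by gradient-trust rules (>70% RT match for
the reference gradient, >50% for a different one, an elution-time window
when the gradient is unknown, everything for direct injection) and bins the
surviving distinct compounds by hormone class. A synthetic-data module
generates spiked peak tables with decoys and known ground truth so recall
and false-annotation rates are measurable exactly.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Screen a three-feature peak table against the biotransformation rule set at
±0.02 Da:

```sh
printf 'mz,rt,leaf_1\n262.1596,3.6688,15230\n234.1195,5.7546,8120\n465.10,3.50,20110\n' > demo_peaks.csv
hormonomics screen --peaks demo_peaks.csv --db biotransformations \
    --tol 0.02 --unit da --out demo_hits.csv
# 13 annotation(s) for 3 feature(s) -> demo_hits.csv
```

`demo_hits.csv` begins:

```
Compound name,Biotransformation,Actual m/z,Experimental m/z,Experimental RT,Predicted RT,%RT match,dm/z,MSI level,leaf_1
Abscisic acid,M-OH+CH3,262.1569,262.1596,3.67,5.56,66.0,0.0027,3,15230.0
2-hydroxymelatonin,M-NH2+H2,234.113,234.1195,5.75,5.07,86.5,0.0065,3,8120.0
...
Melatonin,M-CH3+OH,234.1004,234.1195,5.75,4.88,82.1,0.0191,3,8120.0
...
Glucobrassicin,M+NH3,465.0876,465.1,3.5,,,0.0124,3,20110.0
```

Reading this: the feature at m/z 262.1596 is 2.7 mDa from the theoretical
m/z of methylated-for-hydroxyl abscisic acid (262.1569), a putative ABA
metabolite; the feature at 234.1195 is isobaric with ten hypotheses from
the melatonin/serotonin pathway, ranked by how well the observed RT
(5.75 min) agrees with each parent's predicted RT; glucobrassicin + NH3
matches on m/z alone (no predicted RT for that entry, so no %RT score).
All hits are MSI level 3 — hypotheses to triage, not identifications.

The same pipeline is available as a library:

```python
import hormonomics as h

db = h.load_fixture_db()
frame = h.screen("demo_peaks.csv", db, "biotransformations",
                 h.Tolerance(0.02, "Da"))
```

Other subcommands: `build-db` (export the expanded theoretical-m/z table),
`validate-db` (audit a catalogue's masses against its formulas),
`predict-rt` (train the RT model and predict for new SMILES), `meta`
(multi-study screen + class summary from a manifest), `simulate`
(ground-truthed synthetic peak tables). Every run writes a JSON run log
next to its output.

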