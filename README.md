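# driftccs

Automated collision cross-section (CCS) determination from ion-mobility
mass-spectrometry (IMS-MS) feature tables.

IMS separates gas-phase ions by their momentum-transfer collision cross
section Ω with a neutral buffer gas, a shape descriptor that complements
mass in metabolite and peptide identification. Turning measured arrival
times into CCS values, however, depends on the IMS platform and acquisition
mode. `driftccs` implements the standard calibration routes behind one
consistent API, for anyone processing drift-tube (DTIMS), trapped (TIMS) or
traveling-wave (TWIMS/SLIM) data who has feature tables (m/z, arrival time,
intensity) and instrument metadata but no automated way to get CCS out of
them:

* **Stepped-field DTIMS** — the same sample acquired at several drift
  voltages. Under the low-field drift relation the arrival time is linear
  in x = 1000·L²·(273.15/760)·P/(T·V):

      tA = x / K0 + t0

  so an ordinary least-squares fit across fields yields the reduced
  mobility K0 (slope = 1/K0) and the time spent outside the drift cell
  (t0). CCS follows from the Mason–Schamp relation

      Ω = (3 z e / 16 N0) · sqrt(2π / (μ k T)) · (1 / K0).

  Because several features can fall inside the m/z tolerance per field, all
  per-field candidate combinations are regressed and fits with r² ≥ 0.99
  (configurable) are reported — distinct passing fits are distinct
  conformers.

* **Single-field DTIMS / TIMS** — a linear calibration of arrival time
  against the reduced CCS Ω′ = (1/z)·sqrt(mI/(mI+mB))·Ω of reference ions,
  applied untargeted to every detected feature. The **enhanced** mode
  regresses against Ω″ = (P/T)·Ω′ instead, folding each run's measured
  pressure and temperature into the calibration so that drift between the
  calibrant run and temporally distant sample runs cancels. Calibrant runs
  are auto-assigned to sample runs by polarity and acquisition timestamp
  (closest following run, falling back to the closest preceding one). A
  `tims_scan` mode accepts IMS scan numbers in place of arrival times.

* **TWIMS (Synapt, SLIM)** — non-linear calibration, either a degree-D
  polynomial of Ω′ on the corrected arrival time t′ = tA − t_acc, or the
  linearized power law ln Ω′ = X·ln t′ + ln Y followed by
  t″ = t′^X·z/√μ and a final line Ω = a·t″ + b. The corrections include the
  SLIM ion-accumulation time t_acc and the Synapt EDC delay
  C·sqrt(m/z)/1000. Features outside the calibrant arrival-time range are
  flagged `extrapolated`.

The package ships a synthetic-campaign generator (`driftccs.synth`) that
inverts each forward model with known ground truth, so every calibration
mode is testable end-to-end without instrument data.

## Worked example

Fit a stepped-field campaign (7 drift voltages, 850–1450 V) and print the
result for a tune-mix-like ion:

```python
from driftccs import NITROGEN, SteppedFieldModel, TargetMolecule
from driftccs.physics import PROTON_MASS_DA
from driftccs.synth import TUNE_MIX_LIKE_IONS, make_stepped_field_campaign
from driftccs.targets import AdductSpec, TargetIon

campaign = make_stepped_field_campaign(list(TUNE_MIX_LIKE_IONS), seed=1)
ion = TUNE_MIX_LIKE_IONS[0]                       # m/z 322.0481, CCS 153.73
target = TargetIon(TargetMolecule(ion.name, ion.mz - PROTON_MASS_DA),
                   AdductSpec("[M+H]+", PROTON_MASS_DA, 1, "positive"))
model = SteppedFieldModel(target, campaign.features_per_field,
                          campaign.metadata, NITROGEN)
print(model.fit().summary())
```

```
Stepped-field fit: cal322 [M+H]+ (expected m/z 322.0481, z=1)
fields: 7, r2 threshold: 0.99
conformers accepted: 1
  [1] CCS 153.7300 A^2  K0 1.366728 cm^2/(V s)  r^2 1.000000  t0 0.2000 ms  fields 7
```

The fit recovers the planted CCS of 153.73 Å² and reduced mobility
1.3667 cm²/(V·s) exactly (the campaign is noiseless), with the regression
intercept returning the generator's 0.2 ms out-of-cell time.

The same models are reachable from the command line:

```
driftccs synth --kind stepped --out demo_in --seed 1
driftccs stepped --features demo_in/features.csv --metadata demo_in/metadata.csv \
    --targets targets.csv --out demo_out
```

which writes `ccs_records.tsv` (one row per accepted conformer, CCS to
4 decimals), `replicate_stats.tsv` (mean CCS and %RSD per molecule/adduct)
and a deterministic `report.txt`.

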