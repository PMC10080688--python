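# phquench

**From protonation dynamics to photoprotective quenching: a pipeline for
pH-gated light-harvesting complexes.**

Plants and mosses dissipate excess absorbed sunlight through
nonphotochemical quenching (NPQ), whose rapid component is triggered by
acidification of the thylakoid lumen. In stress-related light-harvesting
complexes such as LHCSR1 of *Physcomitrella patens*, lumen-exposed
aspartates and glutamates act as pH sensors: their coupled
protonation states reshape the protein's conformational landscape and
modulate a charge-transfer (CT) quenching channel in the central
lutein–chlorophyll pair (L1-Lut / Chl *a*612).

`phquench` implements the complete analysis chain that turns simulation
outputs into quenching observables, for computational biophysicists
studying pH-dependent photoprotection:

1. **Titration analysis** — protonated fractions f(pH) from constant-pH
   trajectories, fitted to the Hill equation for the protonated fraction,
   f(pH) = 1 / (1 + 10^{n (pH − pKa)}), with 2× standard errors from a
   blocked bootstrap (blocks resampled within each trajectory to respect
   autocorrelation), and classification of each residue as a pH-sensor
   candidate (ΔpKa > 1 above the water reference, Glu 4.3 / Asp 3.9),
   a non-sensor, or a coupled site whose nonmonotonic curve defeats a
   single-site fit.
2. **Protonation microstates** — P/D (protonated/deprotonated) labels of
   a residue triad, windowed protonation fractions and Pearson-correlation
   coupling diagnosis, and a Markov state model over the 2³ microstates
   (transition matrix, populations, dominant states per pH).
3. **Conformational landscape** — time-lagged independent component
   analysis (tICA: generalized eigenproblem C(τ)v = λC(0)v), HDBSCAN
   density clustering with per-cluster microstate composition,
   free-energy reweighting of boosted (accelerated-MD-style) sampling by
   second-order cumulant expansion
   F = −kT[ln p_b + β⟨ΔV⟩ + β²σ²_ΔV/2] + C, composition-preserving
   stratified frame sampling, and representative-structure selection.
4. **Quenching-site geometry** — chlorin-frame carotenoid displacement,
   coverage (covariance) ellipses, bond-length alternation (BLA).
5. **Excitonic couplings** — TrEsp point-charge couplings
   V = K_e Σ q_i q_j / r_ij (K_e = 116140 cm⁻¹·Å·e⁻²) with the customary
   empirical rescale factor (default 3.7, applied as division).
6. **Charge-separation energetics** — linear-response reorganization
   energies λ_X = σ²_X/(2k_BT) and free energies G_X = ⟨E_X⟩ − λ_X from
   vertical-energy fluctuations, nonadiabatic Marcus rates
   k = (2π/ħ) V² (4πλk_BT)^{−1/2} exp(−(ΔG+λ)²/4λk_BT), and a
   coarse-grained excitation-lifetime model of the chlorophyll pool with
   a CT sink (closed-form survival integral of the 2×2 master equation).

A first-class **synthetic-data module** generates every input with known
ground truth — an exactly solvable Ising-like model of coupled titration
(with an exhaustive-enumeration oracle), Gaussian energy series, biased
samples from known free-energy surfaces, and rigid toy pigment pairs —
so each estimator is validated end to end.

## Worked example

The built-in demo configuration emulates six constant-pH ensembles
(pH 3–8, two replicas of 600 frames) of a coupled acidic triad plus two
control residues, a three-microstate landscape under a known boost, and
cluster-level LE/CT energetics:

```python
from phquench.pipeline import demo_config, run_all

summary = run_all(demo_config(seed=1), "runs/demo")
```

or equivalently `phquench run --seed 1 --out runs/demo`. The summary
(also written to `runs/demo/summary.json`) contains, among others:

```
titration:   E114 -> coupled_undetermined        (nonmonotonic curve)
             E233 -> sensor_candidate, pKa 6.59  (shift +2.3 vs Glu 4.3)
             D118 -> non_sensor,       pKa 4.61  (shift +0.7 vs Asp 3.9)
microstates: dominant at pH 3 = PPP; at pH 8 = PDD
energetics:  CT-LE gap  CL2: 5149 cm^-1   CL5: 5539 cm^-1
             k_cs (1e9/s, CP29-like set)  CL2: 52.9   CL5: 24.6
             tau  (ps,    CP29-like set)  CL2: 2995   CL5: 3006
```

Reading the output: E114's titration curve goes *up and down* with pH —
the signature of proton sharing with its more acidic partner — so no
single-site pKa is reported and the site is flagged as coupled; E233's
pKa is shifted 2.3 units above the water reference, making it a
candidate lumenal pH sensor. The fully protonated microstate (PPP)
dominates at pH 3 and gives way to deprotonated patterns at pH 8. The
charge-transfer state sits ≈5000 cm⁻¹ above the chlorophyll Q_y
excitation in both conformational clusters, while the low-pH cluster's
larger coupling yields a charge-separation rate (V₁/V₂)² ≈ 2.2 times
faster, shortening the complex lifetime accordingly.

## Command line

`phquench` exposes thin subcommands over the library:

```
phquench run          --seed 1 --out runs/demo      # full pipeline
phquench titrate      --traj-dir <dir> --sites E114,E227 --out fits.csv
phquench microstates  --traj traj.csv --triad E114,E227,E233 --out net/
phquench couple       --pairs manifest.csv --rescale 3.7 --out V.csv
phquench rates        --couplings V.csv --lambda-sets lam.json --out rates.csv
```

All file formats are plain CSV/XYZ/JSON (see `phquench.io`).

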