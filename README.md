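# cectkit

Contrast-enhanced micro-CT (CECT) analysis of nanoparticle diffusion into
articular cartilage, packaged as a tested, reusable pipeline.

Cationic contrast agents diffuse into cartilage because its proteoglycans
(PGs) carry fixed negative charge; neutral agents stay outside and instead
pool in surface defects. CECT therefore probes both cartilage composition
(how much agent enters, and how fast) and surface integrity (where an
excluded agent accumulates). `cectkit` implements the complete analysis a
CECT cartilage study needs — and, because such studies run on cadaver or
animal tissue with no public raw data, it ships a synthetic
osteochondral-plug phantom generator with exact ground truth, so every stage
is validated end to end without any real scans.

For image analysts and cartilage biomechanics researchers who want a
scriptable, reproducible version of this workflow, or a testbed for
variations of it.

## What it computes

**Partition profiles.** A plug volume is surface-aligned, segmented by
attenuation thresholds, and reduced to the mean attenuation of a 1.2 mm ROI
per depth slice, interpolated to a fixed 100-point normalized-depth grid.
Subtracting the 0 h (pre-immersion) profile and dividing by the bath
attenuation gives the depthwise partition in percent:

    partition(z, t) = 100 · [A(z, t) − A(z, 0)] / A_bath

**Uptake kinetics.** Bulk partition over immersion time follows exponential
saturation,

    P(t) = P_max · [1 − exp(−t/τ)]

with maximum partition `P_max` and diffusion time constant `τ` (time to
63.2 % of `P_max`), fitted per sample by nonlinear least squares and
averaged across a cohort with t-based 95 % CIs.

**Indentation biomechanics.** Stress-relaxation (4 × 4 % steps, 600 s holds,
100 %/s ramps) and sinusoidal (1 Hz, 4 % peak-to-peak) records yield the
equilibrium modulus `E_eq` (ν = 0.2), strain-dependent instantaneous modulus
`E_inst` (ν = 0.5), stretched-exponential relaxation parameters (α, β) from
`σ(t) = σ_eq + Δσ·exp[−(t/α)^β]`, and the dynamic modulus and phase shift.
All moduli use the Hayes correction `E = P(1−ν²)/(2aκw)` for a flat punch on
a bonded layer; κ(a/h, ν) is computed from the layered-contact integral
equation (see `docs/methods.md`).

**Densitometry.** Safranin-O section images are converted gray → optical
density through a linear calibration against imaged neutral filters
(OD 0.0–3.0), averaged depthwise over three sections, and summarized as bulk
(1–100 % depth) and superficial (1–30 %) PG content.

**Statistics.** Shapiro–Wilk normality gate, then Spearman ρ with Fisher-z
95 % CIs (exact permutation p for n ≤ 9) between diffusion characteristics
(`P_max`, τ) and structural/functional parameters, rendered as a signed,
significance-flagged table.

## Worked example

```bash
cat > run.yaml <<EOF
seed: 1
output_dir: out
analysis:
  bath_hu: 1200.0
EOF
cectkit run --config run.yaml
```

This simulates a demo plug series (8 time points, 0–72 h), a 27-sample
coupled cohort, indentation records and densitometry sections; analyses all
of them; and writes CSVs, figures and `out/report/summary.json`:

```json
{
  "cohort_pmax_mean_pct": 56.98,
  "cohort_tau_mean_h": 62.24,
  "dynamic_modulus_mpa": 5.241,
  "e_eq_mpa": 0.501,
  "phase_shift_deg": 17.44,
  "sample_pmax_pct": 56.25,
  "sample_tau_h": 62.9,
  "significant_correlations": 3
}
```

Reading: the demo sample's fitted uptake plateau is ≈56 % of the bath
concentration with a ≈63 h time constant (the phantom's generating values
are 56.49 % and 62.85 h — the pipeline recovers them through the full image
chain); the cohort means agree with 95 % CIs of roughly ±6 % and ±11 h at
n = 27; the indentation analysis returns the generator's 0.5 MPa equilibrium
modulus and 17.4° phase shift; and 3 of the 8 structure–function rank
correlations are significant at this seed. `out/stats/correlations.md`
holds the shaded correlation table, `out/report/provenance.json` the config
hash, seed, versions and stage timings. Re-running with the same config and
seed reproduces every CSV byte for byte.

The same stages are available individually (`cectkit simulate`,
`analyze-diffusion`, `fit-kinetics`, `analyze-biomech`, `densitometry`,
`correlate`, `report`) and as library functions.

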