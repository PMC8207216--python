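# puckerfit

Analysis toolkit for studies of abasic (AP) nucleotides and the enzymes
that process them — in particular the comparison of ribose vs deoxyribose
abasic sites in the APE1 endonuclease active site. It covers the three
quantitative layers such a study needs:

1. **Sugar pucker.** The conformation of a furanose ring is summarised by
   the Altona–Sundaralingam pseudorotation phase *P* and amplitude
   *ν*<sub>max</sub>, computed from the five endocyclic torsions
   ν₀…ν₄ (ν₀ = C4′-O4′-C1′-C2′, …, ν₂ = C1′-C2′-C3′-C4′):

       tan P = (ν₄ + ν₁ − ν₃ − ν₀) / (2 ν₂ (sin 36° + sin 72°))

   with 180° added when ν₂ < 0 (implemented via `atan2`, which is
   identical where ν₂ ≠ 0 and stable at ν₂ = 0). Phases near 18° are
   C3′-endo (RNA-like, northern hemisphere of the wheel), near 162° are
   C2′-endo (B-DNA-like, southern). Rings can come from multi-model PDB
   files (crystal structures or trajectory snapshots) or from plain TSV
   torsion tables; ensembles are summarised with circular statistics and
   hemisphere / named-bin occupancies.

2. **Pre-steady-state kinetics.** Multiple-turnover product formation is
   biphasic, `product = A(1 − e^(−k_obs·t)) + v_ss·t`; the steady-state
   rate constant is derived, `k_ss = v_ss / A`, never fitted.
   Single-turnover courses use the pure exponential. Fitters are
   scikit-learn-style estimators (`BurstKineticsModel`) with
   replicate-aware standard errors.

3. **Equilibrium binding.** Titrations (EMSA-style, fraction of probe
   bound vs total protein) are fit with the quadratic tight-binding
   isotherm AB = [A_T + B_T + K_D − √((A_T+B_T+K_D)² − 4 A_T B_T)]/2 to
   yield K_D,app (`TightBindingModel`).

A synthetic-data module generates every input with known ground truth —
torsion sets and 3D rings at a prescribed phase, von Mises pucker
ensembles, noisy time courses and titrations — so the full pipeline runs
and is testable without any external data.

## Worked example

```python
import puckerfit as pf

# --- sugar pucker of one nucleotide across a trajectory ---------------
spec = pf.PuckerMixtureSpec(components=((19.0, 50.0, 0.8),
                                        (160.0, 50.0, 0.2)),
                            n=10_000, seed=42)
traj = pf.gen_pucker_trajectory(spec)                # ground truth known
states = [pf.pseudorotation_phase(pf.TorsionSet(*row))
          for row in traj.torsions]
dist = pf.pucker_histogram(states)
print(dist.hemisphere_fractions)
# {'northern': 0.7947, 'southern': 0.2053}

# --- burst kinetics ---------------------------------------------------
tc = pf.gen_time_course(25.0, 2.3, 7.5, noise_sd=0.5, seed=3)
fit = pf.fit_multiple_turnover(tc)
print(f"k_obs = {fit.k_obs:.2f} /s, k_ss = {fit.k_ss:.3f} /s")
# k_obs = 2.26 /s, k_ss = 0.299 /s

# --- binding affinity -------------------------------------------------
titr = pf.gen_titration(3.0, 2.0, noise_sd=0.03, seed=4)
print(f"K_D,app = {pf.fit_kd_app(titr).k_d_app:.2f} nM")
# K_D,app = 3.06 nM
```

The hemisphere fractions recover the 0.8/0.2 mixture weights; the kinetic
fit recovers the generating burst rate (2.3 s⁻¹) and steady-state rate
(0.30 s⁻¹) from 2%-noise data; the titration fit recovers the nanomolar
dissociation constant.

The same pipeline is scriptable from the shell:

```sh
puckerfit simulate trajectory --seed 11 --n 1000 \
    --components 19:50:0.8,160:50:0.2 --out-prefix run/traj
puckerfit pucker run/traj_torsions.tsv --torsion-table --residue 7 \
    --out-prefix run/pucker
puckerfit distribution run/pucker_series.tsv --out-prefix run/dist
```

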