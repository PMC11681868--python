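# phosphorec

Analysis toolkit for **how antibodies recognise a phosphorylated serine
epitope**: post-processing of MD trajectories and crystal structures of
antibody/phosphopeptide complexes, plus ITC-derived binding thermodynamics.

Anti-phosphosite antibodies achieve nanomolar affinity and thousand-fold
phospho/non-phospho selectivity with a paratope built from one arginine and
a few uncharged polar residues. `phosphorec` quantifies the structural and
dynamic signatures behind that behaviour:

* **Phosphorus contact frequencies** — a residue interacts with the
  phosphoserine in a frame when any of its atoms lies strictly within
  4.0 Å of the phosphorus atom; percentages are computed per replicate
  (after discarding the leading 20 % of each run as equilibration) and
  averaged across replicates.
* **Hydrogen bonds and the bidentate clamp** — donor/acceptor heavy atoms
  within 3.5 Å; a frame is *bidentate* when two distinct guanidinium
  nitrogens (NE/NH1/NH2) of an Arg bond two distinct terminal phosphate
  oxygens simultaneously. The clamp is what pins the phosphate group.
* **Phosphate rotation dynamics** — the CB–OG–P–OT torsion tracked per
  frame; circular distributions, watershed peak detection, hard-core
  rotamer-state assignment with an unassigned buffer, hysteresis-filtered
  120° rotation events and dwell-time statistics. In the unprotonated
  PO3²⁻ state the three terminal oxygens are equivalent (3-fold symmetry);
  in singly protonated PO3H⁻ they are chemically distinct.
* **Binding thermodynamics** — ΔG = RT ln K_D, TΔS = ΔH − ΔG
  (R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹, T = 298.15 K), mutant fold changes
  K_D(mut)/K_D(wt) and phospho/non-phospho selectivity ratios, with a typed
  "no measurable binding" sentinel.
* **A ground-truth trajectory generator** — a minimal phosphoserine +
  arginine + partner-residue mimic whose rotamer jumps (continuous-time
  Markov chain), contact occupancies and clamp occupancy are prescribed
  exactly, so every analysis stage is testable without any external data.

## Worked example

```bash
phosphorec thermo | head -4
```

```
    clone    antigen   Kd_nM  dG_kcal  dH_kcal  TdS_kcal  dG_sd  TdS_sd    T_K
    A4 WT    phospho    3.34   -11.56    -24.4    -12.84   0.11    0.42 298.15
A4 H-S53A    phospho    3.55   -11.53    -24.9    -13.37   0.29    0.58 298.15
A4 H-S54A    phospho    6.95   -11.13    -23.5    -12.37   0.20    0.28 298.15
```

The wildtype A4 clone binds the phosphopeptide with K_D = 3.34 nM, i.e.
ΔG = −11.56 kcal/mol at 298.15 K; the large favourable enthalpy
(−24.4 kcal/mol) is partly paid back by an entropic penalty
(TΔS = −12.84 kcal/mol) — the signature of an enthalpically driven,
conformationally restrained complex.

The simulate → analyse loop on the rigid-clamp preset:

```bash
phosphorec simulate --preset C7-like --out sim/
phosphorec analyze-traj --topology sim/topology.pdb \
    --traj sim/replicate_0.pdb --traj sim/replicate_1.pdb --traj sim/replicate_2.pdb \
    --phospho-res A:8 --arg-res H:53 --out report/
```

prints `{"single_peak": true, "clamp_ge_0.95": true}`: the torsion
distribution has a single mode and the Arg clamp persists in ≥95 % of
retained frames — the behaviour of a highly selective binder, in contrast
to the `nonantibody-like` preset (three near-equal modes, frequent 120°
rotation events, rare clamp). `report/` contains `rmsd.tsv`,
`contacts.tsv`, `bidentate.tsv`, `dihedral.tsv`, `histogram.tsv`,
`kinetics.json` and `summary.json` with the exact thresholds echoed.

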