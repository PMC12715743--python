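# dfiscreen

Non-targeted LC–HRMS screening of parabens, their phase I/II metabolites and
related phenolic endocrine-disrupting chemicals (EDCs), built around
**diagnostic fragment ion** evidence rather than spectral-library lookup.

Parabens (alkyl/benzyl esters of 4-hydroxybenzoic acid) and their
ring-hydroxylated metabolites (alkyl protocatechuates) fragment under
negative-mode HCD through a conserved cascade — ester cleavage (m/z
137.0239 / 136.0160), decarboxylation to phenolates (93.0340 / 92.0262 /
91.0184), CO losses (108.0211, 95.0133) and the oxygen-shifted analogues for
protocatechuates (153.0188, 152.0110, 109.0290, …). Because every member of
the homologous series funnels into the same small set of product ions, those
ions act as a class fingerprint: a precursor whose MS2 contains **at least 4
diagnostic ions** (<10 ppm), at **≥3× the process-blank signal**, with a
plausible elemental formula (C 7–30, H 6–60, O 3–10, S 0–1, RDBE 5–10, 5 ppm)
is prioritized as a paraben-family candidate — including conjugates and
analogues that no library contains.

The package provides:

- `dfiscreen.chem` — monoisotopic mass arithmetic over C/H/D/N/O/S, the
  [M−H]⁻ convention (hydrogen-atom subtraction), ppm errors, RDBE, and
  bounded elemental-formula decomposition.
- `dfiscreen.fragments` — the fragmentation-pathway graph and diagnostic-ion
  registry (16 ions, mass-balanced edges), class screening sets, deuterated
  analogues and phase II conjugate masses (sulfate +79.9568, glucuronide
  +176.0321, glycine +57.0215).
- `dfiscreen.msio` — centroid mzML 1.1 read/write, extracted ion
  chromatograms (EICs) and chromatographic peak detection with MAD-based S/N.
- `dfiscreen.screen` — DDA precursor prioritization, the DIA (all-ion
  fragmentation) selection rule (full-scan intensity ≥10⁵ at CE 0 with a
  strictly decreasing 10/20/40 eV intensity series), and inclusion-list
  export (0.4 min RT windows).
- `dfiscreen.conjugates` — sulfate/glucuronide/glycine conjugate screening
  via the free-form fragment plus SO₃⁻•/HSO₄⁻ marker ions, and
  hydrolyzed-vs-unhydrolyzed speciation verdicts.
- `dfiscreen.rtmodel` — a linear QSRR retention-time model (RDKit 2D
  descriptors, forward stepwise leave-one-out selection, OLS).
- `dfiscreen.qaqc` — cosine spectral matching against an MSP library,
  Schymanski confidence levels (1 = standard-confirmed, 2 = ΔRT ≤ 1.0 min,
  3 = tentative), IDL/MDL estimators, recovery, matrix effect and RSD.
- `dfiscreen.simulate` — a seeded generator of DDA/DIA mzML runs of a
  spiked biofluid-like matrix (1–25 ng/mL spikes, process blanks,
  CE-dependent fragment profiles, benzophenone-like interference channels)
  with ground-truth manifests. All tests and acceptance numbers run on this
  generator; no instrument data are required.

## Worked example

Simulate a 25 ng/mL three-paraben spike with a matched process blank, then
screen it:

```bash
dfi simulate --out sample.mzML --mode DDA --seed 1 --level 25 \
    -c MeP -c EtP -c PrP --manifest truth.csv
dfi simulate --out blank.mzML --mode DDA --seed 2 --blank -c MeP -c EtP -c PrP
dfi screen-dda --sample sample.mzML --blank blank.mzML --inclusion-list inclusion.csv
```

Output (abridged):

```
      mz    rt  n_matched  matched_ions                               blank_ratio formulas   class
151.0395 5.892          5  A2@136.0160;B2@92.0262;B3@91.0184;C;E             inf   C8H8O3 paraben
165.0552 6.892          7  A1@137.0239;A2;B1@93.0340;B2;B3;C;E               inf  C9H10O3 paraben
179.0708 7.992          7  A1@137.0239;A2;B1@93.0340;B2;B3;C;E               inf C10H12O3 paraben
```

All three spiked parabens are prioritized. Methyl paraben matches only 5 of
the 7 paraben screening ions — it cannot lose an R-olefin, so the m/z
137.0239 ion and its CO₂-loss daughter at 93.0340 are structurally
unavailable — but still clears the ≥4-ion rule. Each candidate carries an
infinite blank ratio (no blank signal), a unique elemental formula, and an
inclusion-list row such as `151.0395, 5.692, 6.092` for targeted
reacquisition.

Fitting the retention model on the built-in 14-standard table:

```bash
dfi registry --standards --out standards.csv   # name, smiles, rt, ...
dfi fit-rt --training training.csv --out model.txt
# selected ['clogp', 'hba', 'hbd']; R2=0.9936 RMSE=0.231 min
dfi predict-rt --model model.txt --smiles "CCCCCOC(=O)c1ccc(O)cc1" --observed 10.3
# predicted 9.969 min, delta RT 0.331 min   -> confidence level 2 (ΔRT ≤ 1.0)
```

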