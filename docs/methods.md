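# Methods

This note documents the models and procedures implemented in `dfiscreen`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Mass conventions

All masses are monoisotopic (C 12 exactly, H 1.007825, D 2.014102,
N 14.003074, O 15.994915, S 31.972071 Da). The [M−H]⁻ m/z of a neutral is
its monoisotopic mass minus the mass of a hydrogen **atom** (1.007825 Da),
neglecting the electron. This convention reproduces published 4-decimal
fragment tables for this compound class (4-hydroxybenzoate at 137.0239
rather than the 137.0244 obtained by subtracting a proton) and carries a
systematic offset of ~0.00055 Da (the electron mass) relative to the
physically exact ion mass. At the 5–10 ppm tolerances used everywhere in
the workflow the offset is negligible (≈4 ppm at m/z 137 would be the
worst case if conventions were mixed; they are not — the same convention is
applied to theory and to simulated data).

RDBE is computed on the neutral-formula basis as C − (H+D)/2 + N/2 + 1.
Radical fragment ions are **not** RDBE-screened: the RDBE constraint
belongs to the precursor composition filter only, where even-electron
neutrals are the relevant hypothesis space.

## Formula decomposition

`decompose_mass` enumerates neutral CHOS formulas whose deprotonated mass
falls within the ppm tolerance of the query. The element grid is exhausted
exactly (hydrogen is solved from the mass window, which is algebraically
equivalent to full nested enumeration and verified against one in the
tests). Defaults follow the composition restrictions used for this chemical
space: C 7–30, H 6–60, O 3–10, S 0–1, RDBE 5–10, 5 ppm. The tolerance is
applied on the **ion** mass axis; whether such restrictions are stated for
neutral or ionic mass is ambiguous in common usage, and at 5 ppm the
difference (a constant 1.007825 Da shift in the reference point) changes no
decision in practice. Candidates are ordered by |ppm error|, then
even-electron (Senior-rule) validity, then Hill string, making results
deterministic and order-independent.

## The diagnostic-ion registry

The registry stores **ion compositions**, not m/z constants: every m/z,
deuterated analogue and conjugate mass is recomputed from formulas, and
each pathway edge (parent ion, neutral/radical loss, daughter) is
mass-balance-checked to 10⁻³ Da at construction. The encoded cascade:

| series | ions | mechanism |
|---|---|---|
| A | 137.0239 (A1), 136.0160 (A2) | heterolytic R-olefin / homolytic R• ester cleavage |
| B | 93.0340 (B1), 92.0262 (B2), 91.0184 (B3) | CO₂ loss from A1/A2, then H• loss |
| C | 108.0211 (C ≡ G2) | CO loss from the rearranged acyl species (A3) |
| D | 124.0160 (D1), 123.0082 (D2) | CH-loss branch shared between classes |
| E | 95.0133 (E) | CO loss from D2 |
| F/G | 153.0188, 152.0110, 109.0290, 107.0133 | the protocatechuate analogues (+O) |
| H/J/K | 139.0031, 111.0082, 83.0133 | CH-loss branch of the protocatechuate series |

A3 and F3 are mechanistic intermediates (rearranged forms at the same m/z
as A2/F2) and are flagged non-screening. Sixteen distinct m/z values are
observable; the registry is a plain table (CSV-exportable) so users can
extend it to other homologous series.

**Screening sets.** Common diagnostics for both classes: 91.0184, 95.0133,
108.0211. The paraben set adds 92.0262, 93.0340, 136.0160, 137.0239
(7 ions); the protocatechuate set adds 109.0290, 111.0082, 124.0160,
152.0110, 153.0188 (8 ions). The characteristic (observable) paraben set is
8 ions (the screening 7 plus D2 at 123.0082, which is too weak to be a
reliable screen). Methyl and benzyl paraben cannot undergo the heterolytic
R-olefin loss — methyl has no β-hydrogen and benzyl cannot form the olefin —
so A1 *and its sole daughter* B1 are excluded from their applicable sets,
leaving 5 screening ions. This is a deliberate design choice: B1 is reached
only through A1 in the encoded pathway graph, so excluding A1 alone would
leave the registry internally inconsistent. Both compounds still clear the
≥4-ion rule comfortably.

## DDA screening

ddMS2 scans are clustered by precursor m/z (5 ppm) and elution contiguity
(gaps >0.3 min split clusters). Diagnostic ions are counted as **distinct
labels matched anywhere in the cluster's scans across the CE scheme** —
fragment coverage is CE-dependent (ester-cleavage ions at 10–20 eV, the
phenolate family at 40 eV), so merging across collision energies is the
reading that makes a 3×CE acquisition scheme useful; shared-m/z ions
(C/G2) count once. Candidates need: ≥4 matched ions (<10 ppm), MS1 peak
≥3× the maximum corresponding blank height (EIC peak **height**, not area;
a zero-blank channel yields an infinite ratio and passes), and a non-empty
formula candidate list under the composition bounds. The class call is the
class whose screening set supplied ≥4 matches ("ambiguous" if both).
Benzophenone-like interferences — intense co-extracted channels that
fragment to m/z 91.0184 — are controlled purely by the ≥4-ion rule plus the
formula constraint; no exclusion list is used.

The co-elution window between diagnostic-ion evidence and the precursor
apex defaults to ±0.1 min, matching the instrument-stability RT-shift bound
a QC scheme would apply on a run of this length.

## DIA screening

All-ion fragmentation provides no precursor isolation, so candidate
precursors are reconstructed: (1) find retention times where any diagnostic
ion peaks in the per-CE AIF traces; (2) at each such time, take full-scan
ions with intensity ≥10⁵ (CE 0); (3) keep ions whose intensity sequence
across CE 0 → 10 → 20 → 40 eV is strictly decreasing — precursor survival
falls monotonically with collision energy, while fragments and background
do not. "Consistently decreased" is implemented as *strictly* decreasing at
every step with a configurable relative slack (default 0), since the
qualitative rule does not quantify tolerance. Blank-ratio, ≥4-ion and
formula constraints then apply as in DDA, and accepted candidates can be
exported as an inclusion list (m/z, apex ±0.2 min) for targeted ddMS2
reacquisition.

## Conjugate screening and speciation

Phase II conjugates are screened at the free-form [M−H]⁻ plus the
conjugation delta: SO₃ (+79.9568), C₆H₈O₆ (+176.0321, glucuronide) or
C₂H₃NO (+57.0215, glycine/hippurate — encoded from the hydroxyhippuric-acid
relationship, since glycine amidates the carboxyl). A hit requires the
free-form fragment (neutral loss of the moiety) **plus at least one further
evidence ion**: for sulfates the SO₃⁻• radical anion at 79.9568 or HSO₄⁻ at
96.9596 (this package's exact-mass rendering of the nominal m/z 80 and 97
markers), or any applicable diagnostic ion of the free form. Glucuronide
screening is always active even though sulfation dominates for this
chemical class — a zero glucuronide count is itself a reportable finding.

Hydrolyzed/unhydrolyzed comparison: fold change = hydrolyzed apex /
unhydrolyzed apex of the free-form MS1 EIC peak (infinite when the free
form appears only after hydrolysis). Verdicts: **predominantly_conjugated**
when fold ≥5 or the free form is undetected pre-hydrolysis while a
conjugate hit exists; **predominantly_free** when fold ≤1.5 with no
conjugate hit; **partially_conjugated** otherwise; **not_detected** when
absent from both runs. The 5×/1.5× thresholds are this package's
quantitative rendering of an inherently qualitative comparison; they are
arguments, not constants.

## QSRR retention model

Ten standard RDKit 2D descriptors (clogp, TPSA, MW, heavy atoms, HBD, HBA,
rotatable bonds, aromatic rings, ring count, fraction Csp³) form a fixed
pool. Forward stepwise selection minimizes closed-form leave-one-out RMSE
(hat-matrix identity), with lexicographic tie-breaking so the fit is
independent of row and column order; rank-deficient or ill-conditioned
additions are skipped. Ordinary least squares on the selected subset gives
the final affine model, serialized as a plain-text coefficient file.
LOO-based selection makes the model robust to the exact descriptor pool —
on the built-in 14-standard table it selects lipophilicity plus two
polarity counts (R² ≈ 0.99, RMSE ≈ 0.23 min on the synthetic retention
scale). The ΔRT between prediction and measurement feeds the confidence
rules: ≤1.0 min for level 2 by default, with the stricter 0.5 min variant
available as an argument.

## Spectral matching and QA/QC

The library match score is 100 × cosine similarity of
square-root-intensity-weighted peak vectors after greedy ppm-tolerance peak
pairing, best entry across collision energies. It is a transparent stand-in
for proprietary library-search scores, sharing their 0–100 scale and the
customary acceptance threshold of 70; it makes no claim of reproducing
their values. Self-matches score exactly 100.

- **IDL**: lowest calibration concentration with precursor S/N strictly
  greater than 3 (solvent standards).
- **MDL (upper bound)**: lowest spike level with MS1 signal ≥3× the process
  blank *and* a triggered, clear MS2 ("clear" operationalized as the ddMS2
  trigger firing with ≥3 fragment peaks above noise in the simulator).
- **Recovery / matrix effect**: the standard post-extraction-spike scheme —
  recovery% = 100 × (spiked − unspiked)/(post-extraction spiked − unspiked);
  ME% = 100 × (post-extraction spiked / solvent standard − 1), negative
  meaning suppression. Zero denominators yield NaN with an explicit
  undefined marker rather than an exception.
- **RSD**: 100 × sample SD / mean.

Chromatographic S/N uses 1.4826 × MAD of the trace outside detected peak
regions (floored at one count): detection-limit definitions of this kind
never specify the noise estimator, and MAD is robust to the peaks
themselves.

## The synthetic-data generator

The generator emulates the acquisition geometry of a Q-Exactive-type
negative-mode workflow: full scans 80–1000 m/z every 0.02 min; DDA with
top-5 selection above an intensity trigger (10⁵ analog), 1.5 Th isolation,
7 s dynamic exclusion and three ddMS2 scans (10/20/40 eV) per selection;
DIA with three AIF scans per cycle. Analytes elute as Gaussians (0.15 min
FWHM) with apex intensity = concentration × response factor (4×10⁴ per
ng/mL) × matrix suppression (0.85, i.e. 15% suppression — inside the
10–30% band typical of a cleaned-up biofluid matrix). With these defaults
the 1/5/25 ng/mL spike levels land at ≈3.4×10⁴ / 1.7×10⁵ / 8.5×10⁵:
1 ng/mL sits below the DDA trigger, reproducing the missed-trigger failure
mode of real low-level spikes, and 25 ng/mL sits well above every rule
threshold.

Fragment m/z values are drawn from the registry with Gaussian jitter of
σ = 2 ppm truncated at ±3σ, so ground-truth ions always stay inside the
10 ppm matching window; intensities carry Poisson counting noise.
CE-resolved fragment profiles are plain per-class dicts following the
qualitative HCD pattern (A/F ions dominant at 10–20 eV, B/C/E and G/J/K
families growing at 40 eV); per-compound structural exclusions are applied
automatically (MeP/BzP never emit A1/B1). The matrix contributes
exponential baseline peaks and benzophenone-like interference channels
(deprotonated hydroxybenzophenones at ≈6–8×10⁵) that trigger MS2 but
fragment only to 91.0184. Retention times of the 14 built-in standards are
synthetic, ordered by reversed-phase lipophilicity, and include the
MeP/OH-EtP and BzP/iPeP co-elution pairs.

**What passing tests show — and what they do not.** The simulator
reproduces the *logical* structure of the screening problem: trigger
economics, CE-dependent fragment coverage, blank contrast, interference
that defeats 1–3-ion rules, conjugate evidence patterns, and DDA/DIA
concordance. It does not model ion-optics or C-trap competition, profile
peak shapes, isotope patterns (beyond explicit deuterated species),
retention drift between runs, or realistic co-eluting metabolite
backgrounds of thousands of features. Recovery and false-positive rates
measured on it therefore validate the decision rules and their
implementation, not instrument-level sensitivity; sample-dependent
identification rates from real biofluid data are outside what desk-scale
synthetic runs can reproduce.

## Numerical and interface choices

- Retention times are minutes everywhere (gradients are specified in
  minutes); mzR-style second-based readers interoperate via the mzML unit
  attribute.
- mzML I/O is a self-contained mzML 1.1.0 layer (64-bit float arrays;
  uncompressed on write, zlib accepted on read), round-trip-tested and
  cross-validated against Bioconductor mzR. Profile-mode spectra are
  rejected loudly — the workflow operates on centroided data only.
- EIC windows are ppm-based, mirroring the ppm thresholds of the matching
  rules; a scan without a matching peak contributes zero intensity.
- Determinism: a single integer seed fixes every simulated byte; screening
  and fitting are deterministic given their inputs.

## Known limitations

- The registry covers the paraben/protocatechuate/phenolic-acid chemical
  space; other EDC classes (bisphenols, halogenated phenols) do not share
  the fragmentation fingerprint and need the library-matching route, for
  which only the transparent cosine stand-in is provided.
- DIA candidate reconstruction pairs precursors and fragments by retention
  time and CE-monotonicity only; full spectral deconvolution of complex
  DIA data is out of scope.
- Positive-mode ionization, adducts other than [M−H]⁻, and isotopic fine
  structure are not modelled.
- Quantitative NTA (calibration-transfer or descriptor-based concentration
  estimation) is not attempted; the workflow is qualitative.
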