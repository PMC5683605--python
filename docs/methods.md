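# Methods

## The measurement this package models

Metallocarboxypeptidases remove single C-terminal residues from peptides.
To profile specificity across many substrates at once, a peptide library is
split into five aliquots, each incubated with a different enzyme amount (or
enzyme variant), and each aliquot is then labeled on its free amines (the
N-terminus and every Lys side chain) with one of five isotopologues of the
TMAB tag: D0, D3, D6, D9 (0/3/6/9 deuteriums) and D12 (9 deuteriums plus
three ¹³C).  Pooled and run on LC-MS, one peptide yields a set of five MS1
peaks whose relative heights report its abundance under each condition.  A
peptide consumed by the enzyme shows a dose-dependent decrease; a cleavage
product shows a dose-dependent increase.

## Mass and label model

Residue masses are a frozen table of standard monoisotopic values (5
decimals) in `constants.py`; peptide mass = residues + water (18.01056 Da)
plus modification deltas (acetyl +42.01057, Met-ox +15.99491).  The TMAB
tag transferred to an amine is the cation C₇H₁₄NO⁺, 128.10753 Da; the
channel steps per tag are 3.01883 Da (3×(²H−¹H)) and, between D9 and D12,
3.01007 Da (3×(¹³C−¹²C)).  These values are derived from standard atomic
masses; only the relative spacings matter for peak-set geometry.  Because
the quaternary ammonium is permanently charged, each tag contributes one
charge; observed m/z at charge z with t tags is
`(labeled_mass + (z − t)·proton)/z`, which leaves channel spacing at
`t·step/z` regardless of the bookkeeping convention.

Expected charge counts Lys + Arg + a free N-terminus.  His is excluded by
default (flag available) because His-containing peptides — like Cys- and
Tyr-containing ones — react with label impurities and are dropped from
quantification.  Observed charges at or below the expected charge are
accepted during matching, since multiply basic peptides are routinely
observed at lower charge states than the counting rule predicts.

## Detection, validation and ratios

Detection predicts the 5-channel pattern for each library peptide at each
admissible charge and takes the nearest centroid within 50 ppm per channel
(ties toward lower m/z); a set needs ≥2 matched channels, and the
best-supported charge state is kept so each peptide is reported once.
Identification validation applies: parent mass within 50 ppm; tag count
equal to the free-amine count; charge admissible; and, when MS2 is
available, ≥80% of the major fragments (top-20 peaks or ≥5% of base peak)
matching the b/y series with at least five matches.  Without MS2 the
fragment rule is reported "not evaluated" and the remaining gates decide.

Ratios divide each condition's channel intensity by the no-enzyme control.
The control must exceed background (default: the run's 5th intensity
percentile; the choice is configurable because "background" is
instrument-dependent); a sub-background numerator or a ratio below 0.10 is
censored at the floor 0.10, and ratios above 5.00 are censored at the cap.
Apex centroid intensity is used per channel (not summed envelopes).

## Classification and profiling

On the ratio at the highest enzyme amount: good substrate ≤0.40 (≥60%
decrease), weak in (0.40, 0.80], non-substrate above 0.80; thresholds are
closed at the printed boundary values (a 1e-9 epsilon guards float
round-off).  A profile rising to ≥1.5× and non-decreasing across enzyme
amounts (15% relative slack, so multiplicative noise does not break strict
monotonicity) is a product.  The partial decrease expected at intermediate
enzyme amounts is recorded as a `dose_consistent` flag rather than used as
a veto, since reference good substrates include rows with essentially no
intermediate decrease.

Domain preference uses the intensity remaining with only domain I active
(the E762Q mutant) over only domain II active (E350Q).  Calls: ≤0.50 →
domain I preferential, ≥2.00 → domain II preferential, otherwise shared.
The cutoffs are not dictated by the reference tables but reproduce every
qualitative call derivable from them.  Censoring propagates as a
raw-intensity ratio would: censored-low numerator → "<0.10", censored-low
denominator → ">5.00", both → indeterminate (reported shared, flagged).

P1′ profiles tally C-terminal residues per category; P1 profiles tally the
penultimate residue and count only peptides whose P1′ is Lys or Arg, the
residues a basic-specific carboxypeptidase can engage.  Product peptides
are located in the precursor sequences and the cleaved residue is the one
immediately downstream; multiple placements are all reported and flagged
ambiguous.

## Kinetics

`fit_mm` minimizes least squares for v = Vmax·S/(Km+S) with
Levenberg–Marquardt on log-parameterized (Vmax, Km), which enforces
positivity without constraints; standard errors are mapped back by the
delta method.  Default start: Vmax₀ = max rate, Km₀ = median S.  Units are
centralized in `enzyme_nM_to_uM`: Km in μM, kcat in s⁻¹ via
kcat = Vmax/[E]; an explicit calibration factor converts arbitrary signal
rates to μM/s because fluorescence assays do not fix this conversion.
Degenerate inputs (all-equal or all-zero rates) return an unconverged fit,
mirroring "not detectable" reporting for the inactive double mutant.  The
assay's initial-rate validity condition (≤20% substrate consumption) is a
design assumption of the data, not modeled.  pH profiles are normalized to
max = 100%; the half-max range defaults to the outermost measured grid
points ≥50% (interpolated crossings available as an option).

## Docking pose filter

Pose correctness is purely geometric: heavy-atom, mass-weighted COMs of the
pose's P1′ and P1 residues must lie within the cutoff (default 10 Å) of the
COMs of the receptor's S1′ and S1 pocket residues.  Hydrogens are excluded
(pose files typically omit them) and the pocket COM uses the whole residue
(backbone + side chain).  Residue numbering follows the input receptor
file.  The score is percent correct over all supplied poses; the reference
protocol retains 101.  The rank statistic correlates percent-correct with
cleavage extent (1 − ratio) via Spearman, so +1 means better-docked
peptides are better substrates.

## Synthetic data: what it emulates and what it does not

The generator encodes the study's qualitative findings as ground truth:
cleavage only of C-terminal Lys/Arg; a veto on Pro/Asp/Ile at P1; an
Arg-skewed P1′ preference for domain I and comparable Lys/Arg handling for
domain II.  Enzyme response is `ratio(E) = (1−eff) + eff·exp(−E/E50)` with
per-peptide E50 ~ U(2, 20) nM over the titration 0/0.1/1/10/100 nM; this
endpoint-matching form is an invented interpolation — the reference data
constrain only the endpoints.  Cleavage efficiencies are drawn per true
category from fixed bands (good 0.75–0.95, weak 0.35–0.50, non 0–0.08),
placing expected max-enzyme ratios at least ~0.10 from the 0.40/0.80
decision boundaries; with the default 5% channel CV (≈7% CV on a ratio)
misclassification is then rare but not impossible.  Intensity noise is
log-normal and multiplicative with mean 1.  Products gain
`1 + 2.5·eff·(1−exp(−E/E50))`.

Round-trip tests and the acceptance script use 200-peptide experiments —
large enough for stable category counts while keeping the default test run
in seconds.  Synthetic spectra place peaks at exact predicted m/z (no mass
error, no retention time, no isotope envelopes, no charge-state envelopes,
no label-efficiency loss).  Passing round trips therefore demonstrates the
correctness of the detection/quantification/classification logic, not
robustness to real instrument artifacts such as chimeric peaks, m/z
calibration drift or co-elution.

The packaged five-protein precursor FASTA contains synthetic scaffold
sequences constructed so trypsin digestion (≤2 missed cleavages) yields the
reported peptides with correct precursor attribution (the two human globin
entries carry the canonical mature chain sequences); positions are
fixture-relative, not database coordinates.

## Known limitations

* No de-novo or open database search; identification is closed-library.
* No retention-time dimension; peak sets are matched in m/z only.
* Censored ratios enter classification at their floor/cap values; interval
  information is retained only as flags.
* The dI/dII ratio computed from censored per-condition ratios can differ
  in magnitude (never in call) from one computed from raw intensities.
* The docking filter consumes poses; it performs no docking, scoring or
  minimization itself.
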