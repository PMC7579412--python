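# Methods

This note records the scientific and numerical choices behind `ddgbench`:
what each stage computes, the defaults and why, what the synthetic data do
and do not emulate, and the places where the design was genuinely open.

## Sign conventions and units

ΔΔG is the change in folding free energy upon point mutation in kcal/mol,
with **positive = destabilizing**. Predictor output may be on another
affine scale (e.g. Rosetta Energy Units); every evaluation and aggregation
entry point accepts a `(slope, intercept)` rescale, defaulting to the
identity. The rescale is applied *before* classification, because the
±1 kcal/mol class boundaries are physical, not predictor-relative.

## Mutation taxonomy

Nine residue classes underlie the taxonomy:
Small `GAVSTC`, Large `FYWKRHQE`, Negative `DE`, Positive `RK`,
Polar `YTSHKREDQN`, Non-charged polar `YTSNQH`, Hydrophobic `FILVAGMW`,
Cysteine `C`, Proline `P`. Classes overlap (H is large, polar and
non-charged polar) and do not cover every residue with a size class
(D, N, I, L, M, P are neither Small nor Large).

A mutation receives a **multi-label** category set:

- one directional polarity label X→Y when the wild type is in X and the
  mutant in Y, for X, Y among {Positive, Negative, Non-charged polar,
  Hydrophobic} (these four sets are pairwise disjoint, so at most one
  directional label applies; the 12 cross pairs plus the two like-to-like
  pairs NCP→NCP and H→H are categories);
- *Charge to charge* for same-sign swaps only (K↔R, D↔E) — opposite-sign
  swaps already have their own directional labels;
- *Involves proline* / *Involves cysteine* when either residue is P/C;
- *Small to large*, *Large to small*, or *Same size* when both residues
  carry size classes; mutations where either residue lacks one get no size
  label;
- *Buried*/*Surface* copied from a structural burial call when available;
- *Everything* always.

Stability classes: stabilizing ΔΔG ≤ −1 kcal/mol, destabilizing
ΔΔG ≥ +1 kcal/mol, neutral in between, with **both boundaries inclusive**;
ordinal scores 2/1/0 and classification error = |Δscore|, so 2 marks a
stabilizing↔destabilizing confusion ("egregious").

## Structural filters and burial

**Foreign contacts.** A mutated residue is rejected when any of its heavy
atoms lies within 5 Å (inclusive) of a *foreign* atom: any atom on another
chain, or any non-water HETATM on any chain — so same-chain ligands count,
while water (HOH/WAT/DOD) never does. The rationale is that such mutations
report on binding as well as folding energetics. Hydrogens are ignored
everywhere (most crystal structures lack them; uniformity beats the tiny
precision gain).

**Burial.** Relative solvent accessibility is the residue's summed atomic
SASA divided by a published theoretical maximum per residue type (Tien et
al. 2013 values, Å²). SASA is Shrake–Rupley sphere sampling (via biotite)
with probe radius 1.4 Å, 960 points per atom, and element-based van der
Waals radii (C 1.70, N 1.55, O 1.52, S 1.80; 1.80 fallback). Because the
reference maxima are tabulated in Gly-X-Gly context, an isolated residue
can exceed them; the ratio is capped at 1. A residue is **Buried** when
relative SASA ≤ 20%, **Surface** above — and burial is computed on the
*isolated mutated chain* (after stripping away all other chains, waters
and heteroatoms), consistent with the monomer-folding framing. Tests check
the production SASA against an independent random-sphere-sampling oracle
to within 5%.

PDB handling: model 1 only; for alternate conformations the
highest-occupancy altloc is kept, ties broken alphabetically.

## Curation pipeline

Fixed order: row validation (single point mutations with canonical
residues and finite ΔΔG) → structural filters → homology deduplication →
category balancing. Re-running the pipeline on its own output is a no-op,
and every removal is logged with a stage and reason rather than silently
dropped.

**Deduplication.** Parent chains are clustered by single linkage at ≥ 60%
global sequence identity (identities / alignment length, Needleman–Wunsch
with match 1, mismatch 0, gap open −1, extend −0.1 — simple and
reproducible; identity at these levels is insensitive to the exact gap
scheme). Within a cluster, records sharing (position, wild type, mutant)
collapse to one; positions are compared after alignment mapping onto a
cluster reference when sequences are available, since homologs often
differ in author numbering, and by raw numbering otherwise. The survivor
is the measurement at pH closest to 7; ties break toward the lower pH,
then first occurrence; records without a pH are treated as pH 7 for
selection only and flagged in the log. Different mutations at the same
site always survive independently.

**Balancing.** Each *narrow* category (the 14 polarity pairs, charge to
charge, involves proline, involves cysteine) is filled to
min(cap, available) with cap = 50 by default. Small to large, Large to
small, Buried, Surface and the pure aggregates receive no dedicated fill —
they are supersets populated by the narrow selections. Narrow categories
can overlap (C↔P mutations are both *Involves cysteine* and *Involves
proline*), so a candidate is only picked if it does not push any of its
narrow categories past the cap. When a category has more candidates than
slots, selection is a seeded random draw stratified by parent cluster
(cycling clusters in shuffled order, one pick per visit) so entries spread
across unrelated proteins instead of piling onto the most-studied one.
The draw is deterministic given the seed.

**Composition null.** Expected category frequencies under random
mutagenesis draw the wild type from the parent amino-acid composition and
the mutant uniformly from the 19 alternatives; expectations are obtained
by brute-force summation of the classifier over all 380 ordered pairs
(under a uniform composition, e.g., hydrophobic→hydrophobic is
(8/20)·(7/19) ≈ 14.7%). This is the simplest null consistent with
"mutations chosen at random from the starting structures".

## Metrics

All metrics join experiment and prediction by record id and are reported
per category, per replicate, with cross-replicate mean ± sd (sd uses
ddof = 1, and is 0 for a single replicate). Undefined values — n < 3 or
zero variance for Pearson, all-equal experimental values for PI, a
degenerate confusion marginal for MCC — are carried as NaN and rendered
`NA`, never as 0, because 0 is a meaningful value for every one of these
statistics.

- **Filtered Pearson** removes the ⌊n·f⌋ entries with largest
  |prediction − experiment| before correlating (f = 0.10 by default,
  configurable). Among tied errors the earlier record is dropped first,
  which makes the statistic deterministic in record order. This
  "drop-the-gross-outliers" reading is a convention; the fraction is
  exposed precisely because other readings exist.
- **Predictive Index** is evaluated over all pairs with weights
  w_ij = |ΔΔG_j − ΔΔG_i| and concordance c_ij ∈ {+1, 0, −1}; tests verify
  exact agreement with a brute-force enumeration for n ≤ 12.
- **MCC** defaults to the ternary (3×3) generalization
  (c·s − Σ p_k t_k) / √((s² − Σ p_k²)(s² − Σ t_k²)); a binary
  stabilizing-vs-not mode is available for comparability with binary
  reports. On two classes the formula reduces to the classical binary MCC.
- Classification percentages (same / off by one / off by two) partition
  100% by construction and are printed to one decimal.

## Run aggregation

A ΔΔG engine produces a stream of model energies per variant in generation
order. `converge` consumes models one at a time and stops as soon as the
two lowest energies seen so far differ by ≤ 1.0 energy units (tolerance
over *all* consumed models, not consecutive ones — it is the gap between
the best and second-best structure that certifies convergence), or after
5 models; the returned energy is the minimum of the consumed prefix, so
early stopping is well defined: appending further models to a converged
stream cannot change the result. ΔΔG = converged(mutant) −
converged(wild type). A legacy mode reproduces the older fixed protocol
(mean of exactly 3 models per variant) for comparison runs; the two modes
agree exactly on constant streams.

## Synthetic data: what it emulates, what it does not

The generator exists so every stage is exercised end-to-end with known
ground truth:

- **Mutation tables** place each mutation on a randomly generated parent
  sequence at a site whose residue matches the wild type, with a
  controllable per-category mix (realized by sampling residue pairs that
  carry the requested label). Experimental ΔΔG is drawn from a 3-component
  Gaussian mixture with means −1.5 / 0 / +1.5 kcal/mol and sd 0.5, so all
  three stability classes are populated and the class boundaries are
  genuinely tested; mixing weights default to 0.15 / 0.35 / 0.50
  (stabilizing / neutral / destabilizing), the destabilizing-skewed shape
  typical of point-mutation stability data.
- **Predictions** are slope·ΔΔG + intercept + N(0, σ²), which gives the
  metrics a closed-form target: Pearson's r should approach
  σ_exp/√(σ_exp² + σ²), and tests check this at n = 2000 within three
  standard errors.
- **Structures** are ideal α-helices (Cα radius 2.3 Å, rise 1.5 Å/residue,
  100°/residue; N, C, O, Cβ placed geometrically, no side chains beyond
  Cβ): a two-chain fixture with controllable axis separation exercises the
  5 Å foreign-contact rule, and a packed pseudo-atom core (verified at
  generation time to contain a residue with relative SASA ≤ 0.20 and one
  ≥ 0.5) exercises burial. Parent structures for curation runs are
  single-chain helices carrying the parent sequence.

What passing tests on these data *do not* show: real proteins have packed
tertiary structure (synthetic parents are open helices, so curation runs
label essentially everything Surface), experimental ΔΔG has
heteroscedastic, lab-dependent error rather than clean Gaussian mixtures,
real predictors have structured (not i.i.d.) errors, and homologous
parents in real data share partial, gapped identity rather than the
clear-cut identical/unrelated split generated here. The synthetic route
validates the machinery and the statistics, not any predictor's accuracy
on real mutations.

## Problem sizes

The acceptance script (`scripts/acceptance.py`) uses 1,200 mutations over
10 parents of 120 residues, a cap of 50, prediction noise 0.5 kcal/mol and
3 replicates — large enough that every narrow category reaches its cap and
the balancing, dedup and metric paths are all exercised, while the whole
run stays within seconds. The test suite uses smaller instances of the
same generators.

## Known limitations

- mmCIF input, biological-assembly expansion, and multi-mutation records
  are out of scope; structures must be single-model PDB files.
- The balancing rule among >cap candidates (stratified seeded sampling) is
  one defensible choice among several; benchmarks built with different
  rules will differ in membership while satisfying the same category
  counts.
- Sequence identity uses one fixed alignment parameterization; borderline
  clusters near the 60% threshold could differ under other scoring
  schemes.
- Burial ignores hydrogens and side-chain atoms beyond those present in
  the input; relative SASA inherits whatever incompleteness the deposited
  structure has.
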