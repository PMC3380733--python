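# Methods

## Problem setting

A tandem mass spectrum is a list of fragment m/z–intensity peaks recorded
for one selected precursor ion. In a typical low-resolution dataset most
scans do not come from a cleanly fragmented peptide; they carry little
signal and are unidentifiable by any search engine. `msqc` scores each
spectrum with a probability of being "high quality" (worth searching) using
no labels at all: the only inputs are the peak lists themselves.

## Features

Ten per-spectrum features are computed (see README for the list). Design
choices the definitions leave open were fixed as follows:

- **Mass table.** Monoisotopic residue masses of the 20 standard amino
  acids, taken from pyteomics; Leu/Ile coincide and Gln/Lys nearly so — a
  peak pair whose gap matches several residues counts once. Water, ammonia,
  CO, NH and the proton likewise come from pyteomics' atomic data.
- **Tolerance.** All pair comparisons use an inclusive ±0.5 Da window,
  appropriate for ion-trap resolution, overridable via YAML config.
- **Normalized intensity.** NormI(x) = intensity(x) / total intensity of
  the spectrum. (A rank-based normalization would also fit the definition
  of the Good-Diff fraction; plain proportions were chosen for simplicity
  and scale invariance.)
- **Complementarity target.** Two singly-charged peaks are complementary
  when their m/z values sum to the *uncharged precursor mass*
  (precursor_mz·z − z·proton). Two alternative bookkeeping conventions are
  exposed via `MassConstants.pair_sum_convention`: the singly-protonated
  precursor mass (`"protonated"`) and the b+y ion-pair sum, neutral mass +
  2·proton (`"by_pair"`). The default keeps the package's worked fixture
  arithmetic exact.
- **f1 capping.** A peak participating in several complementary pairs
  contributes its NormI once per pair; the literal sum is then capped at
  1.0 so f1 remains a fraction. The Good-Diff fraction (f5) is not capped;
  with disjoint pairs it is bounded by 2.
- **Degenerate spectra.** Pair features of spectra with fewer than two
  peaks (and f9 with fewer than three) return 0 with a logged warning
  rather than raising, so batch processing never aborts.
- **f9** uses the sample (n−1) standard deviation.
- **Pair search.** Implemented with `searchsorted` windows and prefix sums
  over the sorted peak list; the contract — equality with a brute-force
  O(p²) double loop — is asserted in the tests on random spectra.

Spectra are canonicalized at read time: peaks sorted by m/z, exact
duplicate m/z merged with summed intensity, zero-intensity peaks dropped.
This makes "number of pairs" well defined and every feature independent of
input peak order.

## Voting and consensus

Each feature votes the top p% of spectra (by descending value) high
quality; the count is ceil(n·p/100) and boundary ties break by input
position (stable sort), making the pipeline deterministic. The default
p = 50 assumes nothing about the true class balance; it deliberately
over-retains, and the consensus probability is what orders spectra within
the retained half.

The consensus cost is jointly convex and quadratic in each block, so the
alternating exact minimizations converge to a stationary point of the
constrained problem; because the updates are averages of simplex rows
(anchored to the one-hot Y), feasibility never needs to be projected —
the solver instead *validates* Y on input and asserts row-stochasticity and
cost monotonicity at every iteration. The stopping rule is
‖U^t − U^{t−1}‖_F ≤ ε with ε = 1e-6 and a 1000-iteration cap; hitting the
cap flags `converged=False` on the result rather than raising. On all
tested instances the rule fires within tens of iterations. The fixed point
can be checked independently: substituting the U-update into the Q-update
gives the linear system (diag(α+d) − AᵀA/m)Q = αY, and the tests compare
the iterative solution against both this direct solve and a generic
box-constrained minimizer of the cost.

α trades off the initial votes against cross-feature smoothing: as α → ∞,
Q is pinned to Y and U becomes the per-spectrum fraction of high votes
(simple majority averaging); small α lets strongly coherent spectra
reshape the group probabilities. The default α = 90 keeps the groups close
to their votes while still breaking ties between spectra with the same
vote count. k is carried as a parameter in the math but fixed at 2
throughout the tool.

Hard calls use p_high ≥ threshold (default 0.5, boundary inclusive).

## Synthetic data

The generator exists so that every stage — I/O, features, voting,
consensus, evaluation — is testable with no external data, with known
planted labels.

High-quality spectra draw a random peptide (length 8–15, uniform residues),
emit the singly-charged b-ion ladder including the full-length acylium ion
(so even a dipeptide shows a residue-mass gap), and place each backbone
cleavage's complementary partner at pair-sum-target − b. With the default
neutral-mass target this shifts the y-series by 2·proton relative to strict
protonation physics; the simplification guarantees that planted
complementary pairs are detectable under whichever pair-sum convention is
configured, and leaves residue-ladder spacing untouched. Ions are dropped
independently with probability 0.2, water/ammonia-loss satellites added
with probability 0.3, m/z jittered with σ = 0.05 Da, fragment intensities
drawn lognormal (median 100, σ_log 0.4), and 5–40 low-intensity noise
peaks added.

Poor-quality spectra are pure noise: 20–70 peaks uniform over the
instrument's acquisition window (100–1700 Da — noise placement is
independent of the spurious precursor), a haystack of small intensities
with 1–4 dominant spikes, and a low neutral precursor mass (uniform
250–900 Da). Placing noise across the full scan range matters: tying the
noise window to the small precursor would make poor spectra several times
denser per Da than real noise and turn the pair-count features into
density artifacts.

Defaults are n = 1000 with 5% high quality, matching the heavy imbalance
of real ion-trap datasets. All randomness flows from the single `seed`
through one numpy generator.

What the generator does *not* emulate: multiply charged fragments, isotope
envelopes, correlated chemical noise, intensity structure along the ladder,
retention time. Passing the end-to-end recovery test therefore shows the
machinery is sound under the stated model, not that any particular ROC
number transfers to real instrument data — on real data the features
themselves are noisier and the separation is expected to be weaker.

## Evaluation

ROC curves threshold p_high with the ≥ convention on the grid
{0} ∪ {observed scores} ∪ {just above max}, so both corner points always
appear; TPR is the fraction of truly high spectra retained and
TNR = 1 − FPR the fraction of poor spectra removed. `tnr_at_tpr` reports
the best removal rate subject to a retention floor. `search_savings(h, n)`
= 1 − h/n is the fraction of database-search time saved by searching only
the h spectra called high quality; reported percentages are rounded to
integers.

## Problem sizes

The default test and acceptance runs use the 5-spectra worked toy instance,
100-spectrum batches for pipeline tests, 200-instance random-ensemble
sweeps (n ≤ 50, m ≤ 10) for the solver guarantees, and one 1000-spectrum
simulation for end-to-end recovery; the whole suite runs in well under a
minute on one CPU.

## Known limitations

- Features treating peaks as singly charged degrade on triply and higher
  charged precursors, whose fragments are often doubly charged.
- The percentile vote fixes the retained fraction per feature; a dataset
  with very different class balance than the vote percentile relies
  entirely on the consensus probabilities (and a stricter threshold) for
  useful filtering.
- mzML/mzXML input is not implemented (MGF only); a reader hook would slot
  in at `msqc.spectra.read_mgf`'s call sites.
- No denoising/preprocessing is applied before feature computation; if a
  morphological or intensity-floor filter is wanted it must be applied to
  the MGF beforehand.
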