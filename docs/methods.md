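# Methods

This note documents the statistical model behind `ecia`, the defaults and
why they were chosen, what the synthetic screen does and does not emulate,
and the numerical decisions that were genuinely open.

## The measurement model

A reciprocal extracellular interaction screen measures every ordered
(bait, prey) pair of an n-protein panel in its own well, absorbance at
650 nm. Each bait preparation and each prey preparation carries its own
additive background — expression level, protein stability, plate coating
quality, intrinsic stickiness — on top of an assay-wide background. The
working model for a non-interacting well is therefore additive:

    x_ij = μ + α_i + β_j + ε_ij

with μ the assay-wide level, α_i the bait-(row-)preparation effect, β_j the
prey-(column-)preparation effect and ε measurement noise. True interactions
add signal on top, in one or both orientations. The matrix is never assumed
symmetric: the (A bait, B prey) well and the (B bait, A prey) well are
independent measurements of the same unordered pair, and a self-pair (A, A)
is a single well that covers both directions at once.

## Median polish

`MedianPolish` fits μ, α, β by Tukey's iterative polish: sweep the median
out of every row into α, fold the median of β into μ; then sweep column
medians into β and fold the median of α into μ; repeat. Because medians
ignore a minority of large values, the handful of interacting wells in any
row or column do not contaminate its effect estimate — the property the
whole analysis rests on. The decomposition is exactly additive after every
half-sweep (reconstruction reproduces the input to machine precision), and
shift- and scale-equivariant.

Numerical decisions:

- **Sweep order** rows first, then columns. The polish fixed point is not
  unique; fixing the order makes the result deterministic and is the
  convention documented here.
- **Even-count medians** are the mean of the two central order statistics.
- **Missing cells** are excluded from every median and never imputed; they
  stay missing in the residuals. A fully missing row or column is an error
  (it has no data to estimate an effect from).
- **Defaults** `max_iter=20`, `tol=1e-8`, where `tol` bounds the largest
  absolute median removed in a full sweep. On screen-scale matrices the
  removed medians drop to ~1e-5 absorbance units within 20 sweeps —
  far below noise — but do not always cross 1e-8, so `converged_=False`
  with a tiny `max_abs_change_` is common and harmless; the warning exists
  for genuinely oscillating inputs. Analyses that need a fully converged
  fixed point (e.g. comparison against a long-run reference) can raise
  `max_iter`.
- **No plate term.** The long-format input carries no plate column, so any
  96-well-plate contribution is absorbed into μ, α, β and the residuals
  rather than modelled separately.

## MAD scoring

Residuals are pooled screen-wide and standardized robustly:
`s = (r − median(r)) / MAD(r)` with `MAD(r) = median(|r − median(r)|)`.
Two deliberate conventions:

- **Raw MAD units** — the 1.4826 normal-consistency constant is *not*
  applied. The 2.5 cutoff is stated in raw MAD units; in robust-z terms it
  corresponds to 2.5 × 0.6745 ≈ 1.69 normal standard deviations one-sided.
- **Pooled, not per-row/column**: preparation structure has already been
  removed by the polish; the residual distribution is treated as one
  population with a right tail of interactions.

A degenerate residual distribution (pooled MAD = 0) is an error: scores are
undefined, not infinite.

## Hit calling

For each unordered pair with scores s_ab and s_ba:

- geometric mean g = sqrt(s_ab · s_ba), defined only when **both** scores
  are strictly positive — two below-median wells must never multiply into a
  hit. Self-pairs use their single score as g.
- **bidirectional** iff g > 2.5 (strict);
- else **unidirectional** iff max(s_ab, s_ba) > 2.5 (strict); a pair with a
  missing orientation can reach at most this class;
- else none.

The classes are disjoint by construction (bidirectional takes precedence).
Because g ≤ max(s_ab, s_ba) for two positive numbers, every bidirectional
pair has at least one orientation above the cutoff. Note the converse
asymmetry: a pair with one very large score needs only a modestly positive
opposing score for g to clear 2.5 (with s_ab ≈ 12, any s_ba > 0.53
suffices), so strongly one-sided pairs are sometimes promoted to
bidirectional. That is a property of the geometric-mean rule itself, and
the retest stage is the mechanism that weeds out the resulting
false promotions. The whole score pipeline is invariant under any positive
affine transform of the raw absorbances (the polish absorbs shifts, the MAD
absorbs scale), verified as a test property.

## Retest confirmation

A retest screen is small and enriched for predicted positives, so its value
distribution cannot support MAD scoring. Instead each dataset (primary and
retest, separately) is robustly standardized by `(x − median)/IQR`, with
quartiles by linear interpolation between order statistics (the numpy
default; the convention matters at small n and is fixed for
reproducibility). Joint normalization of the pooled datasets is available
as an option but is not the default.

Per pair, the two normalized orientation values are combined by the same
guarded geometric mean as in hit calling — including for self-pairs, whose
single normalized value must be positive to count: a below-median value is
background, and letting it through would allow a negative "threshold".
The confirmation threshold is the *minimum* normalized geometric mean over
the primary screen's bidirectional hits — the weakest signal still included
— and a retest pair is confirmed when its geometric mean is strictly above
it. Two consequences worth knowing:

- On a retest identical to the primary, the threshold-defining pair sits
  exactly at the threshold and does not confirm (strict inequality); every
  hit strictly above it does.
- The confirmation *rate* is computed over predicted hits, so it is
  deliberately diluted by false-positive predictions that fail to confirm;
  the planted-only rate in the acceptance output separates recall of true
  interactions (~0.9–0.97 across seeds) from this dilution.

Reproducibility is the Spearman rank correlation between the two screens'
per-pair geometric means, computed on the **raw-value** geometric means:
raw absorbances are non-negative, so the summary is defined whenever both
orientations were measured, and ranks are unchanged by any monotone
normalization — making the statistic invariant under monotone transforms of
either screen, which the normalized variant (whose positivity guard drops a
data-dependent half of the pairs) is not. Hit-versus-control distribution
comparisons use the two-sided Mann–Whitney U test, a rank-based choice
consistent with the robust spirit of the rest of the pipeline.

## The synthetic screen

`simulate_screen` draws α and β independently for the bait and the prey
preparation of the same protein (two different biochemical objects), adds
noise, plants `n_true_pairs` interactions with a fixed additive effect in
both or one orientation, clips at zero (absorbance cannot be negative — a
deliberate deviation from pure additivity, negligible at the default
settings), and optionally appends prey-only negative-control wells and one
strong positive-control well. Defaults, chosen once as a realistic
desk-scale screen:

| parameter | default | rationale |
|---|---|---|
| n_proteins | 50 | desk-scale mirror of the 200-protein design |
| overall_background | 0.25 A650 | typical colorimetric plate background |
| row/col_effect_sd | 0.05 A650 | preparation biases comparable to, and larger than, noise |
| noise_sd | 0.02 A650 | per-well measurement noise |
| n_true_pairs | 30 | ~2.4% of the 1,275 unordered pairs, a sparse-interaction regime |
| effect_size | 0.16 A650 | 8 × noise_sd: clear but not caricatured binding signal |
| noise_family | normal | `lognormal-additive` (centred, variance-matched) probes right-skew |

What the simulator does **not** emulate: 96-well spatial (edge) effects,
plate-to-plate batch structure, saturation of the colorimetric readout,
affinity- or ligand-dependent signal, and correlated biases between a
protein's bait and prey preparations. Passing recovery tests therefore
demonstrates that the analysis inverts the stated additive bias model, not
that it is robust to every artifact of real plates.

A null-screen subtlety: after polishing pure noise, the standardized score
tail P(s > 2.5) runs ≈ 5.1% rather than the 4.59% of a robust-standardized
normal sample, because the polish concentrates the residual core slightly
(deflating the pooled MAD relative to the tails). The property test for the
null tail averages several seeds and allows for this small systematic
inflation.

## Problem sizes

The test suite and the acceptance script run the full analysis at the
200 × 200 design scale once (seconds) and otherwise at the 50 × 50 default,
with smaller matrices (≤ 6 × 6) wherever behaviour is checked against
exhaustive-enumeration or long-run reference implementations. Reference
polish runs use 500 sweeps at `tol=1e-12` so both routes sit at the same
fixed point to ≤ 1e-8.

## Known limitations

- The geometric-mean promotion asymmetry described under hit calling.
- The confirmation threshold is a sample minimum, hence sensitive to the
  single weakest included hit; it is reported alongside the rates so users
  can judge its stability.
- IQR normalization per dataset assumes the two screens' value
  distributions differ only by location and scale.
- With duplicate (bait, prey) records the default policy is to error;
  averaging is opt-in, and no variance model is attached to the average.
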