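# Methods

## Input model

A consensus map is an ordered list of markers per chromosome with
cumulative positions in centimorgans (cM); map files carry each marker's
distance from the previous one and positions are recovered by running
sum, so the first marker anchors the origin at 0 and the chromosome
length is the last marker's position. QTL description files carry one
record per mapped QTL: name, study, chromosome (c1–c26), trait code,
optional LOD and R², mapping method, and an optional position and
confidence interval (CI). Both formats are UTF-8 TSV with one header line
and `#` comments — a convention of this package; the surveys this work
descends from never specified a dialect. Absent numeric fields are empty
strings and stay `None` in memory: several source studies reported no CI
or LOD, and encoding absence as zero would corrupt placement.

Trait labels are normalized to the 43 canonical codes of the cotton
survey vocabulary (fiber quality, yield, seed quality, morphology,
resistance, physiology, drought tolerance) through a synonym table,
because source spellings vary ("Micronaire", "Leaf morph", "Nematode
related"). R² is stored exactly as declared per study — fraction or
percent — since it never enters placement; LOD likewise is carried
through reports only.

## Projection rules

Records are completed against the consensus map before analysis:

- missing position → midpoint of the two flanking markers' positions.
  "Average distance between markers" readings are ambiguous; the midpoint
  is the only interpretation that yields a single deterministic placement.
- missing CI → the flanking-marker interval. If a reported point position
  falls outside that substituted interval, the interval is widened to
  contain it, keeping every kept record internally consistent
  (ci_lo ≤ position ≤ ci_hi).
- exclusions, reported not raised: a flanking marker absent from the map
  (`MARKER_NOT_ON_MAP`), no position and no usable flanking pair
  (`UNRESOLVABLE`), a position outside [0, chromosome length]
  (`OUT_OF_RANGE`), and a QTL name occurring at two or more distinct
  positions on one chromosome within one study (`MULTI_LOCATION`). All
  copies of a multi-location QTL are dropped — the conservative choice
  when the source record cannot disambiguate which placement is real.

Filtering is idempotent: re-running it on its own kept set excludes
nothing.

CIs convert to per-QTL standard deviations for the meta-model as
σ = (ci_hi − ci_lo) / (2 z), with z the standard-normal quantile of
(1 + level)/2 and level defaulting to 0.95 (source studies rarely state
their CI level; 95% is the field convention and the parameter is
configurable). σ is floored at 0.1 cM so point intervals cannot produce
zero-variance mixture components.

## Cluster and hotspot detection

The detector operationalizes the survey's rule of thumb — multiple QTL
within a roughly 20 cM region constitute one cluster or hotspot — as an
anchored sliding window. Candidate windows [x_i, x_i + w] are anchored at
the sorted QTL positions (w = 20 cM by default, taken as exactly 20);
windows holding at least `min_cluster` (default 4) QTL qualify, and
overlapping qualifying windows merge into a single call reported as the
span from its first to its last member. Anchoring at data points rather
than a grid makes calls deterministic and invariant to input order, and
merging matches the one-call-per-region convention of published
catalogues. Clusters require at least `min_traits` = 2 distinct trait
types ("various traits"); the per-trait rerun of the same scan yields
hotspots with `min_hotspot` = 4 — unstated in the survey text but equal
to the smallest published hotspot. Membership is by point position by
default; a `ci-overlap` mode additionally admits QTL whose CI intersects
the call interval, for collections dominated by wide-CI studies.

Names follow the published convention: `c{N}-cluster-{i}` with i
restarting per chromosome in start order, and `c{N}-{Trait}-Hotspot-{j}`
with j a single genome-wide counter per trait advancing in chromosome
then start order.

One known limit of the merged-window operationalization: manually curated
catalogues sometimes list two adjacent same-trait hotspots separated by
less than one window (e.g. spans ending at 50 and starting at 51 cM).
Under anchored windows with merging, such geometry necessarily fuses into
one call — any tail anchor of the first group captures enough members of
the second. The packaged catalogue transcribes the published intervals
verbatim; the detector is validated against a brute-force enumeration
oracle and on separable geometry instead.

`estimate_false_positive_rate` scatters n QTL uniformly on a chromosome
and reports the fraction of Monte-Carlo replicates (default 10,000,
seeded) in which some window qualifies — the probability that a cluster
of the observed size arises by chance. It is deliberately simple: a
per-chromosome null, not a genome-wide multiplicity correction.

## Mixture meta-model

Projected positions x_i on one chromosome, with known variances σ_i²
from their CIs, are modelled as a K-component Gaussian mixture with
component means μ_k (the meta-QTL) and weights π_k:

L = Σ_i log Σ_k π_k φ(x_i; μ_k, σ_i²).

There is no free component variance — each observation brings its own,
the standard meta-QTL formulation. EM updates are responsibilities
r_ik ∝ π_k φ(x_i; μ_k, σ_i²), weights π_k = mean_i r_ik, and
precision-weighted means μ_k = (Σ_i r_ik x_i/σ_i²)/(Σ_i r_ik/σ_i²); for
K = 1 this reduces to the closed-form inverse-variance weighted mean,
which the tests assert to 1e-6 cM. The log-likelihood is checked every
iteration and an decrease beyond floating-point noise raises immediately.
Each component mean gets a 95% interval μ_k ± 1.96/√(Σ_i r_ik/σ_i²),
clipped to the chromosome when a length is supplied.

Numerical choices: responsibilities are computed in log space
(logsumexp); convergence at log-likelihood gain < 1e-8 or 500 iterations;
10 initializations per K — the first at K-quantiles of the data
(deterministic), the rest jittered quantiles from the seeded generator;
a component whose total responsibility falls below 1e-6 is reset to the
worst-fit observation rather than silently vanishing; ties in model
selection break toward smaller K.

K is selected by refitting for K = 1..min(kmax, n) (kmax default 10, the
customary cap in meta-QTL software) and minimizing AIC with 2K − 1
parameters per model; AICc and BIC are selectable, and a user-forced K
bypasses selection. On the reference condition used in the tests — two
components 50 cM apart, observation σ = 2 cM, 10 QTL each, 100 seeded
draws — AIC recovers the planted K in 94 runs and BIC in 97; both clear
the ≥ 90% design requirement and AIC stays the default for its weaker
small-K bias on sparse chromosomes.

## Genome-distribution statistics

The trait × chromosome table counts kept records per cell; totals are
derived, and tabulation conserves the record count. Uniformity is tested
with Σ(O − E)²/E against equal expected counts (df = categories − 1,
critical value from the χ² quantile at 1 − α). The subgenome test splits
totals into A (c1–c13) and D (c14–c26) halves with equal expectation —
13 chromosomes each, hence df = 1 and critical 3.84 at α = 0.05. On the
packaged survey table this package computes χ² = 18.64 for the 536 vs 687
subgenome split where the original report prints 18.72; the recomputed
value is reported as-is and only the exceedance of the critical value is
asserted. Homoeologue comparison pairs the 13 A–D chromosome pairs and
flags calls whose intervals intersect within a ±10 cM slack — an informal
alignment, since homoeologues share no coordinate system; same-trait
hotspot sharing is tallied separately.

## Synthetic data

The generator emulates the meta-layer of a pooled survey, not the
underlying QTL mapping: maps with markers every 1–5 cM on chromosomes of
80–150 cM; planted regions contributing Normal(center, sd) positions for
their trait lists; uniform background QTL with per-(chromosome, trait)
Poisson counts at `background_rate` per 100 cM (default 0.2, spread over
five common traits), matching the uniform null of the chance-rate
estimator; CI widths log-normal with median 15 cM and log-sd 0.5,
mimicking the published mix of tight and very wide intervals; LOD and R²
drawn from plausible ranges but never used in placement; study labels
round-robin over 42 studies. Fractions of records can be emitted with
position and/or CI blanked and nearest flanking markers attached, to
exercise projection. All draws flow from one seed; identical seeds give
byte-identical emitted files.

What passing synthetic tests do not show: real collections have
correlated study effects (shared parents, shared markers), CI widths that
correlate with study design rather than being i.i.d., and marker maps
with long gaps — none of which the generator models. Recovery results on
synthetic data therefore validate the machinery, not the biological
claims of any particular survey.

## Problem sizes

The verification battery uses: 1,000 random instances of ≤ 12 QTL for the
window-scan/oracle comparison; 100 seeded draws for K selection; 100
seeded collections (three planted regions, two chromosomes) for recall;
200 background-only collections against the 10,000-replicate chance-rate
estimator, compared within three binomial standard errors. These sizes
give stable pass/fail behaviour at sub-percent Monte-Carlo noise while
keeping the full battery at about two minutes on one core.

## Known limitations

- The projection stage assumes the source coordinates are already on (or
  compatible with) the consensus map; true map merging via shared markers
  is out of scope.
- The chance-rate estimator and the χ² tests are per-chromosome; no
  genome-wide multiple-testing correction is applied, matching the
  descriptive style of the original surveys.
- Published catalogues built by manual inference cannot always be
  regenerated by any deterministic window rule (see detection above);
  catalogue fixtures and detector output are therefore validated
  separately.
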