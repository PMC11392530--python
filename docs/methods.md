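# Methods

`epismc` implements pairwise sequentially-Markovian-coalescent (SMC)
demographic inference that uses, besides nucleotide polymorphisms, one or
more *hyper-mutable* heritable markers — above all heritable CG methylation
(site-level "SMPs" and region-level "DMRs").  This note describes the model,
the numerical choices and the limits of what the simulations show.

## The model

### Markers and their pair-emission laws

A marker class is defined by its number of possible states `nbs` and its
mutation model.  Symmetric markers follow a Jukes-Cantor-type chain: the
state changes at total rate `mu` per site per generation and moves uniformly
to one of the other `nbs - 1` states.  For a pair of genomes whose lineages
coalesce `t` generations ago, the probability of observing the same state is

    P(id | t) = 1/nbs + (nbs-1)/nbs * exp(-2 mu t nbs/(nbs-1)),

the factor 2 counting the two branches.  The ancestral state at the common
ancestor is drawn from the stationary distribution — the mutation process is
assumed stationary, as everywhere in the SMC family.  Because the law
saturates at `(nbs-1)/nbs`, markers with `mu >> 1/(4N)` are reversible and
homoplasic: a finite-site treatment is mandatory, and identity no longer
implies recent common ancestry.

CG methylation is modelled as an asymmetric two-state chain with gain
(methylation) rate `mu_SM` and loss rate `mu_SU`; the pair law over
{both-U, both-M, discordant} follows the same construction.  Defaults follow
the experimentally measured *A. thaliana* rates `mu_SM = 3.5e-4`,
`mu_SU = 1.5e-3` per site per generation.

### The coupled region + site methylation process

Methylation also changes in blocks: a whole region (1 kb, or 150 bp, per the
two empirical estimates in the literature) gains or loses methylation at
rates `mu_RM = 2e-4`, `mu_RU = 1e-3` per region per generation.  We model the
joint (region status, site status) pair per lineage as a 4-state Markov
chain: a region-level event flips the region status *and resets every site
in the region to the new status*; site-level events continue on top at their
own rates.  This single generator drives both the simulator and the
9-symbol emission law (region-pair status {UU, UM/MU, MM} x site-pair symbol
{both-U, both-M, discordant}), so inference and simulation are mutually
consistent by construction.  The 4x4 matrix exponential gives the exact
pair law; the contract is isolated in `markers.region_site_generator` so an
alternative coupling (e.g. an Ising-type model) could be swapped in.

### The SMC hidden Markov model

The hidden state at a position is the discretized pair coalescence time
(TMRCA).  Time is cut into `n_states` intervals of equal prior coalescence
mass under a guess demography (default `n_states = 40`; the experiments
below say what they used); each interval is represented by its conditional
mean time, computed by averaging the inverse coalescent CDF over
sub-quantiles.  Transitions follow the SMC' kernel: from TMRCA `s` a
recombination strikes with per-site probability `1 - exp(-2 r s)`; the
recombination height is uniform on `[0, s]`; the detached lineage
re-coalesces at rate `2/(2N(t))` below `s` — half of that being the
invisible self-coalescence that keeps the TMRCA — and `1/(2N(t))` above.
With piecewise-constant `N(t)` all inner integrals are closed-form in the
cumulative hazard; the remaining average over the recombination height uses
32-point Gauss-Legendre quadrature.  Partial selfing at rate `sigma`
rescales the recombination rate by `1 - F`, `F = sigma/(2 - sigma)`.

All computation is carried out in generations with per-generation rates; the
kernel consumes `N(t)` directly, so no coalescent-rescaling step exists to
get wrong.

### Windowed likelihood

For long sequences observations are binned into fixed windows (default
100 bp): the window emission is the product of the per-site emissions given
the state, and transitions act between windows.  `window_size = 1` recovers
the exact per-site HMM, which the test suite verifies against exhaustive
path enumeration to 1e-10.  Forward-backward uses per-step rescaling (no
underflow at any length); inner loops are numba-compiled.

### Fitting

Two strategies, matching standard practice in this tool family:

* **Baum-Welch (generalized EM).**  The E-step accumulates expected
  transition counts, initial-state counts and per-state symbol counts over
  all haplotype pairs (composite likelihood, pairs treated as independent).
  The M-step maximises the expected complete-data log-likelihood over the
  free parameters (grouped epoch sizes, optionally `r` and marker rates)
  numerically with Nelder-Mead on log-parameters, accepting the update only
  if the objective improved — hence the likelihood trajectory is
  non-decreasing (verified over randomized fixtures).  Defaults: 30
  iterations maximum, relative tolerance 1e-5.
* **Direct likelihood optimisation.**  Nelder-Mead on the observed composite
  log-likelihood, by default on a 6-haplotype subsample to bound cost;
  best-so-far is returned, never below the starting likelihood.

Two numerical safeguards matter in practice.  First, fitted epoch sizes are
constrained to a factor 500 of the initial constant-size guess: hidden
intervals that receive (almost) no expected coalescences otherwise drift to
infinity, because shrinking their prior mass always raises the likelihood — 
a well-known pathology of this model family.  Second, free hyper-mutable
rates are initialised by a closed-form method of moments: under a constant
size `N0` the marginal pair segregating fraction is
`(nbs-1)/nbs * 2 N0 c / (1 + 2 N0 c)` with `c = 2 mu nbs/(nbs-1)`, which
inverts exactly.  Watterson's theta is useless here (it saturates), while
this start lands near the optimum and leaves Baum-Welch a refinement role.

### Rate estimation and the 1% rule

With a reference marker of known rate (the nucleotide clock `mu_1`), unknown
marker rates are estimated by a dispatch rule: if at most 1% of a marker's
sites segregate, the infinite-site regime holds and
`mu_2 = mu_1 * thetaW_2/thetaW_1 * c(nbs)`; otherwise Baum-Welch frees the
emission rate(s).  The state-count correction `c` is derived by equating the
small-`t` expansion of the pair segregating probability across markers;
under the total-rate (Jukes-Cantor) parameterisation that expansion is
`2 mu t` for *every* `nbs`, so `c = 1` exactly.  The derivation (and the
alternative per-target-state parameterisation, which would give an
`(nbs-1)`-ratio) is kept in one function so it can be swapped.

### Methylation workflow

* **Region-effect test.**  Under site-only epimutation the states of
  distinct CG sites in one genome are independent stationary draws, so two
  annotated sites agree with probability `pi_M^2 + pi_U^2`.  The observed
  number of identical pairs among *disjoint* successive pairs (overlapping
  pairs would be 1-dependent and break the binomial calibration) is tested
  two-sidedly at level 0.05; a distance-stratified variant takes pairs at
  least `d` bp apart.  Calibration (type-I ~ 5%) and power (-> 1 when region
  rates reach the site rates) are verified by simulation.
* **DMR segmentation.**  A 3-state HMM along annotated sites per genome
  pair; hidden states are the region-pair status, emissions are the
  region-conditioned site-pair law evaluated at a moment-matched pair time
  (from the observed discordant fraction), transitions implement a geometric
  region-length prior with mean the configured region length.  Posterior
  decoding yields segments and their length distribution.
* **Observation coding.**  0/1 at non-methylable sites
  (identical/segregating nucleotides), 2/3/4 at annotated CG sites
  (both-U/both-M/discordant), lifted to the 9-symbol region-conditioned
  alphabet when a segmentation is supplied.  Missing data is a dedicated
  symbol that is simply excluded from all counts (emission 1 in every
  state).  The "segregating SMPs only" mode — the default stance for real
  data — drops monomorphic annotated sites from the likelihood altogether;
  note this conditions on a sample-level event that the pair-level emission
  does not model, a deliberate approximation shared with the original
  analyses.

## The simulator

The ancestral recombination graph comes from msprime (discrete genome,
haploid samples; sizes are passed so that a pair coalesces at rate
`1/(2N)`, i.e. `theta = 4 N mu`).  Symmetric-marker and site-only
methylation overlays use msprime matrix mutation models restricted to the
designated marker positions through a rate map — statistically identical to
placing Poisson mutation events on branches.  Minority markers are placed
round-robin (every k-th position), so designated-site counts are exact and
reproducible.  One subtlety: monomorphic designated sites of hyper-mutable
markers are *not* fresh stationary draws — sites whose mutations cancelled
must keep their realised shared state, otherwise the genome-wide state
frequencies and the region-effect test calibration are wrong.

The coupled region+site process cannot be composed from independent
overlays (region events rewrite blocks), so a dedicated engine walks one
marginal tree per region, simulates the region-status path along each
branch (Gillespie) and advances all site chains through each inter-event
segment, resetting them at region flips.  Within a region all sites share
the marginal tree at the region midpoint; since regions (150 bp - 1 kb) are
of the order of the genealogy span, this is an approximation — adequate for
the region-level questions asked of it, and the site-only path (used for
the headline SMP experiments) is exact.

Genic regions are seeded non-overlapping intervals of the configured region
length; methylable CG sites sit every `cg_spacing` bp (default 10) inside
them, with the spacing tightened automatically when a large methylable
fraction (up to 20%) is requested.

What the simulator deliberately does not reproduce: variable mutation and
recombination maps, gene conversion, CHG/CHH methylation contexts,
methylation-SNP interactions (deamination, methylation QTL), tissue
heterogeneity of methylation calls, and any non-Markovian spatial
correlation of epimutations beyond the single region scale (real
*A. thaliana* data show stronger short-range SMP correlation than this
model generates).  Passing tests therefore demonstrate correctness of the
implementation under the stated model, not fidelity of that model to real
methylomes.

## Study scenarios

`simulate.SCENARIOS` encodes the simulation experiments: a constant
`N = 10,000`; 10-fold bottlenecks with ancestral sizes 10,000 and 1,000
(`r = mu_1 = 1e-8`, `mu_2 = 1e-4`, marker 2 on 2% of sites); the same with
`r = 1e-7` (`rho/theta_1 = 10`, the hard regime for SNP-only inference); a
very severe (1000-fold) very recent bottleneck with incomplete recovery;
and methylome scenarios at *A. thaliana*-like rates (`r = 3.5e-8`,
`mu_1 = 7e-9`, 90% selfing) with site-only, region-only or coupled
epimutation.  The sources state the fold changes and ancestral sizes but
not the event times; the times used here (e.g. bottleneck between 1,000 and
5,000 generations ago, the `r = 1e-7` variant shifted to 2,000-10,000) are
package choices, recorded in the scenario table and held fixed.

## Evaluation

* **Demography RMSE**: 102 evaluation points uniformly spaced in log10 time
  across the window (default 100 to 1e6 generations),
  `RMSE = sqrt(sum (y_i - y*_i)^2 / 102)` on natural population sizes (the
  defining formula runs i = 1..102 even though it is described as "a
  hundred points"; the formula wins).  A log-scale option exists.
* **Posterior TMRCA**: per-position expectation of the hidden-state time
  vector under the rescaled forward-backward posteriors.
* **Genealogy spans**: distances between changes of the
  maximum-a-posteriori hidden state (an expected-time-change variant is
  available); spans partition the sequence.
* **LD decay**: `r^2` between biallelic sites with minor-allele count >= 2,
  binned by distance.

## Problem sizes used in the checks

The reference experiments run 10 haplotypes x 100 Mb x 10 replicates; the
shipped test suite and acceptance script reproduce each finding at the
largest size that keeps the whole suite practical on one CPU, chosen per
experiment and fixed in the code: the infinite-site rate recovery keeps the
full 100 Mb length (no HMM is involved; 2-3 replicates), the finite-site
rate recovery runs at 10 Mb with 40 hidden states on a 6-haplotype
subsample, the recombination comparison at 2 Mb x 2 seeds with 16 states,
the methylome-vs-SNP comparison at 1 Mb x 5 seeds with 20 states, and the
region-test calibration at 150 kb x 200 seeds.  Directional findings (which
method is more accurate, under- vs over-estimation) are stable at these
sizes; absolute estimator variance is of course larger than at full scale.

## Known limitations

* The composite likelihood treats pairs as independent; uncertainty
  estimates would need a block resampling scheme (not provided).
* With few recombination events per pair (short sequences) and a saturating
  marker, the hyper-mutable rate and the coalescent time scale are nearly
  confounded; the rate estimate then leans on the nucleotide marker, and
  at reduced scale retains a mild downward bias that disappears with
  sequence length and finer time discretization.
* The DMR segmentation uses one moment-matched time per pair rather than
  integrating over the TMRCA posterior; adequate for length recovery, and
  deliberately simple.
* Real-data input (VCF + methylome table + genic BED) is supported and
  round-trip tested, but no preprocessing pipeline (SNP/methylation
  calling, scaffold selection) is included.
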