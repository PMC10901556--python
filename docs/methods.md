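# Methods

This note documents the models, numerical choices and limitations behind
`p53evo`, in the order the pipeline uses them.

## Substitution model and rate heterogeneity

Protein evolution is modelled with an empirical time-reversible Markov
process.  The instantaneous rate matrix is assembled in GTR form,
`q_ij = S_ij * pi_j` for `i != j`, from the published JTT exchangeability
matrix `S` and equilibrium frequencies `pi` (packaged as plain text in
`p53evo/data/jtt_rates.txt`; the numbers are the Jones–Taylor–Thornton 1992
tabulation used by essentially all likelihood software).  `Q` is normalised
so the expected rate at stationarity is one, which makes branch lengths
read as expected substitutions per site; with chronogram input (branch
lengths in My) a single rate scalar (substitutions/site/My) converts
between the two scales.

Among-site rate variation is the standard discretised gamma: `k` categories
of equal weight (default `k = 5`), each represented by the **mean** of its
equal-probability slice, computed exactly via the regularised incomplete
gamma function.  A median-of-slice variant is selectable
(`gamma_method="median"`) because different programs differ here and the
choice moves posterior probabilities in the third decimal; the package
default is mean-of-slice.  The optional invariant class (+I) appends a
zero-rate category with weight `p_inv`; the variable categories are then
rescaled by `1/(1 - p_inv)` so that the mixture mean stays exactly one —
without this renormalisation, branch lengths would silently change meaning
between models, and model-selection comparisons would be confounded.

`+F` replaces the JTT frequencies with frequencies counted from the non-gap,
non-ambiguous cells of the alignment (19 extra free parameters).

## Trees and surgery

Trees are rooted, with branch lengths primarily in My.  Chronograms
(ultrametric within 1e-6 My) support three operations stated in ages:

- **prune**: removes leaves and suppresses unary nodes, summing lengths, so
  all remaining pairwise patristic distances are preserved;
- **graft**: inserts an extant leaf on a chosen edge at a divergence age
  strictly inside the edge's age span (both endpoints rejected — grafting
  exactly at a node would create a polytomy ambiguity);
- **clade duplication**: models a whole-genome duplication by replacing the
  edge above a clade with a bifurcation at the WGD age whose two children
  are copies of the clade, leaf labels suffixed `_P1`/`_P2`.  Both copies
  inherit the clade's internal branch lengths, so the tree stays
  ultrametric and each species contributes one tip per paralog.

Newick is the only tree format.  Internal-node ids ride in `[&id=N]`
comments, a dialect that common viewers and dendropy round-trip; a flag
drops them for strict consumers.

The synteny rule classifies a p53 gene copy from its flanking genes:
Class II (paralog 2) requires *gps2* upstream in sense orientation together
with a downstream antisense E3-ubiquitin-ligase gene followed by a *capga*
homolog; Class I (paralog 1) requires *slc2a4* upstream in antisense
orientation.  Evidence for both classes at once yields `unknown` with a
conflict flag.  E3-ligase and *capga* homologs are matched by symbol
heuristics (documented in `phylo.py`); the rule is intentionally a total
function of the supplied neighborhood table and does no database lookups.

## Likelihood, reconstruction, calls

Site likelihoods come from Felsenstein pruning over the `(k+1)`-category
mixture, with per-node rescaling of partial likelihoods (log scale factors
accumulated per category and site) to avoid underflow on deep trees.  Gaps
and `X` are missing data — their partial-likelihood vectors are all ones —
and there is no indel model; alignment columns dominated by indels simply
carry little information.  Transition matrices use the symmetric
eigendecomposition available for reversible models, so repeated `P(t)`
evaluations during optimisation are cheap and exactly reproducible.

Marginal ancestral posteriors use the standard two-pass (inside/outside)
algorithm.  Rate categories are mixed with their **per-site posterior**
weights (prior weight times category site-likelihood, renormalised), not
the prior weights; this is the convention that makes the per-node posterior
the true marginal under the fitted mixture.

Parameter fitting maximises the likelihood over (`alpha`, `p_inv`, rate
scalar) with Nelder–Mead on transformed coordinates (log alpha, logit
p_inv, log scale).  A 1-D bounded line search on the rate scalar runs
first: chronogram branch lengths are in My, so the likelihood-relevant
scale can be orders of magnitude from a naive start, and the gamma-shape /
invariant-fraction ridge (a small alpha mimics an invariant class) makes a
bad first simplex land in the wrong basin.  Two branch-length modes exist:
the default keeps the chronogram and fits the single scalar, which respects
the time calibration and is well identified; `per_branch` additionally
re-optimises each branch on the substitution scale by coordinate-wise
bounded Brent sweeps, for users who want MEGA-like behaviour on fixed
topologies (it is slower and intended for modest problem sizes).

Ancestral calls: the ML sequence takes the posterior argmax per site (ties
broken in fixed alphabetical residue order, for determinism); the AltAll
sequence carries the second-most-probable residue at exactly the sites
where the top posterior is below 0.90 and the runner-up reaches 0.10, and
the ML residue everywhere else.  Comparing ML and AltAll binding behaviour
brackets the reconstruction uncertainty with a single alternative protein.

Model selection fits each candidate of the JTT family and ranks by
`AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1)`, with BIC reported alongside and
Akaike weights normalised over rows with a defined AICc.  The sample size
`n` is the number of alignment columns and the parameter count is the
model's free rate parameters plus the rate scalar; both conventions are
stated here because programs differ and the choice shifts AICc values —
rankings on clearly separated models are insensitive to it.

## Binding models

All equilibria are solved exactly, with no trace-ligand approximation.

- **1:1 saturation**: the bound fraction is the stable quadratic root of the
  mass balance; the FP signal model is `mP = f + (b - f) * fraction`, i.e.
  mP linear in bound probe fraction (no anisotropy/intensity correction —
  a documented simplification; it matches how displacement data are usually
  fit in practice).
- **Ternary competition** (probe L and competitor I for protein P): free
  protein solves the monotone scalar mass balance
  `P + L_t P/(K_L + P) + I_t P/(K_I + P) = P_t` — the physical root of the
  underlying cubic — bracketed in `[0, P_t]` and polished by Brent to
  near machine precision; mass-balance residuals are checked to 1e-9.
- **IC50 → K_D conversion**: at the 50%-displacement point the probe
  complex is half its competitor-free value; free probe, free protein and
  free competitor then follow from the probe's known `K_D` and the totals,
  and the competitor's `K_D` is the dissociation quotient of the remaining
  species.  This exact free-species construction reduces to Cheng–Prusoff
  (`K_D = IC50/(1 + L_free/K_D_probe)`) when probe and protein are trace,
  and it diverges as the fitted IC50 approaches the tight-binding floor
  (competitor stoichiometrically consumed), which is rejected with a
  diagnostic rather than returned.
- **Competition fitting** offers two routes and reports both: route A
  (primary) fits a four-parameter logistic for the IC50 and converts it;
  route B fits the exact ternary model directly.  Route A mirrors common
  practice (Prism-style analysis); route B is exact at zero noise.  In the
  sub-stoichiometric probe regime (15 nM probe against 0.2–2 uM protein)
  the routes agree within a few percent; route A carries a small systematic
  bias where tight binding sharpens the curve beyond a logistic.  Curves
  that displace less than 10% of the signal are flagged as lower-bound-only
  estimates.
- **ITC**: per-injection heats follow the single-site Wiseman isotherm with
  the standard displaced-volume corrections for an overfill cell
  (macromolecule diluted by `(1 - dV/2V0)/(1 + dV/2V0)`, titrant
  accumulating as `X_syr (dV/V0)/(1 + dV/2V0)`), a constant per-injection
  dilution-heat offset, and heats as differences of cumulative reaction
  heat with the carry-out correction.  The fit returns `n`, `K_a`, `dH`;
  `dG = -RT ln K_a` (K_a converted to per-molar) and `dS = (dH - dG)/T`
  follow by construction.  A `c`-value (`n K_a M_cell`) below 1 flags a
  poorly constrained fit.  Rows of an ITC CSV are sorted by injection
  index before analysis, so heats attach to cumulative titrant regardless
  of row order.

Nonlinear fits multi-start from log-spaced `K_D` (or `K_a`) grids to avoid
local minima and keep results deterministic; standard errors come from the
fit covariance unless replicates are supplied.

## Synthetic data: what it does and does not emulate

The generators exist so every stage is testable offline, with ground truth
recorded next to each dataset (seeded `numpy` Generator streams; identical
seeds give identical outputs).

- **Sequence evolution** draws root states from `pi`, assigns each site one
  rate category for the whole tree (gamma or invariant — the same
  assumption the likelihood makes), and evolves states branch by branch
  with the model's transition matrices.  The default rate scalar is
  0.002 substitutions/site/My, a typical fast-evolving-protein rate that
  on a 430 My tree produces divergence comparable to a disordered-domain
  alignment.  What it does **not** emulate: indels (the analysis treats
  gaps as missing), alignment error, among-lineage rate variation, and
  selective constraint profiles along the sequence.  Recovery results on
  these simulations therefore validate the inference machinery, not the
  adequacy of JTT+G+I for any particular real alignment.
- **The tree generator** produces random ultrametric topologies; the
  study-shaped variant places a 27-species "teleost" crown at 250 My below
  a stem reaching 380 My on a 430 My root, so a 303 My duplication age
  falls on the crown's parent edge and the duplicated tree has 62 tips —
  the shape and size of a two-paralog fish alignment.
- **FP curves** map the exact equilibria onto mP between two plateaus
  (defaults 60 and 200 mP) and add i.i.d. Gaussian noise (default 2 mP);
  instrument drift and intensity artifacts are not simulated.  The default
  design is the study regime: 15 nM probe, 0.2–2 uM protein, a 12-point
  competitor dilution.
- **ITC isotherms** use the same forward model as the fitter at the study's
  loadings (11 uM cell, ~118 uM syringe, 25 C), so zero-noise round-trips
  are exact by construction and test the optimiser, while noisy round-trips
  probe identifiability.

## Problem sizes and numerical tolerances

Exactness checks compare the pruning engine against brute-force enumeration
over all internal-state assignments on trees of up to 5 taxa (agreement to
1e-8 demanded, ~1e-13 achieved).  Recovery studies use 2,000 sites on the
62-tip duplicated chronogram — large enough that the gamma shape is
recovered within ±0.2 and the invariant fraction within ±0.05 — and model
selection uses a 40-tip tree with 1,200 sites, where the generating
JTT+G+I model separates decisively (Akaike weight > 0.99) from JTT+G and
JTT.  These sizes were chosen as the smallest at which the corresponding
parameters are clearly identifiable; the gamma/invariant ridge makes both
parameters genuinely non-identifiable on small trees (on 20 tips a reduced
gamma shape reproduces the invariant class almost exactly), which is a
property of the model family, not of the implementation.

## Known limitations

- Marginal reconstruction only; no joint (max-sum) reconstruction.
- No indel model; regions dominated by indels are not reconstructable and
  the package makes no attempt to call them.
- The AICc sample-size convention (columns) and the gamma discretisation
  variant are choices on which published programs differ; both are exposed
  as options and pinned in the manifest, but numerical AICc values are not
  comparable across programs.
- FP analysis treats mP as linear in bound fraction and ignores
  fluorescence-intensity changes on binding.
- Errors on fitted `K_D` are asymptotic (covariance-based); replicate-based
  uncertainties, where available in the packaged affinity table, are stored
  as given and never recomputed.
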