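# Methods

## Model

The Golgi is an ordered stack of cisternae (index 1 = cis).  A glycan enters
at cisterna 1, spends a fixed residence time in each compartment (default
10 min), and exits after the last.  Within a cisterna the usual Gillespie
construction applies to the set of applicable reactions: propensity
r_i = k_{e(i),c} · s_i, where k_{e,c} is the *effective rate* of enzyme e in
cisterna c (min⁻¹; a composite of protein level, nucleotide-sugar
availability and catalytic rate — the quantity being fitted) and s_i an
optional substrate-context scale factor.  Waiting times are exponential with
mean 1/R (R = Σ r_i); reaction i fires with probability r_i/R; a waiting
time that overshoots the residence boundary fires nothing and the glycan
moves on (standard SSA-with-deadline semantics).  The within-cisterna clock
resets at each entry; whether a real Golgi "carries over" waiting time is
unknowable in this framing and the reset is the simplest consistent choice.
Enzyme competition is implicit (all enzymes present, one glycan at a time);
glycan-glycan substrate competition and nucleotide-sugar depletion are out
of scope.

Glycans are rooted residue trees serialized to a linear notation (see
`glycosim.notation`).  Canonical form sorts sibling branches by linkage code
with ties broken on the canonical subtree serialization — a total,
chemistry-free order that makes structural isomers compare equal
deterministically.  Classification: oligomannose = 5–9 mannoses and no
GlcNAc-initiated antenna; hybrid = antenna + 5 mannoses; complex = antenna +
trimannosyl core; transient states outside these (e.g. 4-mannose
intermediates mid mannosidase-II trimming) are reported as "other".

## Rule set

The shipped mammalian rule set (`data/rules_default.yaml`) is a documented
reconstruction of the canonical pathway, expressed in a small declarative
vocabulary (residue-level pattern + whole-glycan guards) so users can amend
it.  Choices worth knowing:

- MAN1 is one rule (remove any terminal α1,2-mannose) with a ×0.25 scale
  factor on the Man6→Man5 step, matching the published slow final trim.
- Endo-mannosidase removes the terminal Glc-Man unit of glucosylated input
  in one event (the only two-residue substitution); its product re-enters
  the MAN1 ladder.
- MGAT1 requires exactly Man5 with no antenna and no Glc; MAN2 requires an
  antenna (hence acts only after MGAT1); MGAT2 requires the trimannosyl
  core; MGAT4/MGAT5 additionally require the β1,2-antenna of their arm to be
  *unsubstituted* — this is the mechanism by which galactosylation activity
  limits branching, and what the GalT titration probes.  Antenna cap is 4
  (no penta-antennary rule in the default set).
- GalT carries a ×0.3 scale factor on tri/tetra-antennary substrates; FUT8
  (core fucosylation, requires an antenna) carries ×0.1 on Man5-bearing
  substrates; antenna fucosyltransferases are grouped as one antFUT rule
  restricted to complex glycans, one fucose per antenna, non-sialylated
  antennae only (the sialylation-vs-fucosylation ordering is not settled;
  "fucose only before sialic acid" is the package's choice).  Sialylation
  has separate 3-arm and 6-arm rates (SiaT3/SiaT6), one NeuAc per antenna.
- The oligomannose quench is a pseudo-enzyme with per-cisterna rates whose
  only action is an absorbing "quenched" flag, lumping Man-6-phosphate
  tagging and retrograde ER retrieval.
- Scale-factor values (0.25, 0.1, 0.3) are defaults chosen once as
  plausible relative substrate preferences; they are configuration, not
  fitted constants.

ER input defaults to 80% Man8, 15% Man9, 5% Man9Glc: the 80% Man8 fraction
is the established value, the split of the remainder is this package's
choice and configurable.  Man8 is the B isomer; Man9Glc carries Glc α1,3 on
the A-arm terminal mannose, which blocks MAN1 on that arm until
endo-mannosidase acts.

## Execution

The reachable structure set under a rule set is finite (3,590 states / about
16,000 transitions for the default rules from the three ER species), so the
simulator compiles it once: breadth-first closure, then CSR transition
arrays.  Profiles run on a numba kernel over this graph (~1 µs per event);
`simulate_glycan` is the equivalent pure-Python reference path over explicit
structures, and the two are held to the same distribution by a chi-square
test in the suite.  Every glycan has an independent substream (word i of the
profile seed's SeedSequence stream), so output is bit-reproducible in
(seed, model, n) and independent of execution order.  Profile aggregation:
counts → %, isoforms collated by composition key (Glc folded into Hex,
since MS cannot distinguish hexoses — Man9Glc reports as Hex10HexNAc2),
entries < 0.1% dropped *without renormalization* (toggleable).  Replicate
profiles report per-key mean and SEM = sd/√n across replicates, with the
filter applied after averaging.

## Fitting

Score: Σ (semᵢ − |obsᵢ − simᵢ|)² over the union of composition keys,
zero for keys agreeing within SEM; keys missing on one side contribute
abundance 0 there; observed entries lacking an SEM use
max(0.1%, 5% of abundance) when a policy is enabled (otherwise an error).

Rejection ABC with adaptive threshold: a pilot (default 200 proposals) sets
the initial threshold at the 50th score percentile and, when no final
threshold is given, the final threshold at the 20th.  During shrinking, the
acceptance rate over a sliding window (default 1,000 proposals) is checked
at every proposal; whenever it exceeds 7% the threshold drops by 10%.  The
window is *not* reset after a shrink, so an over-loose threshold cascades
down quickly; the trajectory is non-increasing by construction.  Once at the
final threshold, sampling continues until the target number of
acceptances; only these
fixed-threshold acceptances form the posterior (shrink-phase acceptances are
counted but not kept — keeping them would mix draws accepted under different
tolerances).  Chains are independent (disjoint seed substreams) and share
the pilot-derived thresholds so their stationary targets coincide.
Non-finite scores reject the proposal with a log entry; an iteration cap
returns a partial result with a warning rather than looping forever.

Diagnostics: Gelman-Rubin R per parameter from within-/between-chain
variances (duplicated chains give R = √((n−1)/n) ≤ 1; all-constant chains
give NaN with a warning).  Prior-vs-posterior shift uses a two-sided
Mann-Whitney U test; re-centering a flagged log-normal prior moves μ to the
posterior log-mean keeping σ, an exponential prior adopts the posterior
mean.  Re-centering is an explicit user step between runs, never automatic.
Across independent fitting runs, `posterior_summary` reports per-parameter
means, across-run SDs, and a triplicate profile simulated at the means.

## Synthetic data

Presets freeze ground-truth rate sets for the regimes of interest:
`oligomannose-3c` (≈91% oligomannose at 10,000 glycans — a whole-cell
profile dominated by quenched species), `complex-4c` (≈59% complex),
`man2-null` (mannosidase-II knockout of complex-4c: no complex glycans,
hybrid accumulation, fucosylated Man5 species), `cog4-like` (knockdown of
late transferases) and `fit-demo-3c` (3 cisternae × 5 enzymes = 15 rates,
with localization-informed priors: log-normal in the predominant cisterna,
exponential decay elsewhere, centered near but not at truth).  Replicate
noise is purely SSA sampling noise at finite n_glycans; real MALDI
measurement artifacts (permethylation efficiency, ionization bias, isotope
overlap) are not modeled, so passing tests show the inference machinery
recovers rates under the model's own noise, not under instrument bias.  An
optional multiplicative log-normal measurement-noise knob exists, default
off.

## Numerical and scale choices

- Parameter recovery runs at 2,000 glycans per simulated profile, 500
  accepted draws over 4 chains, 10 repeats (pilot 80, window 50, initial/
  final pilot quantiles 0.75/0.35): small enough for a desk machine, large
  enough that the 90% credible intervals cover the ground truth for well
  over 80% of the 15 parameters and max Gelman-Rubin R stays near 1.
- Identifiability at this scale is uneven: rates acting where their enzyme
  barely resides, or after their substrate saturates (late-cisterna GalT),
  have posteriors close to their priors.  The contraction test therefore
  asserts SD contraction for the strongly identified rates and a
  median-contraction summary over all of them.
- Zero total propensity idles the glycan until cisterna exit; the quenched
  flag persists across cisternae.  The kernel's event buffer is sized at 64
  events/glycan (the default rule set is acyclic in residue count and
  cannot exceed ~20).
- Flux maps are composition-keyed (like profiles and reported tables);
  quench events appear as self-loops, which leaves interior-node flux
  conservation intact.  The normalized condition/control ratio uses the
  *divide* form — (f_cond/f_ctrl) ÷ (F_cond/F_ctrl), F = total flux of the
  normalizing enzyme — which is the form under which "ratio > 1 means the
  condition prefers this pathway" is unit-free; a `variant="multiply"` flag
  exposes the alternative convention.
- Condition/control flux comparisons assume matched n_glycans; raw counts
  are used because matched sizes cancel in the ratio.

## Limitations

Cisternal maturation vs vesicular transport is not modeled (cisternae are a
fixed ordered pipeline); no bisecting GlcNAc (MGAT3), poly-LacNAc, O-glycans
or glycosaminoglycans; no mass-spectral artifact simulation; enzyme rules
are a literature-shaped default, not a measured specificity table — treat
them as a starting configuration to edit, which is why they live in a YAML
file rather than code.
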