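# Methods

This note documents the models implemented in `titinmech`, their
parameters and defaults, the synthetic-data generator, and the numerical
and design choices that were genuinely open.

## 1. State space and kinetic scheme

An Ig domain is a pair `(fold, redox)` with
`fold ∈ {FOLDED, UNFOLDED}` and
`redox ∈ {RED, SS_BG, SS_BF, SS_FG}` — fully reduced, or carrying one
disulfide of the CysB/CysF/CysG triad. Allowed transitions:

* **unfold / refold** for every redox state;
* **isomerization** `SS_BG → SS_BF` (CysF attacks CysB) and
  `SS_BG → SS_FG` (CysF attacks CysG), only while unfolded;
* **reduction** `SS_* → RED` by exogenous reductant (Tcep), second order
  in reductant, only while unfolded;
* optional **reverse isomerization** `SS_BF/SS_FG → SS_BG`
  (off by default).

The folded core buries the triad, so all chemistry is gated on the
unfolded state. Chemistry is additionally gated on the chain being held
extended (`chem_force_min`, default 1 pN): at zero force the collapsed
chain buries the cysteines much as the folded core does, and the
geometry required for the nucleophilic attack is unavailable. This
matters only during quench pulses, where refolding then competes with
nothing, giving the clean exponential refolding fraction
`1 − exp(−k_fold·Δt)`.

## 2. Rates (AFM-scale defaults, `domain_kinetics.RateSet`)

| parameter | default | origin |
|---|---|---|
| oxidized unfolding `k0_u(SS_*)`, `Δx` | `1.06·exp(−100·0.3/4.11) ≈ 7.16e−4 s⁻¹`, 0.3 nm | solves k(100 pN) = 1.06 s⁻¹ |
| reduced unfolding `k0_u(RED)`, `Δx` | 5.0e−6 s⁻¹, 0.3 nm | puts the 40 pN/s ramp mode near 182 pN |
| `k_iso1` (BG→BF) | 0.021 s⁻¹ | measured at 100 pN; force-independent by default (`dx_iso = 0`) |
| `k_iso2` (BG→FG) | 0.027 s⁻¹ | idem; regiospecificity k_iso2/k_iso1 ≈ 1.29 |
| `k_fold(SS_BG)` | 0.058 s⁻¹ | from refolding fraction 0.44 at a 10 s quench: −ln(1−f)/Δt |
| `k_fold(SS_BF)` | 0.054 s⁻¹ | from 0.42 at 10 s |
| `k_fold(SS_FG)` | 0 | no refolding observed |
| `k_fold(RED)` | 0.01 s⁻¹ | rare refolding of reduced domains |
| `k_red2` | 0.0025 s⁻¹ mM⁻¹ | 10 mM Tcep ⇒ 0.025 s⁻¹, comparable to isomerization |
| `refold_force_max` | 0 pN | refolding only during quench |

The printed mean unfolding forces (114 pN oxidized vs 182 pN reduced at
40 pN/s) and the 100 pN clamp rate are not exactly co-satisfiable by one
Bell pair per state; the defaults prioritise the clamp rate for the
oxidized state and the ramp statistics for the reduced state. The
single-Bell-pair mean at 40 pN/s for the oxidized defaults is ~106 pN.

Constant-force protocol segments are sampled with the exact Gillespie
algorithm. Time-varying segments use thinning with adaptive windows in
which the force changes by at most `kT/Δx_max`, so the proposal bound
stays within a factor e of the true rate even for steep ramps; each rate
is monotone in force, so per-transition endpoint maxima bound the total.

## 3. Polymer elasticity and step sizes

* WLC interpolation formula for single-domain step prediction at
  50–300 pN, inverted by Brent's method on `z ∈ [0, 1−1e−12]` to 1e−12
  relative tolerance. Persistence length `p = 0.4` nm, contour gain
  `l_aa = 0.4` nm/residue, `kT = 4.11` pN·nm (25 °C) — standard
  single-molecule values.
* FJC (Langevin function) for the filament-scale entropic springs with
  Kuhn length `b = 1.1` nm for all unstructured polypeptide.
* Geometry: `n_ext = 88` extensible residues per domain,
  `d_folded = 4.4` nm folded end-to-end distance. These reproduce the
  26.4 nm reduced unfolding step at 170 pN.
* Loop topology (I69 defaults): `loop_BF = 51`, `loop_FG = 11`,
  `loop_BG = 57`. With these, predicted steps at 100 pN are 17.0 nm
  (BG→FG isomerization), 3.7 nm (BG→BF, the "4 nm" population), 6.0 nm
  (oxidized unfolding) and 19.0 nm (Tcep reduction of the B–G loop).

**A deliberate inconsistency.** Exact residue conservation along the
unfold → isomerize → reduce path requires
`loop_BG = loop_BF + loop_FG = 62`, but `loop_BG = 57` is what
simultaneously reproduces the observed 6 nm unfolding and ~19 nm
reduction steps (the folded-state geometry of the B–G loop evidently
does not decompose additively into the two sub-loops). The package keeps
the observationally calibrated default and exposes
`DisulfideTopology.is_conservative`; the additivity identities are exact
(to numerical precision) for conservative topologies, and the invariant
tests exercise them there. All counts are configurable.

## 4. Synthetic AFM traces (`synthetic_afm`)

A trace is `extension(t) = n_folded(t)·d_folded +
released_residues(t)·l_aa·z_wlc(F(t))` plus measurement noise. Events
come from the stochastic engine; each step is smoothed by an exponential
instrument response (default 1 ms), and the recording adds white
Gaussian noise (default σ = 1 nm — a conventional instrument figure, as
the actual noise magnitude is instrument-specific) at 1 kHz, with
optional linear drift. Ground-truth event logs are returned with every
trace, which is what makes detector and estimator validation exact.

What the generator emulates: staircase force-clamp recordings,
force-ramp unfolding, three-pulse refolding protocols, tethers of 1–8
domains, redox heterogeneity via initial states. What it does not
emulate: cantilever dynamics and thermal spectra, surface adhesion
artifacts, tether pickup ambiguity (multiple molecules), baseline
nonlinearity, or instrument drift beyond linear. Passing tests on
synthetic data therefore validate the estimators under the stated noise
model, not robustness to every experimental artifact.

## 5. Trace analysis (`trace_analysis`)

Step detection is least-squares binary segmentation with a penalty of
`10·σ̂²·ln n` per breakpoint (σ̂ from the median absolute deviation of
first differences), a minimum plateau of 6 samples, and plateau levels
estimated by medians that skip a 5 ms guard zone after each break (the
instrument-response transient). Breaks closer than the minimum plateau
are collapsed and re-fit as a single change point: the min-plateau
constraint can otherwise forbid the optimal split next to a transient
and leave two spurious half-steps. Calls below 2 nm are merged away.
On flat noise-only traces the detector makes no calls; on
eight-domain clamp traces at 170 pN it recovers ≥95% of events
one-to-one among traces whose events are separated by >20 ms (closer
coincidences are physically unresolvable at 1 kHz and are the traces an
experimenter would discard as unassignable).

The 6-sample minimum plateau (rather than a more conservative ~20) is
needed because unfolding events on multi-domain tethers at 100–170 pN
pile up within tens of milliseconds.

Histogram fits are nonlinear least squares of Gaussian sums (lmfit) on
1 nm bins with peak-seeded initial means. Refolding fractions are
`Σ probe-pulse unfolds / Σ unfold-pulse unfolds` with a trace-level
bootstrap SEM (1000 resamples); for the disulfide-specific refolding
fraction, traces with isomerization signatures in the unfold pulse are
excluded first, mirroring experimental fingerprint selection.

## 6. Whole-I-band kinetic Monte Carlo (`filament_mc`)

The I-band is two entropic springs (N2B spring, residues 3712–4289;
PEVK, 10216–12022 in the long cardiac isoform; 11851–12022 in the short
one) plus an Ig inventory per isoform. Long-isoform (N2BA) inventory:
101 I-band domains — 21 triad, 24 B/F-pair, 17 F/G-pair, 6 B/G-pair,
24 single-cysteine, 9 cysteine-free. The short-isoform (N2B) inventory
is not fully annotated anywhere public; the default is a constructed
44-domain set {4, 8, 5, 2, 12, 13} that preserves the ~9% triad
fraction. Filament length is the FJC extension of all unstructured,
non-sequestered residues plus 4.4 nm per folded Ig.

Time stepping: 10 ms fixed steps (Δt ≤ 10 ms enforced), triangle force
0→30→0 pN at 1 Hz, 20 min horizon, all domains initially folded.
Per step each domain draws at most one transition with probability
`1 − exp(−k·Δt)`; rates use the midpoint force of the step, and the
refolding probability integrates the exact sub-threshold time within the
step (refolding is allowed below 1 pN, i.e. near the force trough), so
results are stable between 10 ms and 1 ms steps to well under 1%.
`n_replicates` independent filaments can be propagated in one vectorized
pass; the reported length is then their mean, a cheap variance-reduction
device for steady-state summaries.

**Filament-scale rates.** The per-class transition-rate table used by
the original whole-filament analyses is not publicly printed, so the
defaults here are the package's own calibration, chosen for the
low-force regime: a single unfolding Bell pair `k0 = 2.8e−3 s⁻¹`,
`Δx = 0.3 nm` shared by all Ig classes and redox states, the measured
zero-force folding rates for oxidized states (0.058/0.054/0 s⁻¹ for
B–G/B–F/F–G), 0.01 s⁻¹ for reduced cysteine-containing domains, and
0.3 s⁻¹ for cysteine-free/single-cysteine domains (the faster folding
typical of other I-band modules). Two considerations force the shared
unfolding pair:

1. *Steady state within ~5 min*: the unfolding/isomerization turnover
   must complete on a few-minute timescale under 0–30 pN cycling, which
   needs an effective unfolding rate of order 10⁻² s⁻¹ — much faster
   than the AFM-calibrated reduced-I69 pair extrapolated to 30 pN.
2. *Direction of the redox effect*: the oxidized filament is shorter at
   peak force than the reduced one because disulfide-containing domains
   refold much faster (and sequester residues), while reduced domains
   that unfold stay unfolded. If oxidized domains additionally unfolded
   ~10²× faster at 30 pN (as the AFM weakening at 100+ pN would
   suggest when extrapolated), the never-refolding F–G states would
   ratchet open and invert the effect. At ≤30 pN both states are far
   from their unfolding transition and the steady state is dominated by
   the folding asymmetry, so a shared low-force unfolding pair is the
   defensible default; per-class overrides are exposed.

With these defaults the oxidized long-isoform filament is several
hundred nm shorter at 30 pN than the reduced one, the effect is weaker
in the short isoform (fewer cysteine-containing domains), and the
trajectory plateaus after a few minutes. These are qualitative
predictions: the magnitude depends on the unpublished rate table.

Steady-state summaries average per-cycle peak-force lengths after a
10 min burn-in. The trend test regresses 100 s block means, not raw
cycles: per-cycle peaks decorrelate over ~1/k_eff ≈ tens of seconds and
naive regression on autocorrelated cycles flags equilibrium excursions
as spurious trends.

## 7. Dwell-time fitting (`dwell_fit`)

Unfolding times and isomerization latencies are exponential with right
censoring at the trace horizon; the MLE of a censored exponential rate
is `events / total exposure`. The two branches share one exit rate that
is split by branch counts (the multinomial MLE). Only traces longer
than 20 s enter isomerization fitting, mirroring the experimental
selection that favours completed isomerization. CIs are percentile
bootstrap over traces (1000 resamples, seeded); resampling traces rather
than events respects within-trace correlation. With 500 domains and
20 s censoring, ~300 isomerizations are observed and the branch-rate
ratio carries ~10% sampling SD — the precision ceiling of that design,
visible in any single-seed estimate.

## 8. Triad scanning (`triad_scan`)

Each Ig sequence is globally aligned (Biopython `PairwiseAligner`,
BLOSUM62, gap open 11 / extend 1, free end gaps for short flanks) to the
89-residue I91 module, the field's reference numbering. A cysteine
mapping within ±2 columns of positions 23/73/80 is called CysB/F/G and
the domain is classified TRIAD / PAIR_* / SINGLE_* / NONE. Each
extracted domain is sanity-checked for the strictly conserved
tryptophan near reference position 35 (warning, not error). The 12
manually curated Ig domains absent from automatic annotation of
canonical titin ship as a packaged coordinate table; titin band
boundaries (Z/I/A/M) are an editable config table with approximate
defaults. Alignment parameters are surfaced because the original
analysis pipeline's settings are not published. The packaged reference
sequence is the canonical I91/I27 module sequence; its internal
landmarks (C47, C63, Trp34) match the expected conservation pattern.

The whole-molecule census (163 Ig domains; 101 I-band; 21 I-band triads)
requires the canonical titin sequence (UniProt Q8WZ42-1) and its domain
feature table, which are not redistributed; the scanner consumes any
FASTA + TSV pair in that layout.

## 9. Problem sizes in the shipped tests

The test suite regenerates all data: 200–300 synthetic traces for
detector/pipeline checks, 500-domain dwell ensembles, 10⁴-event
branch-count ensembles, 1000-domain ramp ensembles, and 20-minute
filament runs (with 8–40 replicate filaments where variance matters).
These sizes match the study conditions where stated and otherwise were
chosen to keep Monte Carlo error safely inside each test's tolerance.

## 10. Known limitations

* Step-size theory ignores extensible-WLC corrections and temperature
  dependence beyond kT.
* The kinetic scheme has no unfolding intermediates, no domain–domain
  coupling, and no cantilever dynamics.
* Isomerization force dependence is a free option (`dx_iso`), default
  off, because rates were measured at a single force.
* Filament-scale rate defaults are a calibration, not measured values;
  only orderings and stability properties are asserted.
* The N2B-isoform Ig inventory is constructed, not annotated.
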