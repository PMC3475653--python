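# Methods

## The systemic impact factor

A missense mutation changes a protein's folding or binding free energy
by ΔΔG (kcal/mol). At the pathway level that change perturbs the rate
constants of the reactions the protein takes part in. The systemic
impact factor combines the two levels:

    SIF = ΔΔG_max × C

where ΔΔG_max is the larger of the mutation's free-energy changes over
the protein states considered (uncomplexed and complexed — taking the
maximum keeps scores comparable between proteins for which only one
state was evaluated), and C is the *control coefficient* of a pathway
readout S with respect to the perturbed parameter group:

    C = ((S′ − S) / S) / δ

with S′ the readout after scaling the targeted rate terms by a total
relative perturbation δ (default 0.1, i.e. 10%, split across terms by
weights that sum to one). C is the normalized (relative/relative)
sensitivity — the standard control-coefficient convention
(∂S/∂p)(p/S) evaluated by a one-sided forward difference at the working
δ; a central-difference flag exists. The normalized form is required
because coefficient magnitudes are compared across parameters whose
absolute scales differ by orders of magnitude.

Two variant transforms are provided: a per-class scale factor λ
(`lambda` transform, defaults λ_F = λ_S = 1, no fitted default — the
data explored qualitatively suggest functional mutations warrant
λ_F < λ_S, but no value is canonical), and a provisional exponential
form C·exp(ΔΔG/RT) with RT = 0.5922 kcal/mol at 298 K. The exponential
form's exact published expression could not be recovered, so it is
flagged provisional and not used anywhere else in the package.

## Perturbation channels, not parameter symbols

Perturbations act on *channels* — multiplicative factors attached to
individual rate terms — rather than on shared parameter symbols. This
is forced by the biology: the cyclin degradation rate constant k_d
appears in two terms (degradation of the total cyclin pool and of the
active MPF complex), and CycB mutations perturb those two terms with
different weights (0.3/0.7), while Cdk1 mutations act through the MPF
term alone. The three built-in G2-M composites are:

| spec        | channels (weight)                                | used for |
|-------------|--------------------------------------------------|----------|
| kd_CycB     | cycb_degradation (0.3), mpf_degradation (0.7)    | structural CycB mutations |
| kd_Cdk1     | mpf_degradation (1.0)                            | structural Cdk1 mutations |
| J_combined  | J_iwee (0.9), J_a25 (0.1)                        | functional Cdk1 mutations |

δ = 0.1 is read as a *relative* 10% perturbation: k_d = 0.008 makes an
absolute perturbation of 0.1 a 1250% change, which is not a
"perturbation" in any meaningful sense. For composites the stated
constraint ∂p^X + ∂p^Y = 0.1 becomes weights summing to one at total
δ = 0.1. The mapping of the two published Michaelis-constant symbols
onto the four J constants defaults to J_iwee (MPF acting on Wee1) and
J_a25 (MPF acting on Cdc25) and is overridable in
`g2m_mutation_specs`.

## The G2-M model

State variables: total cyclin B (`CycB`; Cdk1 is constant and in
excess, so every cyclin molecule is complexed and total cyclin equals
total MPF), active MPF, and the active fractions of Wee1 and Cdc25
(totals 1). Equations (dimensionless):

    dCycB/dt  = kS − kd·CycB
    dMPF/dt   = kS − kd·MPF − Vwee·MPF + V25·(CycB − MPF)
    Vwee      = kwee′(1 − Wee1) + kwee″·Wee1
    V25       = k25′(1 − Cdc25) + k25″·Cdc25
    dWee1/dt  = kawee(1−Wee1)/(Jawee + 1 − Wee1) − kiwee·MPF·Wee1/(Jiwee + Wee1)
    dCdc25/dt = ka25(1−Cdc25)·MPF/(Ja25 + MPF) − ki25·Cdc25/(Ji25 + Cdc25)

Newly synthesised cyclin binds Cdk1 immediately and enters as *active*
MPF (the Novák–Tyson convention); Wee1 phosphorylation then moves it to
the inactive pool CycB − MPF. The published table that defines this
system prints the equations as images, with the constants and a prose
glossary in text; the two places where the prose is genuinely ambiguous
were resolved as follows and validated against the published control
coefficients:

* V_wee/V_25 use the two-state form k′(1−X) + k″X (both states retain
  activity), the form used throughout the Novák–Tyson lineage.
* "The Michaelis constant of MPF for Wee1/Cdc25" can place the constant
  in the substrate or in MPF itself. Wee1 inactivation carries its
  constant in the substrate (J_iwee + Wee1); Cdc25 activation carries
  it in MPF (J_a25 + MPF). This is the only combination of the
  defensible placements that reproduces all three published
  coefficients (0.011, 0.004, 0.011) within their printing precision;
  all-substrate placement underestimates the degradation-channel
  coefficient by ~40% and all-MPF placement collapses the
  Michaelis-channel coefficient.

Mitotic entry is the first upward crossing of active MPF = 2.0; the
readout S is CycB at that moment (wild type: S = 2.1046 at t = 10.94).
Since the cell grows linearly in time through G2, a perturbation that
raises S delays entry and lengthens the cell. The default horizon is 50
dimensionless time units — comfortably past the wild-type crossing and
past the crossings of all 10%-perturbed variants.

## The reduced MAPK model

Nine species (ShcGS adaptor pool plus inactive/active pairs of Ras,
Raf, Mek, Erk), twelve constants c1..c12, concentrations in
molecules/cell, time in minutes, horizon 100 min. The published
equation images are likewise unavailable and the printed unit groupings
are internally inconsistent with the prose glossary (e.g. the Mek
deactivation rate printed among the Michaelis constants), so the
right-hand sides are this package's reconstruction, honouring each
constant's stated role and printed value:

    dShcGS/dt  = −c12·Erk*·ShcGS                      (negative feedback)
    Ras:   act = c1·ShcGS·RasGDP/(c2 + RasGDP),  deact = c3·RasGTP
    Raf:   act = c4·(RasGTP/Ras_T)·Raf,          deact = c5·Raf*
    Mek:   act = c6·Raf*·Mek,                    deact = c7·Mek*
    Erk:   act = c8·(Mek*/Mek_T)·Erk/(c9 + Erk), deact = c10·Erk*/(1 + Erk*/c11)

Choices and their rationale:

* c2 is used literally as the Michaelis constant of Ras activation; at
  its printed value the reaction is saturated in RasGDP, making the Ras
  tier switch-like in ShcGS — it stays on until feedback erodes the
  adaptor pool below c3·Ras_T/c1 and then shuts off. This is what makes
  Ras-level perturbations act on the pulse's time axis.
* Raf activation is proportional to the *fraction* of active Ras
  (Ras_T = conserved total), keeping c4 a first-order rate as printed.
  Erk activation is likewise scaled by the active-Mek fraction.
* Erk deactivation is first-order at rate c10 below the Michaelis
  constant c11 and saturates at flux c10·c11 above it ("rate and
  Michaelis constant" per the glossary).
* The Mek tier is a fast mass-action/first-order pair; at full Raf
  activation c6·Raf_T ≈ c7, putting Mek* near half-activation — a
  graded tier, which is what gives Raf/Mek-level perturbations their
  amplitude leverage.

The reconstruction is validated against every qualitative behaviour
stated for the system: tier totals conserved to better than 1e-6
relative, wild-type Erk* a transient pulse (amplitude ≈ 4.4·10^5
molecules/cell ≈ 58% of Erk, peak ≈ 8.5 min, half-max return ≈ 19.5
min), and amplitude graded in the downstream channels. The published
coefficients themselves exist only for the G2-M system, so quantitative
validation is necessarily G2-M-side.

Component dominance in this reconstruction: Mek/Erk *activation*
channels are strongly amplitude-dominant (|C_amp| 3–6× the time
components); Raf and Erk *deactivation* channels are duration-dominant
(they stretch the pulse tail); the feedback channel is peak-dominant;
and Ras-level channels act almost entirely through a shift of the
feedback shutoff time, which moves amplitude, duration and peak
together (near-isotropic vectors with duration strictly the smallest
component). Mutations routed through different tiers therefore carry
three-component vectors pointing in clearly different directions
(~60° between Ras-level and Mek-level), which is the separation the
grouping summary reports. Note this assigns duration dominance to
downstream *deactivation* rather than to the Ras tier itself — an
inversion relative to the published narrative for H-Ras mutations that
the printed constants appear to force on any cascade of this shape (the
feedback rate c12 together with the depletion-set amplitude caps the
shutoff-time shift a Ras perturbation can produce); it is recorded here
as a limitation of the reconstruction.

## Curve metrics

Amplitude is the global maximum of the reporter series (ties resolve to
the earliest time; the discrete maximum is refined by a local quadratic
fit so metrics are stable under re-gridding). Peak time is the time of
that maximum. Duration is measured from t = 0 to the first post-peak
time the signal falls to 50% of amplitude, located by linear
interpolation — the falling-edge reading of "time until signal drops to
50% of its maximum"; full-width-at-half-max was rejected because the
definition references only the drop. A series that never falls to
half-max within the horizon gets duration = horizon with a `censored`
flag, which propagates to coefficients rather than silently becoming a
number.

## ΔΔG handling

Ensemble averages over sampled conformations use Boltzmann-Gibbs
weights w_i ∝ exp(−ΔΔG_i/(k_B·T)) at T = 298 K (the free-energy
evaluation temperature; the MD sampling temperatures are metadata).
Lower-energy conformations are up-weighted, so the average never
exceeds the arithmetic mean and tends to it as T → ∞. The standard
error of a mutation's score is the unweighted standard error of the
ensemble mean propagated through the transform; whether the original
error bars weight the variance is unstated, so the unweighted choice is
flagged as an assumption. Scores always use the max-over-states ΔΔG;
ensembles contribute the uncertainty.

## Replica-exchange Monte Carlo

Energy: χ² = Σ((sim − obs)/σ)² over all reference points; integration
failure yields infinite energy (a rejected move, not an exception).
Within-replica moves perturb **one** randomly chosen free parameter per
iteration (the source algorithm is silent on the move set;
single-coordinate moves keep acceptance interpretable) with step
Δx = s·d·10^e, d ~ U{1..9}, e ~ U{e_min..e_max} (default −4..−1, the
order of magnitude of the dimensionless G2-M constants), s = ±1.
Non-positive proposals are rejected (rate constants are positive).
Acceptance is Metropolis, min(1, exp(−β·ΔE)). Every `swap_interval`
iterations one random adjacent pair attempts an exchange with
probability min(1, exp(Δβ·ΔE)) — the printed convention, under which a
pair whose colder member already holds the lower energy swaps with
probability one. All randomness flows from a single integer seed;
identical seeds give identical chains.

## Statistics

Score-phenotype association is simple (unweighted) ordinary least
squares; r² is the squared Pearson correlation and the two-tailed p
value comes from the exact t distribution with n − 2 degrees of
freedom (panels here have n as small as 5, so no normal approximation).
An inverse-variance weighting flag exists for exploration. The
published R² values themselves are not reproducible from the tabulated
eight pairs (the regression's exact point set is under-specified), so
only their orderings are asserted: semi-restrictive > permissive
temperature, and structural-only ≥ all mutations.

## Numerical choices

Integration uses LSODA (stiff-capable) at rtol 1e-8 / atol 1e-10 with a
4001-point output grid per horizon; the G2-M switch is steep near the
transition and these settings leave the readout stable to ~1e-11
relative under tolerance halving. Threshold crossings are located on
the dense grid by monotone cubic (PCHIP) interpolation plus a bracketed
root solve. REMC energy evaluations relax to rtol 1e-6 on a 1001-point
grid — χ² differences at that accuracy are far below the noise scale.

## What the synthetic generator does and does not emulate

`generate_mutation_set` emulates a disease-mutation panel: 40 mutations
round-robin over the four MAPK proteins, random F/S classes, ΔΔG drawn
log-normal (median 3 kcal/mol, σ_log 0.75 — the bulk lies in the
0.5–10 kcal/mol range typical of destabilising missense mutations) with
a 5% admixture of clash-scale values (20–35 kcal/mol) of the kind
produced when a bulky substitution is scored against a rigid backbone.
`generate_reference_timecourse` adds i.i.d. Gaussian noise of known σ
to model trajectories. Real data differ in ways the generator does not
attempt: ΔΔG errors are correlated within a structure, real impact
classes are not coin flips, real time courses have correlated,
heteroscedastic noise and unknown σ. Passing tests therefore show the
machinery is correct under its stated assumptions, not that those
assumptions hold for any particular experimental dataset.

Problem sizes used by the test suite — a 21-point two-species reference
curve, 4 replicas × 1500 iterations for the recovery check, 10^5 draws
for acceptance-rate checks — were chosen as the smallest sizes at which
the statistical assertions have comfortable margins.

## Known limitations

* The two ODE transcriptions are reconstructions from prose (the
  published equation tables are images); the G2-M reconstruction is
  pinned quantitatively by three published coefficients, the MAPK one
  only by qualitative behaviour.
* The MAPK protein→channel mapping is a synthetic stand-in (the
  original assignment table is supplementary material not redistributed
  here); it is an editable TSV.
* The ODE-derived G2-M coefficients differ slightly from the printed
  (rounded) ones; in particular the printed table rounds the
  degradation- and Michaelis-channel coefficients to the same 0.011,
  while the computed values differ by ~30%, which can transpose the two
  mid-ranked mutations whose ΔΔG ratio is smaller than that.
* No SBML import, no stochastic simulation, no global (Sobol/Morris)
  sensitivity analysis, no ΔΔG prediction, no structure handling.
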