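# Methods

This note documents the models behind `mrnaplant`, the provenance and
units of their parameters, the numerical choices, and what the packaged
baseline scenario and synthetic generator do and do not represent.

## Scope and philosophy

The package is a *desk-scale digital design* of a continuous mRNA-LNP
manufacturing line: simplified steady-state balances and empirical design
equations per stage, wired into a single costed scenario, rather than a
general sequential-modular flowsheet solver. Every stage consumes a block
of the `PlantScenario` object and emits into one JSON report, so the whole
chain — sizing → costing → discounted cash flow → Monte-Carlo — is
reproducible offline from the packaged tables.

## Upstream perfusion culture

**Agitation criteria.** Froude `Fr = N²D/g` (vessel diameter), impeller
Reynolds `Re = ρND²/μ`, and mixing time
`Θm = 5.9 (P/V)^(−1/3) (d_R/D_R)^(−1/3) D_R^(2/3)` (P/V in W/m³, lengths in
m, Θm in s). The design criterion `Fr < 0.1` is checked by the report
runner and violated by the baseline mixing block (Fr ≈ 0.26); the report
emits a warning rather than failing, since the criterion is advisory.
`reynolds` takes a diameter selector (impeller default, vessel optional)
because both conventions appear in practice; all rpm→Hz conversion happens
explicitly at the boundary.

**Monod growth.** `μ = μmax·S/(Ks+S)` with glucose limiting. `μmax = 0.5
h⁻¹` and `Ks = 0.1 g/L` are configuration defaults typical of *E. coli* on
glucose — they are not measured values for this process. The biomass yield
on glucose is 0.4 g/g and the feed glucose 8 g/L. The chemostat closed
form is `S* = Ks·D/(μmax−D)`, `X* = Y(S₀−S*)`, with washout returned at
`D ≥ μmax`.

**Perfusion closure.** The loop topology is: feed `F_in = V/τ`; the culture
passes a cell-retaining ultrafilter; permeate `(1−β)F_in` is cell-free;
the retentate is concentrated by a factor κ and the bleed `βF_in` removes
cells at κ·X; substrate is unretained. Steady state gives an effective
cell dilution rate `D_eff = βκ/τ` and

    μ(S*) = D_eff,   (S₀−S*)/τ = X*(D_eff/Y + m_s),

where `m_s` is a Pirt maintenance coefficient (g substrate · g biomass⁻¹ ·
h⁻¹, default 0). With κ = 1, β = 1, m_s = 0 the loop reduces exactly to
the chemostat. The baseline scenario sets `m_s = 0.05`: with pure Monod
kinetics and substrate-limited operation the harvest rate is nearly
insensitive to the bleed setting, whereas a maintenance burden makes
faster turnover (larger bleed) more productive — the qualitative trend the
empirical response surface for biomass production shows. The maintenance
value is a configuration default, not a measurement. An ODE right-hand
side of the same balances is exposed for oracle testing.

**Response surfaces.** `CodedRSM` evaluates quadratic regressions in
factors linearly coded to [−1, 1]; sparse models (purely linear screening
fits) are supported by treating absent terms as zero. Fitting is ordinary
least squares; the ANOVA table reports partial (type-III) sums of squares
`SS_j = β̂_j²/[(XᵀX)⁻¹]_jj`, which coincide with the sequential
decomposition on the orthogonal designs used here. The physical coding
ranges of the packaged biomass and RNA-rate models are configuration
choices spanning the reported operating windows (e.g. UTP 0.4–4 mM,
polymerase 0.1–0.5 µM, Mg 2–14 mM); they are not published values.

## Chromatography sizing

Internal computation is SI; the table-facing units (cm, cm/s, cP, µm, bar)
convert exactly once at the boundary, because mixed bench units are the
dominant error source in these equations.

- Switch time `t = V(1−ε)/V̇s` (min): solid-phase residence time of the
  equivalent true moving bed in one column.
- Plate count `N = 16(t_R/w)²`; Van Deemter `H = A + B/v + Cv` with B
  retained but defaulted to 0 (longitudinal diffusion matters for gas
  systems); `fit_van_deemter` is OLS on (v, H).
- Kozeny–Blake `ΔP = μK₀(1−ε)²Lu/(d_p²ε³)`, solvable for ΔP, u, L or d_p;
  round-trips are exact to 1e-9 and property-tested.
- Column sizing: mobile-phase holdup = flow × retention time; packed
  volume = holdup/ε; cylinder with `L_c = aspect_ratio × D` (default 2,
  matching the ~2:1 columns of the reference design, e.g. 38 × 19 cm for
  10 L/h at 20 min retention and ε = 0.3). The holdup/porosity convention
  is this package's own; alternatives (e.g. empty-column residence) would
  scale volumes by ε.
- Accumulation vessels: volume = inflow × cycle duration (60 L for 10 L/h
  buffered over a 6 h cycle).
- A scheduling check warns when `switch_time × n_columns` is shorter than
  the retention time (the SMB train could not sustain continuous elution).

## IVT kinetics

Transcription velocity (mM nucleotide/min):

    V = k_app [T7] [MgNTP²⁻][Mg²⁺] / ([MgNTP²⁻] + k₁[Mg²⁺] + k₂)

with `k_app = 2.04 min⁻¹`, `k₁ = 0.23`, `k₂ = 0.094 mM`, and [MgNTP²⁻] the
scarcest of the four per-base complexed pools. k₁ is treated as a
dimensionless multiplier on a mM quantity so the denominator is
homogeneous in mM; the alternative (k₁ carrying mM) would make the
denominator dimensionally mixed. T7 concentration is supplied in µM and
converted internally. No published numeric velocity exists to anchor the
rate, so validation is structural: zero limits, monotonicity in each
concentration (the partial derivatives are positive wherever the other
factors are), and conservation.

**Magnesium speciation.** Two closures:

1. *Binding equilibrium (default)*: a single 1:1 Mg–NTP dissociation
   constant `mg_ntp_kd` (default 0.1 mM, a typical MgNTP value and a
   configuration choice). The bound pool solves the quadratic
   `B² − B(T+M+Kd) + TM = 0` for total NTP `T` and available Mg `M`; each
   base's MgNTP share is proportional to its NTP pool and free Mg is
   `M − B`. This keeps the model functional at the reference design point
   (≈4 mM per NTP, 10 mM Mg), where total NTP exceeds Mg.
2. *Excess-Mg* (`mg_ntp_kd=None`): all NTP counted as complexed, free Mg
   the remainder; requires Mg ≥ total NTP and raises an informative error
   otherwise.

**Stoichiometric bookkeeping.** Per incorporated nucleotide one NTP
(apportioned by transcript base composition) is consumed and one PPi
released; PPi precipitates as Mg₂P₂O₇ consuming a configurable Mg
stoichiometry (default 2). Integration is explicit with per-step
adaptivity: a step that would overdraw the limiting NTP or the Mg budget
is shortened so pools empty smoothly, and NTP/RNA, PPi and Mg conservation
are audited every step (tolerance 1e-9 relative); a breach raises an error
advising a smaller step. The reaction therefore self-terminates on
whichever of NTP or Mg runs out first — with the default feed, Mg is the
binding constraint.

**Design space.** `design_space_region` grid-evaluates a response surface
on a regular coded grid and returns the axis-aligned bounding box of
points at or above a floor; it matches a brute-force point filter exactly
by construction and is tested against an independent loop implementation.

**Scheduling.** Reactor trains run staggered cycles (baseline: three 10 L
reactors, 8 L working volume = 80 % occupancy, 4 h cycles, 80 min
stagger). Downstream feed is flagged continuous iff several reactors
interleave with `stagger × n_reactors ≤ cycle time`; each reactor is
credited `⌊horizon/cycle⌋` cycles per observation horizon.

## LNP shell and packing

**Composition.** The surface-occupying lipid count is sphere surface /
APL. Cholesterol intercalates between phospholipid headgroups by default
and is excluded from the surface budget; its count follows its mole ratio
to the surface pool. This is the only reading that reconciles an APL of
≈0.65 nm² with the reference particle (250 Å diameter, 620 DSPC + 2280
DDAB + 124 PEG on the surface, 2876 cholesterol): the exact APL implied by
those counts is 4π(125 Å)²/3024 = 0.6493 nm², which the two-significant-
figure value 0.65 reproduces only to within a few molecules per species.
Counts are integerized by largest-remainder rounding, preserving the
surface-pool total. DOPE is carried as a species with zero baseline
composition.

**Packing.** The seed-configuration problem places rigid molecules
(templates of atom coordinates about their barycenter, rotated by
extrinsic xyz Euler angles) and scores

    f = Σ pairs max(0, d_tol² − ‖Δp‖)² + Σ atoms max(0, g(p))²

with `d_tol = 2 Å`. The overlap hinge subtracts the *distance* from the
squared tolerance, following the published objective as typeset; a config
flag (`squared_distance_variant`) switches to the conventional
`d_tol² − ‖Δp‖²` form. f vanishes exactly on feasible configurations and
is invariant under global rigid motion when no region constraints are
attached. Built-in region constraints cover inside/outside-sphere,
spherical shells and boxes. The minimizer is a seeded multi-start
gradient-free search (uniform restarts polished by Powell); it is
deterministic per seed, returns the best configuration found with a
feasibility flag, and is intended for toy instances (tens of molecules) —
production packing at full particle scale is out of scope.

## Costing

- Power law `Cp = Cp₀(X/X₀)ⁿ` per equipment item; fixed-price items
  (pumps, skid chromatography units, the microfluidic mixer) pass through.
- Cost-index escalation `Cp,₂ = Cp,₁·I₂/I₁`. Two bundled series: the
  *table-consistent* series (default) encodes, per reference year, the
  escalation ratio implied by the packaged equipment table's own
  reference-year and 2021-EUR columns (one anchor row per year, e.g.
  2013 → 49,519/44,045), so the fixture reproduces its source; and a
  *published* CEPCI annual-average series for general use. The two differ
  materially (e.g. 2013→2021 is +12 % table-consistent vs +25 %
  published); the choice is a named scenario field.
- Capital factoring: FCI = delivered × 4.28 (sum of the solid-fluid-plant
  direct and indirect percentages); working capital is 15 % of TCI, so
  TCI = FCI/0.85. On a delivered basis of 100 this yields FCI 428,
  working capital 75.5 and TCI 503.5, matching the published rounded
  ledger (428/75/503) to ±1.
- Cleanroom life-cycle cost: the published linear regression
  `LCC = −1,645,051 + 5156.6·CA + 68.8·MAV + 34·EAV + 514,211·TAV1 −
  742,442·TAR + 2,996,627·AFC` (EUR). It can go negative for small areas —
  a documented property of the empirical fit — and is floored at zero
  where used in the cost chain. Predictors defined by the source study but
  absent from the printed equation (CL, AAV, RAV, THF, TC) are stored,
  documented and unused. The baseline cleanroom (500 m², FFU ventilation,
  raised-floor return, 30 % filter coverage) amortizes over the plant
  lifetime into utilities; a further `utilities_annual` scalar (default
  200,000 EUR/yr, configuration) covers reactor/pump duty.
- Bill of materials: annual cost = printed quantity × unit price,
  recomputed always (the source table's own totals contain rounding
  inconsistencies, and one total cell is a misprint recomputed here);
  membrane/resin replacement rules are already folded into the annual
  quantities and carried as documentation.
- `COM_d = 0.18·FCI + 2.73·C_L + 1.23·(C_U + C_W + C_R)` with waste
  treatment C_W = 0. Labor is operators × 190,476 EUR/yr (default 5
  operators; the count is configuration).
- Stage shares: per-group subtotal / grand total, reported both as raw
  fractions and integer-rounded percentages. Grouping follows the
  flowsheet stages (fermentation / cell lysis / linearization / IVT /
  formulation), stored explicitly per item.

## Finance and uncertainty

- MACRS-5 half-year schedule (20/32/19.2/11.52/11.52/5.76 % over six
  years) on FCI; the 9.5-year class life sometimes quoted alongside is
  recorded but the named 5-year schedule is what the engine applies.
- Cash flows: TCI phased evenly over construction years 1–3 (the phasing
  is a configuration vector), revenue from year 4, depreciation starting
  the first operating year, working capital (TCI − FCI) recovered in the
  final year. Doses/year = 8,000 g ÷ 30 µg = 266,666,667 (configurable;
  "roughly 270 million").
- MSPD: NPV is strictly increasing in the dose price, so bisection on
  [0.01, 100] EUR/dose to |NPV| < 1 EUR is guaranteed to converge; a
  scenario whose floor price already pays back returns the floor, and a
  price above the ceiling raises a bracketing error.
- Monte-Carlo: triangular priors with the mode at the baseline; material
  unit prices −10 %/+30 %, discount and tax rates ±40 %. (One published
  prior bound, 0.4 for the discount-rate maximum, is inconsistent with its
  own +40 % conversion on a 0.10 baseline; the conversions are what the
  engine applies, giving 0.06–0.14.) Each iteration redraws all priors
  independently, rebuilds the bill of materials and finance rates —
  equipment capital is unaffected by the priors and computed once — and
  re-solves the MSPD. Everything is driven by one `numpy` Generator seed;
  identical seeds give bit-identical results.
- Tornado: one-at-a-time low/high evaluation per prior, others at
  baseline, sorted by swing.
- Density fit: nonlinear least squares of
  `y = a + b/(c√(2π)x)·exp(−ln(x/m)²/(2c²))` (a shifted log-normal) to the
  50-bin normalized histogram; reports R² and raises on degenerate
  histograms. It is a fitted summary of the samples, not a generative
  assumption.

## Baseline scenario and synthetic generator

The packaged baseline holds the full reference plant: 37 equipment rows,
17 material rows, the capital factors, 14 triangular priors, finance
defaults, and the process blocks (mixing at 200 rpm in the 0.23 m IVT
vessel, Monod/perfusion upstream, six chromatography columns, IVT feed of
4 mM per NTP with 10 mM Mg and 0.5 µM T7, the 250 Å LNP shell). Its
canonical JSON form is SHA-256 checksummed in the test suite so silent
fixture drift fails loudly. Derived quantities (scaled costs, escalated
costs, material totals) are always recomputed from primary data.

`generate_scenario(seed, ...)` emits schema-valid random scenarios:
log-uniform reference costs (10²·⁵–10⁶ EUR) and sizes, Lang exponents in
[0.2, 0.8], random stage groups and reference years, log-uniform material
prices/quantities, and the standard prior shapes. Generated scenarios are
guaranteed processable end-to-end (property-tested over many seeds). The
generator emulates the *statistical shape* of the fixture, not its
engineering coherence: random scenarios exercise schema, conservation and
monotonicity properties, so green property tests certify the pipeline's
algebra — not the realism of any particular random plant.

## Numerical choices and determinism

- Bisection tolerance 1 EUR on NPV (≈4 × 10⁻⁹ EUR/dose on the price);
  conservation audits at 1e-9 relative; Kozeny–Blake round-trips at 1e-9.
- Monte-Carlo and packing are the only stochastic operations; both require
  an explicit seed and have no hidden global state. Reports are
  deterministic for fixed inputs up to the provenance timestamp.
- The Monte-Carlo headline runs at 10⁴ iterations (the distribution's
  median is stable to ±0.002 EUR/dose across seeds at that size); the
  sample count is a parameter for users who want tighter tails.

## Known limitations

- No oxygen transfer (kLa), shear-death kinetics (shear limits are config
  values only), or CFD upstream; byproduct chemistry (dsRNA, capping
  enzymology) is out of scope.
- No adsorption-isotherm SMB operating-point design or breakthrough
  simulation — sizing is plate/holdup/pressure-drop level only.
- The Mg–NTP equilibrium uses one pooled dissociation constant; per-base
  constants, MgHNTP⁻/Mg₂NTP species and pH dynamics are not modelled.
- Economics assume equity financing, flat operating costs over the
  lifecycle, a single product and no demand elasticity; utilities beyond
  the cleanroom regression are one scalar.
- Several printed design-table values in the source material are not
  mutually consistent (plate counts vs peak widths, tabulated pressure
  drops vs the pressure-drop equation evaluated on the same rows, one
  Van Deemter fit); this package follows the *equations* and validates
  those operations by closed-form and brute-force oracles instead of the
  irreproducible table entries.
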