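# Methods

## Isotope conventions

All internal computation uses the fractional abundance ¹³F ∈ [0, 1); δ¹³C
(‰ vs VPDB) and the amount ratio R appear only at I/O boundaries. The VPDB
ratio is fixed at 0.011180 exactly — the conventional rounded value — so
that δ→R→F chains are bit-reproducible against hand arithmetic; the extra
digit of the more precise 0.0111802 would change fifth-decimal results
without changing any conclusion. δ < −1000‰ and F outside [0, 1) are
rejected as unphysical.

The two-end-member model assumes the measured pool is a conservative
mixture of exactly two isotopically distinct sources and neglects kinetic
isotope fractionation during methanogenesis; the bias that fractionation
would introduce is not modeled (no fractionation factors are applied
anywhere). Following the measurement design, the DIC endmember is taken at
harvest time and the methanol endmember at the start of the incubation;
a time-averaged DIC endmember can be emulated by passing any other
`IsotopeValue`, but is off by default.

Estimators can return values slightly outside [0, 1] under measurement
noise. The raw value is preserved (`f_raw`), a clamped copy (`f_source`)
is used downstream, and `clamped` flags the event — replicate means ± SD
reported from raw values remain unbiased.

Unlabeled pools default to δ¹³C = −30‰ (typical biogenic organic matter);
every estimator takes explicit backgrounds, so the default only drives
convenience paths. Endmembers closer than 1e−6 in F (below GC-IRMS
precision) raise a degeneracy error rather than amplifying noise.

## Pathway atom maps

The bundled networks encode carbon atom fates, not fluxes. Sources are the
methanol-derived methyl carbon (entering as methyl-H₄SPT) and DIC. Each
reaction maps every product carbon to a reactant atom or a source, and
declares lost atoms (decarboxylations, the formaldehyde released by the
reverse ribulose-monophosphate cleavage); validation enforces that
assignments plus losses account for whole copies of each consumed
reactant, that every compound is produced by exactly one reaction, and
that the graph is acyclic.

Terminal fractions forced by the maps: acetyl-CoA 1/2 methanol (methyl vs
CODH/ACS carbonyl); pyruvate 1/3; fructose-6-phosphate carries its two
methanol carbons at C1/C6, and loss of C1 leaves ribose-5-phosphate at
1/5; the pyrimidine ring keeps one methanol carbon of four (aspartate C3,
after OMP decarboxylation removes the α-carboxyl); the purine ring gets
C2/C8 from formyl-level C1 units taken as methanol-derived (the assignment
consistent with reversible C1 interconversion on H₄SPT) for 2/5; IPP keeps
3/5 after mevalonate decarboxylation, and GGPP/phytanyl inherit 12/20 =
60% methanol carbon. Where the literature leaves intermediate maps open,
the encodings follow standard biosynthetic atom fates; each reaction
carries a note stating its basis. Only transferred carbons count — carrier
atoms (CoA, H₄SPT) are excluded, and tetraether (biphytane) synthesis is
out of scope since those moieties do not label under this metabolism.
Measured phytane/phytene cleavage products are identified with the
20-carbon phytanyl compound.

Bulk RNA provenance uses a mean ribonucleotide of one ribose plus an
equimolar purine/pyrimidine mix (5/19 ≈ 26% methanol carbon), which is
what makes DIC the dominant RNA carbon source and motivates ¹³C-DIC
co-labeling for RNA-SIP.

## Uncertainty propagation

Point estimates use replicate means. Monte-Carlo propagation (default
10 000 seeded draws) perturbs each replicate's δ value with Gaussian noise
of the table's reported per-measurement precision — noise is Gaussian in
δ-space, the convention in which IRMS precision is quoted — re-converts,
re-averages and re-estimates; the resulting SD is then the exact standard
error of the estimator under the stated noise model, which is what makes
the ±3 SD calibration property hold. When no per-measurement precision is
reported, the propagation falls back to a parametric bootstrap of the
observed replicate scatter (coverage then degrades with very few
replicates, as a t-statistic with n−1 degrees of freedom). The
across-replicate spread of per-replicate estimates is reported separately
(`sd_replicate`); the two answer different questions and are labeled as
such.

The rate–f_DIC correlation uses Pearson's r, a two-sided t-test p, and a
Fisher-z 95% CI; rates are two-point finite differences of headspace CH₄
between consecutive sampling days.

## Simulator

The simulator forward-integrates one well-mixed incubation with an Euler
scheme (default Δt = 0.02 d; results are insensitive to Δt because only
harvest-time isotope states feed the estimators). Methanol is consumed
first-order with k defaulting to ln(100)/duration, i.e. 99% consumed by
harvest — only the endpoint matters to the estimators, so the kinetic form
is a convenience. Per step, consumed methyl carbon splits into an
assimilated share (default 5% — a modest growth yield typical of
methanogens; neither larger nor smaller values change any isotopic
conclusion, only pool sizes) and a catabolized share. Catabolized carbon
follows the 4:3:1 disproportionation stoichiometry for the methyl-derived
methane, while a mixotrophic fraction f_mix of total methane carbon is
drawn from the DIC pool at its current ¹³F; methanol-derived CO₂ enters
the DIC pool and dilutes its label by mass balance. Biomass markers
(lipid, RNA; 30/70 split of tracked biomass carbon) accrue with the source
split predicted by the pathway networks, drawing the complementary
DIC-derived carbon from the DIC pool, on top of pre-existing
natural-abundance background pools. Carbon and ¹³C are conserved to
floating-point accuracy at every step; an `infinite_dic` switch idealizes
the DIC pool as a constant reservoir (opening the balance) for
machine-precision recovery studies. Measurement noise — Gaussian in δ,
default 0.5‰ — is applied only at export, via per-replicate substreams of
a single integer seed that is logged and embedded in every manifest.

f_mix is constant by default; a rate-dependent mode
f_mix(rate) = f_max·exp(−rate/r₀) (f_max = 0.12, r₀ = 1000 µmol CH₄ L⁻¹
d⁻¹) emulates the observation that slow methanogenesis channels more CO₂
into methane. The functional form is a modeling choice — the phenomenon is
an observed correlation with no published mechanism — and the defaults
span roughly 2–10% f_DIC/CH₄ across the autoclaved-slurry rate sweep.

Presets encode the four study conditions: sediment slurries from the
sulfate-reduction zone (1 mM MeOH + 10 mM bicarbonate over ~1.9 mM ambient
DIC, f_mix = 0.103, 43 d) and the methanogenic zone (~4.3 mM ambient,
f_mix = 0.034, 19 d), a pure culture (30 mM MeOH + 50 mM DIC, 5% label,
f_mix = 0.025), and the autoclaved slurry (20 mM MeOH, ~10% labeled DIC,
rate-dependent f_mix). Headspace/dissolved partitioning is ignored (single
DIC and CH₄ pools), and no population dynamics are modeled — only the
isotopic consequences (f_mix, rate) of the biology are parameterized.

The RNA buoyant-density model is linear: BD = 1.7785 + 0.035·(F − F_nat)
g mL⁻¹, anchored at the light-window midpoint and sloped so fully labeled
RNA (1.813 g mL⁻¹) sits inside the heavy window. Real CsTFA gradients are
not exactly linear in F; the model is used only for ordering and window
membership, which are robust to the slope.

## What the synthetic data do and do not show

The simulator emulates label dilution, disproportionation stoichiometry,
mixotrophic DIC incorporation into methane and biomass, triplicate
structure, and δ-space instrument noise. It does not emulate kinetic
isotope fractionation, biological between-replicate variability (replicate
trajectories are identical; only measurement noise differs), headspace
partitioning, or community effects. Passing recovery tests therefore
demonstrates the estimators' correctness under the stated noise model —
not that field measurements are free of the corresponding real-world
biases. The documented positive bias of the harvest-time-endmember
inversion under a drifting DIC pool is real, reproduced, and bounded by
the pool's ¹³F drift divided by the endmember span.

## Numerical choices

Tolerances: δ↔F round trips hold to 1e−9 ‰; conservation checks to 1e−9
relative; pathway normalization to 1e−12. Problem sizes used by the test
suite (grids of five f_mix values, 100-trial calibration with 2000 MC
draws, six-treatment correlation sweeps with Δt = 0.05 d) were chosen to
make the statistical properties sharp while keeping the whole suite in the
seconds range. Degenerate inputs fail loudly with typed exceptions mapped
to CLI exit codes (2 schema, 3 numerical).
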