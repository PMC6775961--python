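# misosip

Carbon-flow analysis for mixotrophic methylotrophic methanogenesis in
stable-isotope-probing (SIP) incubations.

"Obligate" methylotrophic methanogens such as *Methanococcoides* spp. make
methane from methyl compounds (classically by disproportionation,
4 CH₃OH → 3 CH₄ + CO₂ + 2 H₂O), yet in marine sediment incubations a
substantial share of both their methane and their biomass carbon comes from
the dissolved inorganic carbon (DIC) pool. Quantifying that share from
¹³C-labeling experiments requires three pieces of machinery, all
implemented here for geomicrobiologists and isotope biogeochemists:

1. **Isotope arithmetic** (`misosip.isotope`). Conversions among δ¹³C (‰ vs
   VPDB, with ¹³C/¹²C of the standard R = 0.011180), the amount ratio
   R = (δ/1000 + 1)·0.011180, and the fractional abundance ¹³F = R/(1+R);
   the two-end-member mixing model

   f_DIC/CH₄ = (¹³F_CH₄ − ¹³F_MeOH) / (¹³F_DIC − ¹³F_MeOH),

   label incorporation ratios X = (¹³F_tend − ¹³F_t0)/¹³F_label for paired
   single-labeling experiments and the derived lipid apportionment
   f_DIC/lipid = X_DIC/(X_DIC + X_MeOH), plus mass-balanced pool mixing and
   its inverse (ambient-pool size from observed label dilution).

2. **Atom-level pathway provenance** (`misosip.provenance`). Directed
   acyclic atom maps from the two carbon entry points (methanol-derived
   methyl-H₄SPT and DIC) through acetyl-CoA/pyruvate into
   ribose-5-phosphate and the nucleobases, and through the modified
   mevalonate pathway into IPP, GGPP and the phytanyl chains of archaeol
   lipids. Propagation yields per-atom source fractions: 1 of 5 ribose
   carbons, 25% of pyrimidine, 40% of purine, and 60% of GGPP/phytanyl
   carbon are methanol-derived; the rest is DIC.

3. **Inference and simulation** (`misosip.inference`, `misosip.simulator`).
   Replicate-table estimators with seeded Monte-Carlo uncertainty, the
   methanogenesis-rate vs f_DIC/CH₄ Pearson correlation (Fisher-z CI),
   buoyant-density classification into the heavy (1.803–1.823 g mL⁻¹) and
   light (1.777–1.780 g mL⁻¹) RNA-SIP gradient windows, and a forward
   incubation simulator with full carbon/¹³C mass balance so that every
   estimator is validated by parameter recovery on synthetic data.

## Worked example

Replay the sulfate-reduction-zone slurry scenario end to end — simulate
triplicate incubations (1 mM methanol + 10 mM ¹³C-bicarbonate over a ~2 mM
endogenous DIC pool), export measurement tables, and run the estimators:

```sh
misosip replay --preset sediment-SRZ --seed 1 --out out/
cat out/sediment-SRZ_report.tsv
```

```text
quantity	value
13F_DIC (%)	81.8
f_DIC/CH4 (%)	10.4
f_DIC/CH4 mc sd (%)	0.00032
f_DIC/CH4 replicate sd (%)	0.00044
f_DIC/CH4 true (%)	10.3
incubation time (d)	43
f_DIC/lipid phytanyl (%)	40.0
provenance p_MEOH lipid (%)	60.0
provenance p_MEOH RNA (%)	26.3
```

Reading: the amended label was diluted and further eroded by unlabeled CO₂
from methanol disproportionation to a harvest ¹³F_DIC of 81.8%; the
two-end-member inversion of the harvest methane attributes 10.4% of its
carbon to DIC, against a simulated truth of 10.3% (the small positive bias
is the documented harvest-time-endmember effect of a drifting DIC pool);
the paired single-label lipid estimate returns 40% DIC-derived phytanyl
carbon, exactly the complement of the pathway's 60% methanol contribution;
and bulk RNA is predicted to be only ~26% methanol-derived, which is why
RNA-SIP of methylotrophic methanogens needs ¹³C-DIC as co-label.

Other entry points:

```sh
misosip convert --from delta --to fraction --value 0     # 0.01105638956
misosip provenance --pathway nucleotide_biosynthesis --compound purine-base
misosip mix --table out/sediment-SRZ_13C-DIC_measurements.tsv --mc 10000 --seed 1
misosip density --value 1.808                            # heavy
misosip replay --preset autoclaved-slurry --seed 1 --out out2/   # adds the
#   rate vs f_DIC/CH4 correlation sweep (r = -0.99, p = 2e-4 at seed 1)
```

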