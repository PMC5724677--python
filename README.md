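# tauflux

Quantitative analysis of dissolved free taurine (Tau) and dissolved free
amino acid (DFAA) release by crustacean mesozooplankton, for biological
oceanographers working with shipboard incubation experiments and
water-column bottle chemistry.

Taurine (2-aminoethanesulfonic acid, C₂H₇NO₃S) is an osmolyte present in
essentially all marine metazoans and a substrate for heterotrophic
bacteria. Copepods and amphipods release it continuously; measuring how
fast, and how quickly the ambient pool turns over, ties zooplankton
physiology to the marine dissolved-organic-matter cycle. `tauflux`
implements the full measurement-to-interpretation chain:

* **quantification** — HPLC method-validation arithmetic: external
  standard-curve linearity (OLS, r²), single-point internal-standard
  quantification with a relative response factor, spike recovery
  R = (Ca − Cu)/Cs × 100, replicate precision (RSD, n−1 sd), S/N-based
  LOD (S/N ≥ 3) and LOQ (S/N ≥ 10), and spike confirmation for samples
  between LOD and LOQ.
* **morphometry** — biovolume from length/diameter (copepods as ellipsoids,
  V = 4/3 π a b c with semi-axes a = L/2, b = c = d/2; amphipods as cones,
  V = 1/3 π r² h) and carbon biomass via 0.08 (copepod) / 0.05 (amphipod)
  pg C µm⁻³.
* **release_rates** — the volumetric release rate is the OLS slope of
  chamber concentration on time, truncated at the last time point up to
  which every tracked analyte still increased; fits with r² < 0.60 or
  slope p > 0.05 are rejected, and rises confined to the first sampling
  interval are flagged as handling-stress artefacts. Slopes are normalised
  to pmol individual⁻¹ h⁻¹ and µmol g⁻¹ C h⁻¹.
* **flux_turnover** — bulk community release RRt = RRc × A (abundance A in
  individuals L⁻¹) and steady-state turnover time T = C/RRt.
* **water_column** — DON by difference, taurine-C/DOC and taurine-N/DON
  pool fractions, depth-layer assignment (epi/meso/bathypelagic at
  200/1000 m), layer means, Mann–Whitney U comparisons and Hedges g effect
  sizes.
* **synthetic** — seeded generators for every input: incubation series
  with linear-rise-then-plateau kinetics and optional stress spikes,
  exponential-with-depth profiles, log-normal specimen morphometrics and
  HPLC standard series.

## Worked example

Simulate a subarctic-Pacific-style chamber (50 animals in 0.5 L, sampled
at 0, 2, …, 12 and 24 h, true community rate 425 pmol ind⁻¹ h⁻¹), fit it,
and scale the community mean to the water column:

```python
from tauflux import release_rates as rr
from tauflux.flux_turnover import turnover_range
from tauflux.synthetic import IncubationScenario, simulate_incubation

scen = IncubationScenario.preset("goa", seed=7)
series = simulate_incubation(scen)
tau = next(s for s in series if s.analyte == "Tau" and not s.is_control)
est = rr.estimate_release_rate(
    tau, [s for s in series if not s.is_control and s is not tau]
)
print(est.qc_status, round(est.rate_per_individual_pmol_h, 1),
      round(est.rate_per_gC_umol_h, 2))
# pass 430.3 1.27

res = turnover_range(10.2, (3.51, 5.09), 2.5)
print(round(res.rr_t_min_nmol_L_d, 1), round(res.rr_t_max_nmol_L_d, 1),
      round(res.turnover_min_d, 2), round(res.turnover_max_d, 2))
# 35.8 51.9 0.05 0.07
```

The chamber estimate recovers the simulated rate (430.3 vs 425 true) with
a passing QC verdict; the second call says a community releasing
10.2 nmol ind⁻¹ d⁻¹ at 3.5–5.1 animals L⁻¹ supplies 35.8–51.9 nmol Tau
L⁻¹ d⁻¹, so a 2.5 nM standing stock turns over in 0.05–0.07 days.

The same steps run from a shell:

```bash
tauflux synth incubation --preset goa --seed 7 --n-chambers 3 --out data/
tauflux rates --incubations data/incubations.csv --chambers data/chambers.csv --out rates.csv
```

`tauflux.datasets` ships the published per-chamber rate tables from the
two campaigns (Gulf of Alaska 2013, North Atlantic 2014) as worked inputs
for the summary statistics.

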