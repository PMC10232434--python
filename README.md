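# riveredith

Spatially explicit riverine biodiversity mapping from environmental DNA
(eDNA) read counts.

Water samples taken at a few dozen river sites carry DNA shed by organisms
living anywhere upstream. `riveredith` turns site-level metabarcoding read
counts into reach-level presence/absence maps for every taxon by modelling
how eDNA is produced, transported downstream and degraded, and then derives
α- and β-diversity patterns — and their significance — across the whole
river network. It is aimed at freshwater ecologists and biodiversity
modellers working with spatially replicated eDNA surveys on dendritic
networks.

## The model

A catchment is a single-outlet tree of *reaches* (segments between
confluences, capped at a maximum length). Each reach *i* sheds eDNA at rate

&nbsp;&nbsp;&nbsp;&nbsp;p_i = p₀ · exp(βᵀ X(i)),

a log-linear response to standardized environmental covariates X(i). The
expected eDNA concentration at a sampling reach *j* sums the upstream
contributions, attenuated by first-order decay during transport:

&nbsp;&nbsp;&nbsp;&nbsp;C_j = (1/Q_j) · Σ_{i ∈ γ(j)} p_i · A_{S,i} · exp(−L_ij / (v̄_ij · τ)),

where γ(j) is the set of reaches upstream of *j* (including *j*), A_{S,i}
the open-water source area of reach *i* (length × width), Q_j the
discharge, L_ij the along-stream distance, v̄_ij the harmonic-mean velocity
of the transit and τ the eDNA decay time. Hydraulic variables are
extrapolated to every reach from a few gauges via power laws on drainage
area, with v = Q/(w·d).

Read counts at a site follow a geometric distribution on {0, 1, 2, …} with
mean proportional to C_j. Each genus × season is fitted independently by
MCMC (differential-evolution with a sampled-history archive, DE-MC-Z) under
weakly informative priors: β ~ N(0, 3), p₀ ~ U(0, 1), τ log-normal with
median 5 h and mode 4 h. The maximum a posteriori parameters yield per-reach
detection probabilities (the chance of a nonzero count if the reach were
disconnected from the network), thresholded at 0.5 into presence/absence
maps.

Diversity analyses on those maps include: genus richness per reach with a
decile-stratified bootstrap slope test against drainage area (spatial
autocorrelation makes classical slope tests invalid here); spatial
β-diversity of randomly matched flow-unconnected reach pairs in upstream vs
downstream groups (Jaccard distance with its turnover/nestedness
partition); temporal β-diversity of each reach against a spring benchmark;
and Welch t-tests of predicted vs raw (site-level) diversity.

## Worked example

The forward model on a three-reach Y network:

```python
from riveredith import (build_network, accumulate_drainage_area, PowerLaw,
                        extrapolate_hydraulics, forward_concentration,
                        local_detection_probability)

net = build_network([
    ("h1", "c", 1000.0, 0.3),   # headwater, 1 km, 0.3 km2 local area
    ("h2", "c", 800.0, 0.4),
    ("c", None, 500.0, 0.5),    # outlet reach
])
accumulate_drainage_area(net)
laws = {"width": PowerLaw(2.0, 0.5), "depth": PowerLaw(0.2, 0.4),
        "discharge": PowerLaw(0.05, 1.0)}
net = extrapolate_hydraulics(net, laws, "spring")
p = {rid: 1e-3 for rid in net.reach_ids}       # uniform production
print(f"drainage area at outlet: {net['c'].drainage_area:.2f} km2")
print(f"discharge at outlet:     {net['c'].discharge:.3f} m3/s")
print(f"expected reads at c:     {forward_concentration(net, p, 4.0, 'c'):.1f}")
print(f"local detection prob:    {local_detection_probability('c', net, p):.3f}")
```

```
drainage area at outlet: 1.20 km2
discharge at outlet:     0.060 m3/s
expected reads at c:     41.4
local detection prob:    0.948
```

The outlet drains 0.3 + 0.4 + 0.5 = 1.2 km²; its discharge follows the
power law 0.05·A¹. Of the ~41 expected reads, most originate in the outlet
reach itself and the rest arrive from the two headwaters, attenuated by
exp(−travel time/τ). The local detection probability μ/(1+μ) ≈ 0.95 ≥ 0.5,
so this taxon would be mapped as present at `c`.

The full pipeline on a synthetic study with known ground truth:

```sh
edith make-scenario -o demo --seed 7     # network + covariates + reads + truth/
edith run -c demo/config.yaml            # filter → fit → map → diversity
head -6 demo/results/summary.txt
```

```
# diversity-pattern summary (seed 7)
group          season          metric                  trend   significant
fish           spring          alpha-vs-area           ↘       yes
fish           spring          spatial-beta            →       no
fish           summer          alpha-vs-area           →       no
fish           summer          spatial-beta            ↑up     yes
```

Each row is one verdict: e.g. fish richness in spring *decreases*
significantly with drainage area (≥95 of 100 bootstrap replicates gave a
negative slope), and summer spatial β-diversity is significantly higher
among upstream than downstream flow-unconnected reach pairs. Tidy CSVs with
the underlying maps, MAP parameters, richness, Jaccard decompositions and
t-tests are written alongside.

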