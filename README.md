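# florivis

Quantitative analysis of floral resource supply and wild-pollinator
visitation from year-round field surveys, plus a synthetic survey generator
for testing the full pipeline without field data.

## The problem

In plant communities invaded by alien species, a handful of resource-rich,
long-flowering plants can dominate the supply of nectar sugar and pollen.
Whether wild pollinating insects (bees and wasps, hoverflies, butterflies)
actually concentrate their visits on those plants — or spread them over the
whole flowering community — determines whether managing for a few
"pollinator-friendly" dominants is good conservation practice. Answering
this requires converting raw field measurements into comparable,
area-based resource quantities, and comparing the *diversity* of
resource-supplying flowers with the diversity of insect-visited flowers.

`florivis` implements that workflow as a tested, reusable pipeline:

1. **Per-flower quantification** — nectar sugar mass per flower (µg),

   s = 10 · d(C) · v · C,  d(C) = 0.0037921 C + 0.0000178 C² + 0.9988603,

   from extracted nectar volume *v* (µL) and refractometer concentration
   *C* (g sucrose / 100 g solution), with a rinse-dilution variant for
   flowers too small for capillary extraction; pollen volume per flower
   (µL) from aliquot grain counts, N = mean(counts) · U / 10, and the
   ellipsoid grain volume V = 4/3 π A B² (µm³, semi-axes A ≥ B).
2. **Area-based availability** — floral-unit counts per 1 m² plot ×
   per-flower species means, summed over measured species.
3. **Contribution shares** — each species' proportion p_i of pooled
   monthly or annual site totals, for both resources and visits by group.
4. **Seasonal trends** — penalized-spline GAMs of plot-level series over
   census day: gamma/log on (resource + 0.0001), negative-binomial/log on
   visit counts with dispersion θ estimated during fitting (via mgcv).
5. **Diversity** — Shannon H′ = −Σ p_i ln p_i and evenness J′ = H′/ln S of
   resource-supplying vs. insect-visited species, with Tukey HSD
   comparisons across categories (sites as replicates).
6. **Synthetic data** — seed-deterministic survey datasets with known
   ground truth and configurable visitation regimes (resource-proportional
   vs. even-preference vs. native-biased), so the headline pattern — a
   diversity gap between visited and resource-supplying flowers — is a
   recoverable simulation property.

## Worked example

```python
from florivis import resources as rs, simulate as sim
from florivis import availability as av, contributions as co, diversity as dv

# per-flower quantification
rs.nectar_sugar_mass("direct", 20.0, nectar_volume_ul=1.0)  # 216.36 µg
v = rs.grain_volume(25.0, 18.0)                             # 4241.2 µm³
rs.pollen_volume_per_flower(40_000, v)                      # 0.1696 µL

# a full synthetic survey, analysed end to end
ds = sim.generate(sim.SimulationConfig(seed=1))
profiles = rs.build_species_profiles(
    ds.nectar_samples, ds.pollen_counts, ds.pollen_grains, ds.species)
totals, per_sp = av.plot_availability(ds.floral_counts, profiles)
annual = co.contribution_table(per_sp, ds.visits, "year")
panel = dv.annual_diversity_panel(annual)
print(panel[(panel.site == "site1") & (panel.study_year == 1)].round(3))
```

```
 site  study_year category  H_prime  richness  J_prime
site1           1      Pol    1.585        27    0.481
site1           1      Sug    1.502        26    0.461
site1           1       AP    3.197        30    0.940
site1           1       WB    3.168        30    0.932
site1           1       BF    3.020        30    0.888
site1           1       HF    3.202        30    0.941
```

Under the default even-preference visitation regime the diversity of
insect-visited flowers (AP ≈ 3.2) far exceeds that of resource-supplying
flowers (Sug/Pol ≈ 1.5, evenness < 0.5): a few alien archetypes dominate
the resource pool while visits are spread across the community. Tukey HSD
across categories (`dv.tukey_compare(panel, 1)`) assigns the visit
categories and the resource categories to different letter groups.

A command-line interface mirrors the stages:

```bash
florivis simulate --out data --seed 1
florivis validate --input-dir data
florivis quantify --input-dir data --out profiles.csv
florivis run-all --seed 1 --out results_dir
```

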