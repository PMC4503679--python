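# rangerisk

Assessing the relative impact of projected climate change on the
extinction risk of montane tree species, IUCN Red List style.

Tropical upper-montane floras (the Andean cloud-forest belt above
1500 m a.s.l. is the motivating system) are thought to be unusually
exposed to warming: thermally specialised species occupy narrow
elevational bands, and the land area available shrinks towards the
summits, so an up-slope range shift is a net loss. `rangerisk`
implements the full assessment chain that turns presence-only herbarium
records and gridded climate into Red List categories and an aggregate
risk index:

1. **Candidate selection** — deduplicate occurrence records, drop
   species with no georeferenced records, single-country endemics,
   species with any record below the altitude threshold, and taxonomic
   synonyms, with full per-rule accounting.
2. **Distribution models** — presence/background classifiers on four
   bioclimatic covariates (mean annual temperature, mean diurnal range,
   precipitation of the wettest and driest months), in three families:
   a penalized additive logistic model (GAM), a classification tree,
   and an RBF support-vector machine. Validation splits records at the
   median latitude and scores ROC/AUC against region-wide or
   within-MCP background points.
3. **Range geometry** — extent of occurrence (EOO) in four nested
   modes: raw minimum convex polygon (MCP); modelled binary range;
   habitat-masked (forest AND ≥ 1500 m); and the precautionary
   MCP-clipped mode, which confines projected ranges to the current MCP
   (no migration beyond present range boundaries). Areas are geodesic
   (cosine-weighted cells; equal-area projection for polygons).
4. **Classification** — criterion B1 from EOO size
   (CR < 100, EN < 5 000, VU < 20 000 km²) and criterion A3 from the
   projected EOO decline (VU ≥ 30 %, EN ≥ 50 %, CR ≥ 80 %), plus
   transition matrices, uplisting counts, protected-area coverage, and
   the Red List Index

       RLI = (M − T) / M,   T = Σ w(c)·n(c),   M = W_EX · N,

   with weights LC = 0, NT = 1, VU = 2, EN = 3, CR = 4, W_EX = 5 — 1
   when every species is Least Concern, 0 when all are Extinct.

Because real occurrence/climate inputs of such studies are rarely
deposited, the package ships a first-class synthetic-data generator:
an elongated montane massif, lapse-rate-driven climate, SRES-style
warming scenarios (+3.0 °C "A2-like", +2.2 °C "B2-like"), a forest
mask, protected-area polygons, and species sampled from *known*
Gaussian climatic niches — so every downstream estimate can be checked
against planted truth.

## Worked example

```python
from rangerisk import redlist

counts = {"CR": 1, "EN": 47, "VU": 28, "NT": 19, "LC": 29, "DD": 5}
print(redlist.rli_report(counts, dd_policy="weight_zero"))
```

prints

```
{'dd_policy': 'weight_zero', 'counts': {...}, 'n_species': 129,
 'T': 220, 'M': 645, 'rli': 0.6589147286821705}
```

i.e. a Red List Index of **0.66**: the 129 species carry 220 of a
maximum 645 weight units of extinction risk.

A full synthetic assessment (generate world → filter → model → project
→ classify → report):

```python
from rangerisk import pipeline

report = pipeline.run(pipeline.PipelineConfig(seed=0))
print(report.filter_report.exclusions)
# {'no_georeference': 917, 'single_country': 1287,
#  'below_altitude': 1400, 'taxonomy': 17}   -> 129 survivors of 3750
print(report.category_counts)
#     B1_present  B1_modelled  A3_A2  A3_B2  combined_highest
# CR           0            0      1      1                 1
# EN          11           13      4      3                10
# VU           2            0      5      1                 2
# NT           0            0      0      0                 0
# LC           0            0      3      8                 0
# DD           0            0      0      0                 0
print(report.uplisted, {k: round(v["rli"], 3) for k, v in report.rli.items()})
# {'A2': 1, 'B2': 1} {'B1_present': 0.431, 'B1_modelled': 0.4,
#  'A3_A2': 0.6, 'A3_B2': 0.769, 'combined_highest': 0.415}
```

The columns are assessment bases: B1 on the present habitat-masked MCP,
B1 on the MCP-clipped modelled range, A3 under each warming scenario,
and the join (most severe category) of present and scenario
assessments. Mean region-wide validation AUCs for the 13 planted
species are 0.97–0.99 across the three model families, dropping to
0.53–0.68 when background points are confined to each species' MCP —
discrimination is much harder inside the occupied range.

The same pipeline is scriptable from the shell:

```sh
rangerisk synth world/ --n-species 13        # write DEM, climate, records...
rangerisk assess out/ --seed 0               # full run, renders all tables
rangerisk rli counts.csv                     # index from a category table
```

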