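# bonebed

Spatial-taphonomic analysis of fossil bonebeds: palaeostratigraphic level
detection, planar point-pattern statistics, bone-fabric (orientation)
statistics, and the NISP/MNI taphonomic accounting used to characterise a
vertebrate assemblage.

## Who this is for

Zooarchaeologists and taphonomists working with per-specimen excavation
tables: 3-D coordinates (x, y in m on the site grid; stratigraphic height z
in cm above the site datum), taxonomic/anatomical identifications, and
coded taphonomic observations (fragment length, green vs dry fracture,
shaft-circumference type, weathering stage, abrasion, carnivore tooth
marks, taphotypes, notches, long-axis trend and plunge). The package
answers the standard site-formation questions: how many discrete
fossiliferous levels are there, are the finds within a level clustered or
random, do bone long axes show a preferred fabric, and what do the
assemblage-level counts say about fragmentation, burial, and carnivore
involvement?

## What it computes

- **Level detection** (`bonebed.levels`) — an unsupervised → human-in-the-loop
  → supervised workflow: a 1-D kernel density of z is split at deep
  interior minima into candidate bands; file-based curation overrides
  (merge/split/adjust/discard) refine them; then a random forest and a
  calibrated RBF-SVM trained on (x, y, z) assign every specimen. Agreement
  takes the shared label, disagreement goes to the more confident
  classifier, and a specimen with both posteriors < 80% is left
  indeterminate. Reliability is summarised by raw agreement, Cohen's
  κ = (p_o − p_e)/(1 − p_e), and per-classifier decisiveness.
- **Point-pattern statistics** (`bonebed.pointpattern`) — kernel intensity
  maps; a Monte Carlo quadrat χ² test of Complete Spatial Randomness with
  p = (1 + #{χ²_sim ≥ χ²_obs})/(nsim + 1); Ripley's K and centred Besag's
  L(r) − r (L = √(K/π)), both in homogeneous and inhomogeneous form with
  the reduced-sample border correction; the Hopkins–Skellam statistic
  A = Σe²ᵢ / Σd²ᵢ (nearest-neighbour over empty-space distances, F(2m, 2m)
  null; A ≪ 1 means clustered); and deterministic DBSCAN with a k-distance
  knee heuristic for ε.
- **Fabric statistics** (`bonebed.orientation`) — axial circular means via
  the angle-doubling construction, mean resultant length R̄, Rayleigh
  uniformity test z = nR̄², plunge profiles (flat/intermediate/steep), and
  per-cluster summaries with rose/stereogram figure helpers.
- **Taphonomic accounting** (`bonebed.taphonomy`) — NISP per taxon (% of
  trophic group and of the total), MNI from element laterality and
  ontogenetic age, mortality profiles (% not adult), fragmentation,
  fracture-state and shaft-circumference tables, and surface-modification
  frequencies, each with its conventional denominator (e.g. tooth-marked
  bones are counted against well-preserved non-dental specimens).
- **Synthetic sites** (`bonebed.synthetic`) — a seeded generator producing
  two vertically separated fossil bands (0–50 and 60–90 cm, 10 cm sterile
  gap, slight NE dip) with Thomas-cluster horizontal structure, NE axial
  fabric and mostly flat plunges; plus `build_vm4_fixture()`, a
  deterministic 1609-specimen assemblage whose marginal counts equal the
  published accounting of the Venta Micena 4 bonebed.

## Worked example

```python
from bonebed import simulate_site
from bonebed.levels import propose_levels, train_consensus, classify_specimens, consensus_report
from bonebed.pointpattern import PointPattern2D, Window, quadrat_csr_test, hopkins_skellam
from bonebed.orientation import circular_mean, plunge_profile

site = simulate_site(seed=1)                      # two-band synthetic site, 2 x 1000 finds
bands = propose_levels(site)
print(f"{len(bands)} levels:", [(b.level_id, round(b.z_min, 1), round(b.z_max, 1)) for b in bands])

model = train_consensus(site, bands, seed=1)
assignments, _ = classify_specimens(model, site, threshold=0.80)
rep = consensus_report(assignments)
print(f"assigned {rep.n_assigned}, indeterminate {rep.n_indeterminate}, "
      f"agreement {rep.agreement_rate:.3f}, kappa {rep.kappa:.2f}")

lower = site.df[site.df["level"] == "L1"]
pat = PointPattern2D(lower[["x", "y"]].to_numpy(), Window(0, 6.5, 0, 6))
q = quadrat_csr_test(pat, 8, 8, nsim=4999, seed=2)
hs = hopkins_skellam(pat, m=100, seed=2)
print(f"quadrat chi2 = {q.chi2:.0f}, p = {q.p_value:.0e}; Hopkins-Skellam A = {hs.A:.3f} ({hs.interpretation})")

fabric = circular_mean(site.df["trend_deg"], axial=True)
prof = plunge_profile(site)
print(f"mean axis = {fabric.mean_deg:.2f} deg, R = {fabric.resultant_length:.2f}; "
      f"flat plunges {100*prof['flat']:.1f}%, steep {100*prof['steep']:.1f}%")
```

prints

```
2 levels: [('L1', -1.7, 53.0), ('L2', 57.0, 93.4)]
assigned {'L1': 1000, 'L2': 1000}, indeterminate 0, agreement 1.000, kappa 1.00
quadrat chi2 = 1504, p = 2e-04; Hopkins-Skellam A = 0.051 (clustered)
mean axis = 34.77 deg, R = 0.77; flat plunges 77.4%, steep 4.2%
```

Both generated bands are recovered (the boundary sits inside the sterile
gap), every specimen is assigned with full inter-classifier agreement, the
lower level is emphatically non-random (the Monte Carlo p-value is the
minimum attainable with 4999 simulations; A ≪ 1 confirms aggregation), and
the generator's NE axial fabric (35°) and plunge mixture (79% flat / 4%
steep) are recovered within sampling error.

The same workflow is available from the shell:

```sh
bonebed simulate --seed 1 --out site.csv
bonebed detect-levels site.csv --seed 1
bonebed run-all --seed 1 --out-dir out/
```

## Layout

```
src/bonebed/
  specimens.py     # domain types, CSV I/O, vocabularies, classification maps
  synthetic.py     # seeded site generator (Thomas process, fabric, attributes)
  fixture.py       # deterministic published-marginals assemblage
  taphonomy.py     # NISP/MNI/mortality/modification accounting
  levels.py        # KDE level proposal, HITL curation, RF+SVM consensus
  pointpattern.py  # CSR tests, K/L, Hopkins-Skellam, DBSCAN
  orientation.py   # axial circular statistics, plunge profiles
  pipeline.py      # end-to-end orchestration with a reproducibility manifest
  plots.py         # density/K-L/cluster/rose/stereogram figures
  cli.py           # `bonebed` command-line interface
```

See `docs/methods.md` for the statistical methods, parameter defaults and
known limitations.
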