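# punapipe

Multi-proxy inference of hunter-gatherer high-elevation land use.

When did people begin living in high mountain environments *permanently*,
rather than visiting them on forays or seasonal rounds? For the Andean
Altiplano (~3800 m a.s.l.) this question is usually attacked with single,
ambiguous lines of archaeological evidence. `punapipe` implements the
multi-proxy alternative as a tested, reusable pipeline for archaeologists and
isotope paleoecologists: it confronts three competing land-use models with
five independent lines of evidence from one site and selects the model —
if any — that survives all of them.

The three models and five hypotheses:

| | logistical use | seasonal use | permanent use |
|---|---|---|---|
| H1 drinking-water δ18O (‰) | −8 to −5 | −12 to −5 | −25 to −8 |
| H2 diet δ13C (‰) | low-elevation range | intermediate | high-elevation range |
| H3 round-trip distance to 2500 m | ≤ 80 km | ≤ 1000 km | any |
| H4 demography | children absent, sexes skewed | full spectrum, parity | full spectrum, parity |
| H5 non-local lithics | abundant | present | absent |

The core pieces:

* **Isotope chemistry** — linear correction chains (`v ← a·v + b`) from
  measured bone carbonate to drinking-water δ18O (VSMOW) and diet δ13C
  (VPDB); collagen quality control (≥35 wt% C, 11–16 wt% N, atomic
  C:N ∈ [2.9, 3.6]); highland/lowland classification at the −8‰ boundary;
  two-sample Kolmogorov–Smirnov comparison against reference distributions.
* **Radiocarbon calibration** — posterior mass at calendar age *t* is
  `w(t) ∝ exp(−(y − μ(t))² / 2(σ² + s(t)²)) / √(σ² + s(t)²)`, normalized over
  the curve grid, with 95% highest-posterior-density intervals.
* **Travel cost** — anisotropic Dijkstra over a DEM with Tobler's hiking
  function `speed = 6·exp(−3.5·|slope + 0.05|)` km/h, minimum-time routes to
  the 2500 m contour, and isochrone bands. Arc/Info ASCII grids in and out;
  planar or geographic (great-circle) cell distances.
* **Demography** — interval-apportioned age-at-death histograms and the
  df=1 chi-square sex-parity test `χ² = Σ(obs − exp)²/exp`.
* **Provenance** — local/non-local lithic tallies and abundance classes.
* **Evidence scorecard** — conjunctive support across hypotheses, and the
  convergence calculus: with per-line false-positive rate *p*, the chance
  that *k* supporting lines are all wrong is *p*ᵏ (0.20² = 0.04).
* **Synthetic data** — seeded populations, assemblages, terrains and
  calibration curves with the statistical signature of each land-use model,
  so the whole pipeline is testable without field data.

A 16-burial bone-chemistry table from a ~7,000-year-old Altiplano site ships
as the packaged example dataset.

## Worked example

```sh
python examples/scorecard.py
```

```
| hypothesis | logistical | seasonal | permanent |
|---|---|---|---|
| H1_d18O | fail | fail | pass |
| H2_d13C | fail | fail | pass |
| H3_distance | fail | pass | pass |
| H4_demography | fail | pass | pass |
| H5_provenance | fail | fail | pass |
| supported / evaluated | 0/5 | 2/5 | 5/5 |

selected model: **permanent** (joint false-positive probability 0.00032 at 0.20 per line)
```

Every burial's drinking-water δ18O (−17.5 to −12.9‰) sits below the −8‰
highland boundary and inside the permanent-use window; diet δ13C (−24 to
−20‰) matches high-elevation resources; the 244 km round-trip to the 2500 m
contour is three times the ethnographic logistical maximum; the burial
population spans young children through 50+ adults with sexes in parity
(χ² = 0.69, p = 0.41 on 8 female vs 5 male); and 99.1% of 539 lithic
artefacts are locally matched. Only the permanent-use model passes all five
tests, and the seasonal model passes only demography and distance — the
conjunction leaves a 0.2⁵ ≈ 3×10⁻⁴ joint false-positive probability under
the illustrative 20%-per-line rate.

The other example scripts (`examples/*.py`) each exercise one capability:
isotope screening, calibration of a 7000 ± 40 ¹⁴C BP date, travel-time
analysis on a synthetic cone, the demographic profile, and the
model-recovery simulation. A thin CLI wraps the shell-facing pieces:

```sh
punapipe simulate --model permanent --n 16 --seed 42 --out bundle/
punapipe travel --dem bundle/dem.asc --source-cell 2 0 --contour 2500 --out out/
# -> minimum time to 2500 m contour: 23.3 h, 122.0 km one-way (244.0 km round-trip)
```

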