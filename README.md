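# wormscreen

An in-silico *Caenorhabditis elegans* vulval-induction drug-screening
pipeline: synthetic plate-image simulation with exact ground truth,
fluorescent-object detection and classification, well-level phenotype
scoring, assay-quality statistics, and rule-based hit selection with a
genetic counter-screen classifier.

## The scientific problem

MAPK/ERK (RAS–RAF–MEK–ERK) signalling specifies vulval cell fates in
*C. elegans*, so the pathway's activity can be read directly from vulva
anatomy: wild-type adults develop one vulva, pathway inhibition produces
vulvaless (Vul) animals, and pathway over-activation produces multivulva
(Muv) animals. In a high-content screen, worms carrying a strong
apical-junction GFP reporter (bright in pharynx and vulva) grow in 96-well
liquid culture with test compounds; each well is imaged in four
non-overlapping fields (GFP + brightfield), and GFP objects are gated by
size and intensity into three classes: vulva-sized foci, adult-sized
pharynges, and smaller (larval) pharynges. Two well-level readouts follow:

* **vulvae per adult** `v/a = n_vulvae / n_adults` — pathway activity
  (≈1 wild type, ≈0 under inhibition, >2 in Muv genotypes);
* **percent larvae** `100 · n_larvae / (n_adults + n_larvae)` — an
  organismal-toxicity proxy (worms that failed to reach adulthood).

Control wells feed the screening-assay quality statistic

```
Z = 1 − 3(σ_p + σ_n) / |μ_p − μ_n|
```

(sample SDs; Z ∈ [0.5, 1] indicates a screen-worthy assay). The decision
layer applies three criteria per compound, in order and with strict
inequalities: (i) *artifact* exclusion when vulva-class counts exceed 2× the
positive-control adult count (fluorescent speckles from progeny, bacteria or
drug precipitates), (ii) *toxicity* exclusion when adults fall below 30% of
the positive control, (iii) compounds with `v/a < 0.4` become primary hits.
Validated hits are then re-run in a *lin-1* loss-of-function (Muv)
background: compounds that suppress the Muv phenotype there act downstream
of (or parallel to) the ELK1-family transcription factor; compounds that do
not are on-pathway hits acting upstream.

Real microscope data is not required anywhere: a seeded simulator renders
wells (~25 worms each; dim autofluorescent bodies, stage-dependent pharynx
plateaus, intense mid-body vulval foci, plus confounder speckles) with exact
per-object ground truth, making every downstream stage testable.

## Worked example

Simulate a small plate (three DMSO negative controls, three trametinib
positive controls, one planted suppressor, one inactive compound), score it,
and call hits:

```bash
wormscreen simulate --config sim.yaml --platemap map.csv --out images/ --seed 1
wormscreen score --images images/ --platemap map.csv --out scores.csv
wormscreen zfactor --scores scores.csv --out zfactor.json
wormscreen screen --scores scores.csv --out hits.json
```

which prints

```
wrote 64 images for 8 wells
scored 8 wells -> scores.csv
Z = 0.817 (excellent)
excluded_artifact=0 excluded_toxic=0 primary_hit=1 non_hit=1
```

and produces one score row per well (`scores.csv`):

```
plate,well,compound,conc_um,role,...,n_vulvae,n_adults,n_larvae,vulvae_per_adult,pct_larvae,...
P1,A01,DMSO,0,negative_control,...,26,23,2,1.13043,8,...
P1,A04,trametinib,7,positive_control,...,1,16,9,0.0625,36,...
P1,B01,compoundX,10,test,...,2,22,3,0.0909091,12,...
P1,B02,compoundY,10,test,...,19,19,6,1,24,...
```

DMSO wells score ≈1.1 vulvae/adult (each adult has one vulva, plus an
occasional bright speckle that passes the vulva gate), the
trametinib-like positive controls ≈0.06–0.1, and the planted suppressor
`compoundX` (0.09 < 0.4) is called the single primary hit while `compoundY`
(1.0) is a non-hit. The control separation yields Z = 0.817. Every command
writes a run-metadata JSON with the package version, seed, decision
thresholds and input digests.

## Package layout

| module | contents |
| --- | --- |
| `wormscreen.simulate` | seeded well/plate renderer with ground truth (`render_well`, `render_plate`) |
| `wormscreen.detect` | segmentation, three-class gating, body/focus assignment (`segment_gfp`, `classify_objects`, `assign_foci_to_bodies`) |
| `wormscreen.score` | well scores and plate score tables (`score_well`, `score_plate`) |
| `wormscreen.stats` | Z-factor, dose–response aggregation, pipeline regression, heatmaps |
| `wormscreen.hits` | primary-hit criteria, validation filtering, counter-screen classifier |
| `wormscreen.platemap` / `config` / `cli` | plate-map and config I/O, per-well seeding, the `wormscreen` CLI |
| `wormscreen.benchmarks` | programmatic calibration-plate and planted-screen layouts |

See `docs/methods.md` for the simulation and detection model, parameter
defaults, and known limitations.
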