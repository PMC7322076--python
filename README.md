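# erestrack

Synthetic VAEM (variable-angle epifluorescence microscopy) time-lapse
generation and quantitative analysis of punctate ER-exit-site (ERES)
dynamics around Golgi stacks in plant cortical cells.

The package has two halves:

1. **Generator** (`erestrack.simulate`) — builds ground-truthed synthetic
   movies: a connected cortical-ER network (tubules, sheets, sheet rims,
   enclosed cavities), Golgi blobs inside cavities surrounded by beaded
   rings of bound puncta (~1.5 µm diameter), free 300–500 nm puncta on ER
   subdomains, streaming + Brownian motion, stochastic capture/release
   kinetics, and a Gaussian-PSF/Poisson/read-noise camera model. Every
   scene carries a full `GroundTruth` record (positions, states,
   subdomain labels, event log) used as the oracle for the analysis half.

2. **Analysis pipeline** — multiscale LoG spot detection with subpixel
   centroids (`detection`), ER segmentation and tubule/sheet/sheet-rim
   classification by skeleton-width (`morphology`), object-based
   colocalization and Golgi-association with beaded-ring diameters
   (`association`), frame-to-frame particle linking, motion
   classification and dwell-filtered capture/release event detection
   (`tracking`), and proportion/interval statistics (`stats`), orchestrated
   by `pipeline.run_pipeline` and the CLI.

## CLI

```bash
# generate a ground-truthed movie (TIFF + truth CSVs)
erestrack simulate --config configs/paper_scenario.yaml --out sim/ --seed 1

# individual stages
erestrack detect   --in sim/movie.tif --channel eres --out puncta.csv
erestrack segment  --in sim/movie.tif --out labels.tif
erestrack associate --in sim/movie.tif --out association.csv
erestrack track    --in sim/movie.tif --out tracks.csv
erestrack events   --in sim/movie.tif --out results/

# full pipeline from a YAML run config (scene or input movie)
erestrack run-all  --config run.yaml --out results/
erestrack validate --config run.yaml   # score against ground truth
```

A run config is a YAML file with a `scene` block (generator parameters)
or an `input_movie` path, plus optional per-stage parameter blocks
(`detection`, `segmentation`, `subdomains`, `association`, `tracking`,
`motion`, `events`). All defaults are in `erestrack.config`.

## Conventions

* Coordinates: `x = column`, `y = row`, pixel centres at integer
  positions, origin at the top-left pixel; physical distances in nm.
* Subdomain label codes: 0 background, 1 tubule, 2 sheet, 3 sheet rim.
* Movies are CTYX TIFF with calibration in the image description;
  results are plain CSV.
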