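# mifquant

Quantification toolkit for multiplex immunofluorescence (mIF) of B-lineage
cells in FFPE tissue sections — built for the setting where a 5-plex panel
(CD79a, CD38, Ki-67, CD19, CD138 plus DAPI and a dedicated autofluorescence
channel) is used to enumerate B cells, plasma cells (PCs) and plasmablasts
(PBs) in kidney biopsies, where endogenous CD138 on renal tubular epithelium
would otherwise inflate antibody-secreting-cell (ASC) counts.

It is aimed at image-analysis scientists and translational pathologists who
need reproducible per-slide and per-cohort cell densities from whole-slide
mIF scans, plus the panel-design arithmetic for sequential tyramide (TSA)
multiplexing.

## What it computes

Starting from a named 7-channel image (or an external integer label mask
from any instance-segmentation tool):

1. **Tissue mask** — Gaussian blur + Otsu (or manual) threshold on the
   autofluorescence channel, minus GeoJSON exclusion ROIs; physical area as
   `true pixels x (pixel_size_um / 1000)^2` mm².
2. **Segmentation** — deterministic watershed on DAPI (smooth → log-scale
   Otsu → distance transform → peak-seeded watershed), with optional
   non-overlapping label expansion to approximate whole-cell regions.
3. **Per-cell features** — mean fluorescence intensity (MFI) per channel
   over each cell's pixels, centroid, area, in-tissue flag.
4. **Gating** — a cell is marker-positive when `MFI >= cutoff` (cutoffs per
   marker: manual, Otsu, or a 2-component Gaussian mixture on log
   intensity); cells bright in autofluorescence are rejected outright.
   Default gates:

   | gate | definition |
   |---|---|
   | `b_cell` | CD79a⁺ / CD138⁻ |
   | `plasma_cell` | CD138⁺ / CD38⁺ / Ki-67⁻ |
   | `permissive_pb` | CD38⁺ / Ki-67⁺ |
   | `bona_fide_pb` | CD138⁺ / CD38⁺ / Ki-67⁺ |

   The CD38 co-requirement is what separates true ASCs from CD138⁺/CD38⁻
   tubular epithelium.
5. **Reports** — per-slide counts, densities (cells/mm²) and fractions (% of
   total tissue cells), aggregated *cumulatively* per cohort (counts and
   areas summed, frequencies recomputed from the sums), with derived
   proportions such as the bona fide PB share of permissive PBs and of all
   ASCs (ASC = PCs + bona fide PBs).
6. **Panel ordering** — given a marker × position elution-tolerance matrix
   (% change in thresholded MFI per heat-elution cycle), find the marker →
   position bijection maximizing summed retention, optionally constrained
   to alternate antibody host species between consecutive positions.

A synthetic **phantom generator** renders tiles of disk cells with planted
phenotypes (lognormal intensities), CD138⁺/CD38⁻ tubular rings and
high-autofluorescence artifact blobs, together with a ground-truth table, so
the whole pipeline is testable with no external images.

## Worked example

```python
import mifquant as mq

spec = mq.PhantomSpec(
    image_shape=(1024, 1024),
    phenotype_counts={"b_cell": 80, "plasma_cell": 60, "bona_fide_pb": 8,
                      "t_nk_like": 12},
    n_tubules=2, n_af_artifacts=3, noise_sd=0.0, seed=1,
)
stack, truth = mq.generate_phantom(spec)

result = mq.run_slide(mq.RunConfig(), stack, slide_id="demo")
print("tissue area  :", round(result.tissue_mask.area_mm2, 4), "mm2")
print("cells found  :", result.labels.n_cells, "of", len(truth), "planted")
print("gate counts  :", result.summary.counts)
print("planted truth:", mq.expected_gate_counts(truth))
```

prints

```
tissue area  : 0.0614 mm2
cells found  : 179 of 179 planted
gate counts  : {'b_cell': 80, 'plasma_cell': 60, 'permissive_pb': 20, 'bona_fide_pb': 8}
planted truth: {'b_cell': 80, 'plasma_cell': 60, 'permissive_pb': 20, 'bona_fide_pb': 8}
```

i.e. every planted nucleus was segmented, and the gates recover the planted
phenotype counts exactly (the 20 permissive PBs are the 8 bona fide PBs plus
the 12 CD38⁺/Ki-67⁺ T/NK-like cells — by design the permissive gate is
contaminated by non-B lineages, which is why the CD138 requirement matters).
The three artifact blobs are autofluorescence-rejected and the tubule rings,
CD138⁺ but CD38⁻, receive no gate at all.

The same flow is available from the shell:

```sh
mifquant simulate --seed 1 --out-image tile.tiff --out-truth truth.csv
mifquant run --image demo tile.tiff --out-prefix report
mifquant panel-order          # bundled 5-plex elution-tolerance matrix
```

`mifquant panel-order` prints the staining sequence
`CD38 → CD79a → CD19 → Ki-67 → CD138` with a summed %-MFI-retention
objective of 360.37 — the host-alternating optimum over all 120 orders.

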