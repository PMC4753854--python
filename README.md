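# corebreak

Automated root phenotyping on soil-core break faces from fluorescence
cassette images.

## The problem

Root system architecture in the field is still measured largely by the
core-break method: a soil core is broken at fixed depth increments and the
roots visible on each fracture face are counted by eye.  Counts calibrate
against washed root length density (RLD, cm of root per cm³ of soil), but
manual counting is slow, inconsistent between operators, and miserable work.
Root tissue autofluoresces blue (peak emission near 460 nm) under 365 nm UV
excitation while soil does not, so a UV-lit imaging box produces
high-contrast images of roots on break faces that software can quantify.

`corebreak` implements the full analysis chain for such images, for root
biologists and phenotyping teams:

1. **Well segmentation** — the forty 45 mm wells of the imaging cassette are
   segmented once per session from a high-contrast template image
   (blue channel, 2× block-average downsampling, median filter, attribute
   filtering keeping near-circular components of plausible area, automatic
   thresholding on a grey-level/gradient bivariate histogram, moment-based
   circle fits, raster-order labels 1–40).
2. **Root detection** — fluorescing roots are segmented as *ridgelines*: a
   Steger-style line detector estimates local ridge orientation from the
   Hessian and keeps pixels that are intensity maxima across the ridge
   (directional non-maximum suppression), linked by hysteresis.  The result
   traces the brightest path inside each linear structure, as a human
   operator would.
3. **Debris exclusion** — straw and lint fluoresce too, but are *thicker*
   than roots: a grey-level opening with a polygonal structuring element of
   the maximum root radius keeps only thick objects; attribute filtering
   (elongation < 5, or area > 0.25 × well area) builds a background image;
   thresholding the background-removed image at 50 grey levels yields the
   debris mask, which is subtracted from the linear-structures mask.
4. **Well association** — roots are kept only if they originate inside a
   well; portions extending past the well rim are recovered by morphological
   reconstruction, and each object is labelled by its majority-overlap well.
5. **Measurement** — objects are filtered by length, hue (must be blue) and
   lightness, then counted and measured per well.  Output is CSV with
   `Dim,Core,RootNumber,RootLength` (overlapping roots merge into one
   object, by design).
6. **Calibration** — windowed counts (break depths *t*, *t*+5, *t*+10 cm
   against the washed RLD of the *t*…*t*+10 cm increment) are correlated
   with RLD by least squares; empty-well counts estimate the false-positive
   rate; a fluorescence-spectroscopy summary locates the root/soil contrast
   peak.
7. **Cost model** — a campaign productivity/cost table comparing manual
   five-person coring teams against smaller teams using the imaging box.

Because no public image set exists for this instrument class, the package
includes a first-class synthetic scene generator (`corebreak.synth`) that
renders cassette templates and fluorescence scenes — dark low-chroma soil
background, blue ridged root strokes, thick debris capsules, sensor noise,
under-exposed (dim) frames — with pixel-level ground truth, so every stage
is testable end to end.

## Worked example

```python
from corebreak import CassetteLayout, generate_template, random_scene
from corebreak.pipeline import params_for_layout, process_frame
from corebreak.wells import find_wells
from corebreak.measure import write_csv

layout = CassetteLayout.default(0.5)          # half-scale synthetic cassette
params = params_for_layout(layout)
template = generate_template(layout, seed=1, jitter_px=2.0, flare=0.05)
wellmap = find_wells(template, params)
print(f"wells found: {wellmap.n_wells}, mean radius {wellmap.mean_radius_px:.1f} px")

scene = random_scene(layout, seed=42, roots_per_well=(0, 2), n_debris=2)
result = process_frame(scene.image, wellmap, params)
m = result.measurement
print(f"dim={m.dim}  total roots={m.total_roots()}  total length={m.total_length():.0f} px")
write_csv(m, "demo.csv")
```

prints

```
wells found: 40, mean radius 72.5 px
dim=0  total roots=36  total length=2667 px
```

and the scene's ground truth contains exactly 36 in-well roots — the two
debris strands are rejected by the thickness rule.  `demo.csv` begins

```
Dim,Core,RootNumber,RootLength
0,1,0,0.0
0,2,2,154.01351487285083
0,3,0,0.0
```

i.e. well 2 holds two detected roots totalling 154 downsampled pixels of
centreline length (multiply by `downsample_factor / px_per_mm` — here
2/13 mm per pixel — for millimetres).

The cost table (`corebreak costs --markdown` on the command line):

| team                   | cores/day | cores/h/person | cost/core % | fixed % | operating % | total % |
|:-----------------------|----------:|---------------:|------------:|--------:|------------:|--------:|
| 5 people               |       130 |           3.71 |         100 |     100 |         100 |     100 |
| 4 people + imaging box |       120 |           4.29 |          87 |     113 |          87 |      89 |
| 3 people + imaging box |       100 |           4.76 |          78 |     113 |          78 |      82 |

A four-person team with the box raises per-person throughput by 16 % over
the five-person manual team; total campaign cost (400 genotypes × 4
replicates × 4 cores × 2 sites × 3 years) falls to ~89 % of baseline even
after buying the box.

## Command line

```bash
corebreak simulate -n 3 --template --scale 0.5 -o scenes   # synthetic data
corebreak wells scenes/template.png -o wellmap.yaml        # daily template
corebreak analyze scenes/scene_*.png --template scenes/template.png -o results
corebreak calibrate manifest.csv rld.csv                   # counts vs RLD
corebreak costs                                            # campaign table
```

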