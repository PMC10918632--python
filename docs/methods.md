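# Methods

## The data-packet model

All annotation derives from a *data packet*: an ordered set of
single-band rasters co-registered on one regular north-up grid in
geographic coordinates (EPSG:4326 decimal degrees; latitude ∈ [−90, 90],
longitude ∈ [−180, 180]). A grid is fully described by the north-west
corner of pixel (0, 0), per-axis resolutions in degrees/pixel, raster
dimensions, and a tile size. Each layer is either *categorical* (integer
codes with a category table mapping code → short/long label; e.g. the
30-class Köppen-Geiger climate coding, or the degree-of-urbanization
settlement coding with classes 30 urban centre … 11 very low density, 10
water) or *continuous* (a number in stated units, e.g. persons/km²).
Every layer records its own nodata sentinel — defaults are 255 for 8-bit
categorical layers and −3.4·10³⁸ for continuous ones, conventional
raster practice, but the recorded per-layer value is authoritative and
nothing downstream assumes the default.

A packet is versioned and, once written, treated as static: deriving a
new version copies the layers and *appends* to the changelog, never
rewrites it, so an annotation produced against version *v* can always be
reproduced by re-reading *v*. Each layer carries one BibTeX entry for
its source; `emit_citations` concatenates entries de-duplicated by
citation key in layer order of first appearance. BibTeX parsing is a
deliberately minimal in-package routine (header shape plus brace
balancing, enough to validate one entry and extract its key), since
nothing more is required of the contract.

### Assembly and resampling

`build_packet` co-registers sources that may arrive on different grids:

- categorical sources: nearest neighbor — each target pixel takes the
  source pixel containing its center. Category codes are never
  interpolated; interpolation would invent classes.
- continuous sources: when coarsening (target resolution coarser than
  source on either axis), the mean of the source pixels whose centers
  fall inside the target pixel footprint, ignoring nodata — this
  preserves density semantics; when refining or at equal resolution,
  nearest neighbor.
- nodata propagates: a target pixel whose sampled source pixel(s) are
  all nodata becomes nodata.

Sources must already be geographic lon/lat; reprojection between
coordinate systems is out of scope and a differing CRS identifier is an
error, not a transform.

## Serialization

A packet directory holds a key-value text manifest (one section per
layer, including the category table and a dtype record), an append-only
`CHANGELOG.txt`, one `citations/<feature>.bib` per layer, and one
uncompressed tiled GeoTIFF per layer with standard georeferencing tags
(ModelPixelScale, ModelTiepoint, a GeoKeyDirectory declaring EPSG:4326,
and the GDAL nodata tag), so layers open in ordinary GIS tooling. The
round-trip contract is bit-exactness of raster values and equality of
all metadata; grid parameters are written with `repr` so floats
round-trip exactly. On read, the georeferencing tags of each raster are
checked against the manifest and any disagreement (e.g. an edited width)
is a hard error. Manifest values are single-line; labels may not contain
the `" | "` separator, and citations live in sidecar files precisely so
they can be arbitrary multi-line BibTeX.

TIFF requires file tile edges in multiples of 16; when a grid's logical
tile size is not such a multiple the file uses the next one up, and
logical tiles are cropped out of the covering file tiles. Caching and
read accounting always operate on logical tiles.

## Point queries

Pixel assignment is `col = ⌊(lon − lon₀)/Δlon⌋`, `row = ⌊(lat₀ −
lat)/Δlat⌋`, with each pixel owning the half-open footprint
[west, east) × (south, north]: a point exactly on the grid's north or
west outer edge is inside pixel row 0/col 0, the south and east outer
edges are outside. Continuous layers return the pixel value itself — no
interpolation, which would manufacture data. A point on an interior tile
boundary belongs to the tile of its pixel; tiles never overlap.
Longitudes are never wrapped: 181°E is a data error to surface, not
−179°.

Because tiles are stored uncompressed at known offsets, a tile fetch is
a genuine partial read (seek + read of that tile's bytes), the local
analogue of a byte-range request against cloud-hosted tiled rasters.
Queries resolve coordinates to tile indices *before* touching the
payload store, whose interface accepts only `(layer, tile_row,
tile_col)`; the read log retains raw request tuples, making the privacy
property auditable in tests rather than asserted.

The per-run tile cache is unbounded by default — a desk-scale packet has
far fewer tiles than memory allows — with an optional LRU `max_tiles`
knob. Caching is an optimization only: annotations are identical with
the cache on or off, and with it on each (layer, tile) is fetched at
most once per run regardless of how many records fall in it.

Annotation statuses: `invalid_coordinates` (field fails the strict
validators or is a missing-value term; all features absent),
`out_of_bounds` (valid WGS84 point outside this packet's grid),
`nodata_partial` (at least one layer had nodata under the point),
`annotated`. Records are never dropped or reordered.

## Coordinate QC

The legacy archive pattern `^[+-]?[0-9]+.?[0-9]{0,8}$` is reproduced
verbatim, unescaped dot included, to demonstrate its two failure modes:
a wildcard character slips through (`1234567890a12345678`) and magnitude
is unbounded (`645209.099648`). The strict replacements are anchored
per-axis patterns accepting optionally signed plain decimals with any
number of fraction digits, bounded at ±90.0 (latitude) and ±180.0
(longitude), the bound itself only with a zero fraction; no exponent
notation, no whitespace. A run of redundant leading zeros is tolerated
("090.0" is ninety degrees), which makes the validators exactly
equivalent to "parses as a plain decimal and the value is in range" — a
property the test suite verifies against an independent character-scan
parser.

Flag semantics separate the two failure modes: a number-shaped string
beyond bounds is `*_OUT_OF_RANGE`, anything else `INVALID_*_SYNTAX`, and
the two never co-occur on one field. An INSDC missing-value term
("not applicable", "not collected", "not provided", "restricted
access"; case-insensitive exact match after trimming) yields
`MISSING_VALUE_VOCAB` and suppresses syntax flags — declared missingness
is not an error.

Null-island detection is exact numeric equality with (0, 0) after
parsing, so "0.00" and "0.0000" both hit. Frequent-location reporting
has no principled universal threshold; the defaults (`min_count=50`,
`min_fraction=0.001`) are deliberately conservative for desk-scale
sheets and both configurable. The water-vs-biome check fires only when
the point's settlement class is water *and* the biome text contains no
water-associated substring (water, marine, ocean, sea, river, lake,
aquatic, wetland, wastewater); the country check compares the packet's
country-code layer under the point with the reported name resolved
against the layer's category table. Both checks return "no
determination" (never a conflict) on missing data, and an unresolvable
country name is a distinct error, not a conflict.

## Summaries and rank correlation

Category distributions count non-missing codes; proportions are over
annotated records only, with missing tallied separately, rows sorted by
count descending then code ascending. `top_share` sums the proportions
of a code set (e.g. the three most-sampled settlement classes).

Spearman's ρ is computed as average ranks (ties share the mean of their
positions) followed by the Pearson correlation of the rank vectors —
the standard tie-corrected form; the naive 6Σd²/(n(n²−1)) shortcut is
biased under ties, and gridded population densities tie heavily.
Incomplete pairs are deleted pairwise with an explicit `n_dropped`.
Significance uses t = ρ·√((n−2)/(1−ρ²)) against Student's t with n−2
degrees of freedom, two-sided; an exact permutation p-value is available
for n ≤ 10. Zero rank variance on either margin is an error
(`DegenerateInput`), not a silent NaN.

## Synthetic data

The generator exists so every pipeline stage has a closed-form oracle:

- raster recipes (`index_gradient` with value = row·width + col,
  rectangular `category_blocks`, `constant`, Gaussian `noise`,
  `country_checkerboard`) return ground-truth closures alongside the
  packet, so any pixel's expected value is computable without reading
  the raster;
- sample sheets draw coordinates uniformly over the grid and corrupt
  disjoint subsets at configured rates, one archive failure mode each:
  null island (0.00, 0.00), out-of-range magnitudes (including
  645209.099648 and 11500.859), malformed strings the legacy pattern
  still accepts, INSDC missing-value terms, and a single repeated
  coordinate. The returned truth table holds each record's intended flag
  set, with frequent-location flags computed against the same thresholds
  the validator will use — a corruption cluster large enough to cross
  those thresholds is *correctly* also frequent;
- density/diversity pairs draw a bivariate normal with Pearson
  correlation r = 2·sin(πρₛ/6), the Gaussian-copula relation giving
  population Spearman exactly ρₛ, then map the density margin through
  exp(5 + 1.5z) to a heavy-tailed persons/km²-like scale (Spearman is
  invariant under strictly monotone maps). The accompanying oracle ρ is
  an independent O(n²) pairwise-counting Spearman on the realized draw.

All randomness flows through NumPy's seeded PCG64 generator; identical
specs give bit-identical outputs across platforms. What the generator
deliberately does **not** emulate: real coastlines or settlement
geography, spatial autocorrelation of climate or population fields, or
realistic marginal distributions of archive metadata. Green tests
therefore demonstrate the correctness of the machinery — pixel math,
partial reads, caching, validators, statistics — not the ecological
validity of any particular real-world packet.

## Scale choices and limitations

Test and acceptance workloads use desk-scale problem sizes chosen to
exercise every code path with headroom: packets up to ~70×50 pixels and
3 layers with tile sizes 8–256, 1,000-point query comparisons,
1,000-record sheets, n = 2,000 correlation draws. The copula calibration
tolerance (±0.06 around a 0.8 target at n = 2,000) follows from the
sampling standard deviation of Spearman's ρ at that n.

Known limitations: one CRS (EPSG:4326) end to end, no reprojection; no
interpolation or focal statistics; no overview pyramids (single full
resolution level); the LRU knob is per-run, with no cross-run
persistence; the country check requires the packet to carry a country
layer; Shannon/phylogenetic diversity values are inputs here, never
computed from sequence data.
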