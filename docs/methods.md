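# Methods

## Document model

A cMDX document separates *template data* (the reusable anatomical schema:
drawing surfaces, drawing-tool definitions, a background image) from
*patient data* (the drawn map and the findings form). The package is a
plain zip archive: `Resource/Mask.xml`, `Resource/Tools.xml`,
`Resource/BGImage.<ext>`, `Content/Map.xml`, `Content/Form.xml` and a
`[Content_Types].xml` part. Drawing surfaces are polygons, rectangles or
ellipses; each prostate slice carries a slice factor (`Percentage`, its
fraction of whole prostate volume) and a derived pixel count
(`PixelVolume`) that is recomputed and rewritten on every save at the
reference resolution. The histology record of a focus (the `Befund`
element: primary/secondary Gleason pattern, score = their sum, grading,
optional real dimensions) travels inside a CDATA section of its graphic
object.

Two serialization details are deliberate format fidelity rather than
convention: colour channels serialize in the order **Alpha;Red;Blue;Green**
(A;R;B;G — note blue before green), and polygon coordinates serialize as
`"X1;Y1 X2;Y2 ..."` with rectangles as `"X;Y;Width;Height"`. Numbers use
`.` decimals with round-trip float formatting; dates are ISO-8601. Zone
polygons (`PZ`), section levels and object kinds are artifact extensions
the printed vocabulary does not define; they live under a separate XML
namespace (`urn:cmdx:extensions:2010`) so conforming readers can ignore
them. Unknown attributes on known elements are kept in an `extras` bag and
round-trip on re-save. Readers accept namespace-free documents (lenient
mode). The `Relation`/`RelationSlide` attributes are opaque linkage
strings preserved verbatim; the only semantics the package assigns is that
foci sharing a non-empty `Relation` value belong to one cluster.

## Rasterization convention

All pixel-based quantities use one convention: pixel (i, j) covers the
half-open unit square [i, i+1) × [j, j+1) and belongs to a shape iff its
center (i+0.5, j+0.5) passes the shape test — the even-odd (crossing
number) rule for polygons, standard inequalities for rectangles and
ellipses. Boundary pixels therefore belong iff their center does, ties
cannot occur at half-integer centers against integer-coordinate edges, and
the whole convention is directly checkable against brute-force per-pixel
loops. The reference resolution scales the longest background-image side
to 512 pixels; area *fractions*, not absolute counts, enter the volume
formula, so any fixed resolution works and 512 keeps a cohort analysis at
interactive speed (the per-surface fraction changes by < 0.5 percentage
points between 512 and 1024 on convex surfaces).

The magic-wand selection is an 8-connected flood fill with a per-channel
Chebyshev colour tolerance. Its "outside contour only" mode fills interior
holes of the selected region (hole = complement component not reaching the
border under 4-connectivity, the dual of 8-connected foreground).
Accepted selections convert to polygons by exact pixel-edge ("crack")
boundary tracing — the traced polygon re-rasterizes to the original mask
exactly, a 10×10 square traces to a 4-vertex polygon of area 100, and
interior holes are stitched in keyhole-style (doubled bridge edges cancel
under the even-odd rule).

## Volume, focality, zones

Tumour volume: cancer area fraction per slice (union over foci — a pixel
either contains cancer or not, so overlapping foci count once) × slice
factor, summed, × prostate volume (specimen weight in grams ≈ cm³; no
shrinkage correction). Seminal-vesicle surfaces carry factor 0 and are
excluded. The default template's slice factors are exact binary fractions
(17/128, 19/128, 17/128, 11/128 per side, base→apex; sum exactly 1), so
the complete-coverage limit returns the prostate volume exactly in
floating point.

Focality: bounding-rectangle overlap with transitive closure (union-find),
intra-slice by default; cross-slice linkage only through `Relation`
metadata. Touching rectangles count as overlapping. The exact-polygon mode
(`--clustering polygon`) replaces the rectangle test with polygon
intersection; on thin diagonal adjacent foci the rectangle rule merges
what the polygon rule keeps separate, which is precisely the mechanism
that depresses multifocal-detection sensitivity below 100%.

Zone localization: per section level (base, middle1, middle2, apex — two
consecutive slices each, a template-declared mapping), the percentage of
cancer pixels falling inside the level's PZ polygons. The default is
cohort-pooled (pixel-weighted); a per-specimen mean mode exists behind a
flag. Levels with zero cancer pixels are excluded from the summary with a
warning. Summary statistics over the per-level values are the mean, the
*sample* standard deviation (n−1), and the median.

The cumulative map counts, per pixel, how many foci cover it across the
cohort (foci, not specimens — two overlapping foci of one specimen
contribute two), rendered blue→red over the schema.

## Encryption

Sensitive personal fields (patient name/ID/birthdate by default;
clinical fields stay plaintext so analysis works without a passphrase) are
encrypted with AES-256 in CTR mode, key derived by PBKDF2-HMAC-SHA256
(200 000 iterations default, recorded in the envelope), and an
HMAC-SHA256 tag over salt‖nonce‖ciphertext (encrypt-then-MAC), so a wrong
passphrase or tampering fails loudly instead of yielding garbage. The AES
core is implemented in-package from the standard Rijndael construction and
is verified against the published known-answer vector in the test suite.
Each `encrypt_field` call uses a fresh random salt and nonce; a package
save derives one key (one salt) for the handful of fields of its form,
with a fresh nonce per field. Envelopes carry a versioned scheme tag
(`cmdx-aes256ctr-hmac-v1`) so future schemes can coexist.

## Synthetic cohorts and what they do (not) show

The generator emulates the study conditions rather than patient data:
255 specimens by default, multifocal rate 0.525, foci predominantly in the
peripheral zone (`pz_bias` 0.75), prostate volumes ≈ N(40, 12²) cm³
truncated at 15, per-focus slice-area fractions ≈ Beta(2, 18) clipped to
[0.01, 0.35]. Foci are smoothed star-convex radial blobs (24 vertices,
log-normal radial modulation) clipped to their placement region and
iteratively rescaled so the realized polygon area hits the target within
0.5% (or the region's capacity); the realized values are what the ground
truth records, so analysis errors measure the pipeline, not the generator.
A PZ-assigned focus lies wholly inside the PZ polygon and a non-PZ focus
wholly outside it, which makes zone membership exact. Multifocal
specimens place their clusters in distinct slices ("well separated");
`adjacency_fraction` of them instead receive a pair of thin diagonal foci
in one slice with disjoint polygons but overlapping bounding rectangles,
the geometry that the rectangle rule falsely merges.

Limitations of the emulation: the schema geometry is stylized (ellipses in
a grid, a chord-segment PZ), focus shapes are star-convex rather than
histologically realistic, foci per specimen follow a configurable
truncated Poisson that is not calibrated to any real distribution, and
passing tests demonstrate correctness of the *computations* on drawn maps
— not that drawn maps faithfully capture histology. Capsular-invasion
editing gestures, HIS integration, barcodes and 3-D illustration are out
of scope; SVG backgrounds are rejected (raster formats only).

## Numerical and design choices

- Overlapping mask surfaces resolve by document order (last on top), both
  in rendering and hit-testing.
- Flood-fill tolerance metric: Chebyshev over RGB; cheap and the standard
  magic-wand behaviour.
- Degenerate geometry (zero-area rectangles/ellipses, < 3-vertex polygons)
  is a validation error; validation never raises, it reports one record
  per violated rule.
- Acceptance and test problem sizes (200-specimen cohorts, 50 oracle
  polygons, 100 flood-fill images, 200 clustering sets) are chosen so the
  binomial/rasterization noise is far below the asserted tolerances while
  a full run stays at desk scale.
- PDF reports are rendered with matplotlib with pinned metadata dates, so
  identical documents produce byte-identical PDFs.
- The `n − 1` standard deviation is reported for zone summaries; with four
  level values the n-divisor alternative differs visibly, and the sample
  form is the conventional cohort statistic.
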