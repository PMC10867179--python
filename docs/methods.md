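# Methods

This note records the models, parameter choices, and numerical conventions
behind `melvasc`, and what the synthetic validation does and does not
demonstrate about real tissue.

## Chromogen model and separation

Each staining round is modeled with Beer–Lambert attenuation: a pixel with
hematoxylin density *h* and AEC density *a* transmits
`I = I₀ · exp(−(h·v_H + a·v_A))`, where `v_H = (0.650, 0.704, 0.286)` and
`v_A = (0.2743, 0.6796, 0.6803)` are the published unit RGB optical-density
vectors for hematoxylin and AEC (Ruifrok–Johnston convention), normalized to
unit length, and `I₀` is the white reference. Optical density uses the
natural logarithm; the base cancels in the forward/inverse pair.
Deconvolution computes `OD = −ln(I/I₀)` and projects it onto the two-vector
basis by least squares, clipping negative projections (off-basis residual
color) to zero. Saturated-black pixels, where OD diverges, are assigned a
ceiling density of 16 and flagged. On two-stain mixtures the inverse is exact
to machine precision; the 2 %-of-range acceptance bound is loose headroom for
quantized inputs.

Background cleaning is deliberately minimal: an optional disk-footprint
median despeckle followed by threshold-to-zero, with the threshold taken as
mean + 2 SD of a user-designated blank region. The exact cleaning chain used
by chromogenic-IHC macros in circulation is not standardized; this
median+threshold stand-in is documented as such. The threshold step is
idempotent; re-running the despeckle is a no-op on piecewise-flat signal but
not guaranteed to be in general, so cleaning is applied once.

## Registration

Rounds of sequential mIHC differ by a stage translation; rotation and
deformation are out of scope. Offsets are estimated from the FFT
cross-correlation of mean-subtracted images; the wraparound interpretations
of the strongest peaks are disambiguated by the Pearson correlation of the
implied overlap, which is also reported as registration quality in [0, 1].
ROIs with any round scoring below 0.5 (configurable; the underlying
"well-registered" judgment is visual in practice) are excluded. Offset
recovery is exact for planted integer shifts up to ±25 % of the frame at the
SNR of the synthetic scenes; subpixel refinement is not attempted because
the downstream analysis is object- not pixel-differential.

The paper-scale ROI preset is a 6.25 mm² square (2.5 mm side); the default
desk-scale synthetic ROI is 1 mm² at 1.0 µm/px so the full test suite runs
in minutes. Scanner resolution is configurable; 0.5 µm/px is the
paper-scale default.

## Region segmentation

Tissue: hematoxylin is smoothed (σ = 2 px, which sharpens the glass
background peak the triangle rule anchors on), triangle-thresholded, and the
cut is then refined to the midpoint of the two class means — the triangle
cut sits at the foot of the background peak, which would dilate the tissue
boundary by the smoothing ramp; the midpoint puts the edge at half-ramp.
Holes are filled and specks under 100 µm² dropped.

Tumor: the S100 channel passes an alternating sequential filter (closing
then opening with disks of radius 1, 2, 3 px — the smallest schedule that
removes single-cell speckle at 1 µm/px), is triangle-thresholded, and
8-connected components under `min_nest_area` (default 500 µm², roughly more
than three melanocyte cross-sections; boundary components of exactly the
minimum are kept) are removed, so isolated S100⁺ cells (Langerhans/dendritic
cells) do not count as tumor. PT = tissue ∧ ¬IT by construction, so
|IT| + |PT| = |tissue| holds pixel-exactly.

Thresholding rules are implemented on histograms with deterministic
tie-breaks (lowest intensity) and are verified against exhaustive searches;
binarization is always `value > threshold`.

## Vessel analysis

Channels are median-denoised (disk r = 1 px) and locally flattened with a
white top-hat (disk r = 15 px; the element must exceed the vessel wall
thickness so walls survive while illumination gradients are removed).
Candidates are the union of the Otsu-binarized AQP1, CD34 and PDPN channels,
8-connected, size-filtered to [100 µm², 10⁶ µm²] (excluding single cells and
scan artifacts), and PDPN⁺ objects with panCK coverage above 0.30 are
removed as basal epithelium.

Channel thresholds are Otsu values floored by a robust background ceiling
(median + 3·1.4826·MAD): Otsu presumes bimodality, and without the floor a
channel whose marker is absent from an ROI would be binarized inside its
noise band. Marker positivity of an object requires coverage ≥ 0.10 of its
pixels above the channel threshold AND an object mean ≥ 0.5× that threshold;
the original per-sample manual thresholds are not recoverable, so these
explicit defaults make runs reproducible and are all configurable.

The gate is strictly hierarchical: AQP1 first (blood), else PDPN
(lymphatic), else anomaly; AQP1/PDPN double-positives follow the blood
branch and are logged. MECA79 is a flag on AQP1⁺ vessels rather than a sixth
class because HEV-like vessels are tabulated across blood subtypes.
Morphology comes from `regionprops` on the object mask; lumen area is
filled-minus-wall area, form factor `4π·area/perimeter²`. Region assignment
is majority (> 50 %) of object pixels in IT, ties to PT; objects entirely
outside tissue are excluded and logged.

## Cell analysis

Nuclei: hematoxylin is Gaussian-smoothed (σ = 1 px), top-hat flattened at an
8 µm radius (removes counterstain wash, keeps ~6 µm nuclei), thresholded
(same guarded-Otsu rule), and touching nuclei are split by watershed on the
distance transform, with seeds from `peak_local_max` on a lightly smoothed
distance map and a physical minimum seed separation of 4 µm (smoothing the
distance map suppresses spurious plateau peaks on barely resolved nuclei at
coarse pixel sizes). Intensities are measured over the nucleus dilated by
2 px, a membrane/cytoplasm proxy for non-nuclear chromogens. Nucleus areas
outside [10, 200] µm² are flagged, not dropped.

Gate thresholds per marker derive from Otsu on the distribution of per-cell
means, accepted only when the split's between-class variance fraction
(Otsu's effectiveness η) reaches 0.85 — a pure-noise channel tops out near
0.65, while genuinely stained populations even at a few percent positives
score above 0.9 — so absent markers stay silent. The class gate runs
CD68-first (macrophages show weak CD45), then CD45-gated CD8/CD20, then
other-CD45; multi-lineage positives resolve to the highest z-scored lineage
and are logged.

## Spatial metrics

Infiltration: the IT:PT CD8 density ratio with default cutoff 1.0
(INFILTRATED at ratio ≥ 1, including PT = 0 with IT > 0; both-zero or
missing regions are UNDEFINED). The cutoff is exposed in config and the raw
ratio always reported alongside.

TLS: single-linkage clustering (kd-tree pairs + connected components,
verified against a brute-force pairwise graph) of pooled CD8⁺ T and CD20⁺ B
cell centroids at a 50 µm linkage radius; clusters with ≥ 10 of each lineage
are TLS. The defaults demand genuine co-aggregation at lymphocyte scale and
are configurable; whether the original calls used a count rule or visual
identification is not documented, so the rule here is explicit. Vessels
associate with a TLS when their centroid lies within 100 µm of the cluster's
convex hull (vessels sit at aggregate margins).

Densities are reported against region area by default and additionally
against whole-tissue area, since figure-level density denominators are
ambiguous between the two. Proportions are computed within the blood and
lymphatic families separately and are missing (not 0/0) when a family is
absent.

## Statistics

Two-group comparisons test each group for normality (Shapiro–Wilk at
α = 0.05, the operationalization of an unnamed normality check) and use
Student's t (paired or unpaired) when both pass, otherwise
Wilcoxon/Mann–Whitney; the chosen test is always named in the output. The
procedure holds its nominal size (0.05 ± 0.02 at 1000 null replicates,
Normal and lognormal). Correlations switch between Pearson and Spearman on
the same criterion. One-way ANOVA covers ≥ 3 groups; two groups delegate to
the adaptive comparison. No multiple-testing correction is applied — none is
prescribed by the workflow — so raw p-values with test names are emitted for
downstream adjustment.

Inflammatory environments: per-sample leukocyte-class densities are z-scored
per class across samples (matching a heatmap scaled along its marker rows;
constant classes scale to zero and are flagged) and clustered with
Ward/Euclidean agglomeration cut at k = 3, a choice operationalizing the
three observed environment types; labels are renumbered by descending mean
CD8 density so "inflamed" / "t_cell_rich" / "uninflamed" naming is
reproducible. k is configurable.

Sample aggregation is the plain mean of non-missing ROI values per sample,
with `n_rois` recorded. The cohort-accounting module encodes the discovery
cohort's sample flow (27 + 14 sLN-negative/positive resections passing QA,
13 excluded for tissue loss, 28 analyzed) and checks every characteristics
category sums to the analyzed size.

## Synthetic data: what it emulates, and what it does not

`melvasc.simulate` draws, on a noise background: an elliptical tissue blob
carrying a spatially textured hematoxylin wash (texture scale 40 µm, range
0.30–0.70 of contrast — the texture makes glass the modal histogram class,
as on scanned slides); two S100⁺ tumor nests; vessels as filled annuli whose
walls are positive for their subtype's markers and whose lumen stays at
background (giving analytic truth for morphology and openness); 3 µm-radius
cells positive for their class markers, with macrophages receiving
deliberately weak (0.3× contrast) CD45; TLS as planted disks of CD8/CD20
cells with an HEV-like (AQP1⁺CD34⁺MECA79⁺) vessel at the margin; Gaussian
noise (default contrast 0.5, σ 0.05 — SNR 10, the high-SNR regime of
chromogenic staining). All randomness derives from the spec seed and two
runs are pixel-identical.

Random layouts use hard-core rejection sampling so planted objects are
unambiguous ground truth: vessels keep clear of each other, diffuse
CD8/CD20 lymphocytes keep 55 µm (above the TLS linkage radius) from each
other and from aggregates — the separation scale between diffuse infiltrate
and genuine aggregation — and a lymphocyte that cannot be placed under that
constraint is demoted to the non-clustering other-CD45 class. Object sizes
scale down with ROI extent (floored at biologically sensible minima) so
small test ROIs remain feasible. Default study conditions per ROI: 1 mm²,
20 vessels (blood-dominated, mostly CD34⁺; lymphatics mostly LYVE-1⁻, with
10 % of blood vessels MECA79⁺), 300 cells, 1 TLS of 15 CD8 + 20 CD20.

Passing the planted-truth suite shows the pipeline recovers objects,
phenotypes, compartments and densities when its model assumptions hold
(annular vessels, disk nuclei, flat chromogen levels, Gaussian noise,
well-separated objects). It does not demonstrate robustness to melanin
pigment, staining batch variation, tissue folds/loss, nuclear crowding,
irregular vessel cross-sections, or registration failure modes beyond
translation — on real slides the configurable thresholds exist precisely
because these occur.

## Numerical conventions and limitations

- 8-connectivity for all component labeling; half-open, row-major, 0-based
  pixel boxes; areas are pixel counts × (pixel size)².
- All threshold rules break ties toward lower intensity; every stochastic
  step takes an explicit seed; pipeline runs are byte-reproducible.
- Degenerate inputs (constant images, empty masks, zero-area regions,
  constant vectors) return flagged missing values or raise named errors
  rather than dividing by zero.
- ROI selection on real material (presence of PDPN⁺ lymphatics at the
  tumor–stroma interface) is a documented manual/config step, not automated.
- Deformable registration, melanin correction, stain-vector estimation,
  multi-class tissue typing, TLS maturity staging, and survival analysis are
  out of scope.
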