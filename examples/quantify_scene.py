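"""Generate a synthetic muscle scene and quantify granule content per region.

Builds one 256-pixel EM-like scene with known ground truth, counts granule
pixels per cell region, and chains pixel fraction -> volume fraction ->
glycogen concentration.  In the compressed fixture geometry granule disks
are wider than the thin SR stripes, so measured per-region fractions mix
the seeded densities with spillover from neighboring regions.
"""

from glycovol import SceneConfig, generate_scene, pixel_fraction, summarize

image, locations, granules = generate_scene(SceneConfig(size_px=256, seed=42))
quant = pixel_fraction(locations, granules, slice_thickness_nm=60.0, image_id="demo")

print(f"{'region':>10}  {'N_R':>7}  {'n_R':>6}  {'pf_R':>7}  {'vf':>7}  {'[glyc] g/l tissue':>17}")
for res in summarize(quant):
    print(
        f"{res.region:>10}  {quant.N[res.region]:>7}  {quant.n[res.region]:>6}  "
        f"{res.pf:>7.4f}  {res.vf:>7.4f}  {res.glycogen_muscle_g_per_l:>17.2f}"
    )

print(
    "\npf_R is the fraction of region pixels inside granules; vf the derived"
    "\n3-D volume fraction; the last column is grams of granular glycogen per"
    "\nliter of muscle tissue implied by that volume fraction."
)
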