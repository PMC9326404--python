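"""Grayscale coefficient images and masked texture/color features.

Renders two leaves differing only in potassium, builds the 8-bit CWT-9 wavelet-
coefficient image at 800 nm for each, and compares their gray-level
co-occurrence (GLCM) statistics: the generator links speckle amplitude
negatively to K, so the low-K leaf should show higher contrast.
"""

import leafspec as ls

config = ls.SceneConfig(image_shape=(96, 96))

for k in (0.5, 2.2):
    cube, _, truth = ls.render_scene(config, k_percent=k, seed=11)
    refl = ls.trim_bands(ls.calibrate_reflectance(
        cube, panel_reflectance=config.panel_reflectance))
    mask = ls.segment_leaf(refl)
    img = ls.coefficient_image(refl, mask, scale_exponent=9, wavelength=800.0)

    tex = ls.texture_features(img, mask, wavelength_nm=800.0)
    col = ls.color_features(img, mask, wavelength_nm=800.0)
    print(f"K = {k:.1f}%  (speckle amplitude {truth.texture_effect:.3f})")
    print(f"  {len(tex)} texture features, e.g. "
          f"800 nm-CON-0° = {tex['800 nm-CON-0°']:.1f}, "
          f"800 nm-MEA (ENT) = {tex['800 nm-MEA (ENT)']:.3f}")
    print(f"  {len(col)} color features: "
          + ", ".join(f"{n.split('-')[-1]} = {v:.2f}"
                      for n, v in col.items()))
print("Contrast (CON) rises with surface roughness; the K-deficient leaf "
      "has the larger speckle amplitude and therefore the higher CON.")
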