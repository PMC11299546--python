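"""Generate a ground-truth phantom and segment it.

Builds a folded brain phantom with 3% noise, runs adaptive-MAP
segmentation with partial-volume estimation, and compares the result with
the generator's exact ground truth.
"""
import t1morph as tm
from t1morph import denoise as dn, segment as sg

spec = tm.PhantomSpec(noise_percent=3.0, fold_amplitude=2.0, seed=42)
vol, truth = tm.generate_phantom(spec)
print(f"phantom: {vol.shape} voxels at {vol.voxel_size[0]:.1f} mm, "
      f"true TIV {truth.tiv_ml:.1f} ml")

denoised = dn.sanlm(vol)
mask = sg.head_mask(denoised)
model = sg.init_classes(denoised, mask)
seg = sg.pve(denoised, sg.amap(denoised, model, mask))

k_gm = tm.kappa(seg.hard_labels(), truth.hard_labels, tissue=2)
vols = sg.tiv(seg, vol.voxel_volume_mm3)
print(f"GM kappa vs truth: {k_gm:.4f}   (1.0 = perfect correspondence)")
print(f"estimated TIV: {vols['tiv_ml']:.1f} ml "
      f"(GM {vols['gm_ml']:.1f}, WM {vols['wm_ml']:.1f}, "
      f"CSF {vols['csf_ml']:.1f})")
# A kappa above ~0.97 at this noise level means nearly every voxel is
# assigned the tissue that actually fills most of it.
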