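"""Spatially normalize a scan and strip extracranial tissue.

A phantom subject saved with native voxel sizes is normalized into template
space: header voxel sizes scaled up by 4, affine + nonlinear registration
to the template, resampling, intracranial masking.  The extracted brain is
then compared with the ground-truth brain support using the four overlap
measures (optimal values: JS 100%, RV/FP/FN 0%).
"""

from ratpet import (
    PhantomSpec,
    TemplateSet,
    apply_mask,
    extract_brain,
    make_ground_truth,
    overlap_report,
    scale_voxel_header,
    smooth_gaussian,
    spatial_normalize,
)
from ratpet.phantom import make_subject

gt = make_ground_truth(PhantomSpec())
template = smooth_gaussian(gt.pet, (2, 2, 4))
ts = TemplateSet(
    template=template,
    canonical=apply_mask(template, gt.brain_mask),
    mask=gt.brain_mask,
)

subject = make_subject(gt, subject_seed=31)
native = scale_voxel_header(subject.volume, 0.25)  # emulate a native-header scan

result = spatial_normalize(native, ts, scale_factor=4.0, shear_to=None)
canonical, auto_mask = extract_brain(result.volume)
report = overlap_report(ts.mask, auto_mask)

print(f"normalized volume: {result.volume.shape} at {result.volume.voxel_size} mm")
print(f"estimated translations (mm): "
      f"{tuple(round(float(t), 2) for t in result.transform.affine.translations)}")
print(f"JS {report.js:.2f}%  RV {report.rv:.2f}%  FP {report.fp:.2f}%  FN {report.fn:.2f}%")
print("JS near 100% and FP/FN near 0% mean the automatic extraction reproduces "
      "the true intracranial support after normalization.")
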