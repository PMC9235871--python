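# Demo pipeline configuration: the study conditions at a light raster scale.
# 60 vines in 6 north-south rows (2.4 x 1 m spacing), water potentials on a
# 30-vine subset, noisy quantized sensor, per-pixel index averaging,
# 3 deletion groups, forward iPLS at interval widths 10 and 5.
seed: 1
n_vines: 60
ecophys_subset: 30
n_rows: 6
vines_per_row: 10
gsd: 0.05
noise_free: false
canopy_noise_sd: 0.01
dn_noise_sd: 20.0
aggregation: index-mean
dhvi_mode: window
clip_policy: none
height_threshold_m: 0.5
shadow_threshold: 0.15
cv_k: 3
lv_max: 10
ipls_widths: [10, 5]
centering: fold
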