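{
  "comment": "Default synthetic HA-WBRT head phantom and dose model. Geometry is in DICOM patient coordinates (LPS, mm): +x left, +y posterior, +z superior. All structure primitives are axis-aligned ellipsoids or y-axis cylinders; the seed controls a small sub-voxel jitter of the structure centers and the dose noise. Dose-model defaults are calibrated (scripts/calibrate_phantom.py) so the default phantom passes the packaged NRG-CC001 goal set after prescription normalization.",
  "grid": {
    "spacing_mm": [2.5, 2.5, 2.5],
    "dims": [96, 96, 96],
    "origin_mm": [-118.75, -118.75, -118.75]
  },
  "seed": 1234,
  "jitter_mm": 1.0,
  "structures": {
    "Body": {"shape": "ellipsoid", "center": [0, 0, 0], "semi_axes": [80, 95, 105]},
    "PTV_3000": {"shape": "ellipsoid", "center": [0, -5, 15], "semi_axes": [65, 75, 68]},
    "Hippocampus_L": {"shape": "ellipsoid", "center": [25, 5, 0], "semi_axes": [5.5, 18, 7.3]},
    "Hippocampus_R": {"shape": "ellipsoid", "center": [-25, 5, 0], "semi_axes": [5.5, 18, 7.3]},
    "OpticNerve_L": {"shape": "cylinder_y", "center": [12, -60, -50], "radius_mm": 2.5, "half_length_mm": 15},
    "OpticNerve_R": {"shape": "cylinder_y", "center": [-12, -60, -50], "radius_mm": 2.5, "half_length_mm": 15},
    "OpticChiasm": {"shape": "ellipsoid", "center": [0, -48, -52], "semi_axes": [8, 5, 4]}
  },
  "target_volumes_cc": {
    "hippocampus_per_side": 3.0
  },
  "ct": {"air_hu": -1000, "tissue_hu": 30},
  "dose_model": {
    "rx_gy": 30.0,
    "ripple_amplitude": 0.04,
    "ripple_wavelength_mm": 70.0,
    "cold_well_depth": 0.73,
    "cold_well_width_mm": 2.5,
    "falloff_length_mm": 12.0,
    "noise_sigma_gy": 0.15
  }
}
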