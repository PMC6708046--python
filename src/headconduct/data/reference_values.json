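{
  "name": "head-conductivity-reference-v1",
  "description": "Recommended quality-weighted mean head tissue conductivities (S/m; the brain-to-skull conductivity ratio is dimensionless) with dispersion and observed min/max bounds from the underlying per-tissue syntheses.",
  "entries": [
    {"tissue": "whole_scalp", "weighted_mean": 0.41, "sd": 0.18, "minimum": 0.137, "maximum": 2.1, "n_values": 44, "n_studies": 10},
    {"tissue": "fat", "weighted_mean": 0.61, "sd": null, "minimum": 0.61, "maximum": 0.61, "n_values": 1, "n_studies": 1},
    {"tissue": "muscle", "weighted_mean": 0.3243, "sd": 0.1526, "minimum": 0.1482, "maximum": 0.4167, "n_values": 3, "n_studies": 1},
    {"tissue": "whole_skull", "weighted_mean": 0.02, "sd": 0.02, "minimum": 0.0182, "maximum": 1.718, "n_values": 92, "n_studies": 20},
    {"tissue": "spongiform", "weighted_mean": 0.048, "sd": 0.07, "minimum": 0.0012, "maximum": 0.289, "n_values": 18, "n_studies": 5},
    {"tissue": "whole_compact", "weighted_mean": 0.005, "sd": 0.002, "minimum": 0.0024, "maximum": 0.0079, "n_values": 9, "n_studies": 4},
    {"tissue": "outer_compact", "weighted_mean": 0.005, "sd": 0.003, "minimum": 0.0008, "maximum": 0.0078, "n_values": 10, "n_studies": 2},
    {"tissue": "inner_compact", "weighted_mean": 0.007, "sd": 0.004, "minimum": 0.0028, "maximum": 0.0129, "n_values": 10, "n_studies": 2},
    {"tissue": "sutures", "weighted_mean": 0.0266, "sd": 0.0239, "minimum": 0.0078, "maximum": 0.0735, "n_values": 6, "n_studies": 2},
    {"tissue": "csf", "weighted_mean": 1.71, "sd": 0.3, "minimum": 1.0, "maximum": 2.51, "n_values": 43, "n_studies": 14},
    {"tissue": "whole_brain", "weighted_mean": 0.3746, "sd": 0.1322, "minimum": 0.0541, "maximum": 3.75, "n_values": 63, "n_studies": 11},
    {"tissue": "gm", "weighted_mean": 0.47, "sd": 0.24, "minimum": 0.06, "maximum": 2.47, "n_values": 66, "n_studies": 16},
    {"tissue": "wm", "weighted_mean": 0.22, "sd": 0.17, "minimum": 0.0646, "maximum": 0.81, "n_values": 104, "n_studies": 15},
    {"tissue": "wm_perp", "weighted_mean": 0.12, "sd": 0.05, "minimum": 0.062, "maximum": 0.439, "n_values": 41, "n_studies": 3},
    {"tissue": "wm_par", "weighted_mean": 0.12, "sd": 0.09, "minimum": 0.0543, "maximum": 0.915, "n_values": 41, "n_studies": 3},
    {"tissue": "blood", "weighted_mean": 0.57, "sd": 0.11, "minimum": 0.433, "maximum": 0.7622, "n_values": 4, "n_studies": 3},
    {"tissue": "dura", "weighted_mean": 0.46, "sd": null, "minimum": 0.46, "maximum": 0.46, "n_values": 1, "n_studies": 1},
    {"tissue": "cerebellum", "weighted_mean": 0.537, "sd": 0.1141, "minimum": 0.391, "maximum": 0.635, "n_values": 4, "n_studies": 1},
    {"tissue": "lesion", "weighted_mean": 0.8757, "sd": 0.3772, "minimum": 0.1, "maximum": 1.77, "n_values": 19, "n_studies": 5},
    {"tissue": "ez", "weighted_mean": 0.2949, "sd": 0.0737, "minimum": 0.232, "maximum": 0.5278, "n_values": 15, "n_studies": 1},
    {"tissue": "bscr", "weighted_mean": 50.4, "sd": 39.0, "minimum": 17.9, "maximum": 290.0, "n_values": 10, "n_studies": 4}
  ]
}
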