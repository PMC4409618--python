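{
  "KF1": {
    "kc_source": "hammersmith",
    "description": "Original KF algorithm",
    "reclass_global": {"vertebrae": "tumour"}
  },
  "KF2": {
    "kc_source": "hammersmith",
    "description": "Temporal smoothing added",
    "temporal_smoothing": true,
    "reclass_global": {"vertebrae": "tumour"}
  },
  "KF3": {
    "kc_source": "hammersmith",
    "description": "Frame times of the scan data adjusted to the class schedule",
    "resample_direction": "scan_to_classes",
    "reclass_global": {"vertebrae": "tumour"}
  },
  "KF4": {
    "kc_source": "hammersmith",
    "description": "Liver class reclassified as tumour, classification 9-60 min p.i.",
    "reclass_global": {"liver": "tumour", "vertebrae": "tumour"},
    "time_window_min": [9, 60]
  },
  "KF5": {
    "kc_source": "hammersmith",
    "description": "Liver class reclassified as tumour, classification 20-60 min p.i.",
    "reclass_global": {"liver": "tumour", "vertebrae": "tumour"},
    "time_window_min": [20, 60]
  },
  "KF6": {
    "kc_source": "hammersmith",
    "description": "Liver class omitted",
    "omit_classes": ["liver"],
    "reclass_global": {"vertebrae": "tumour"}
  },
  "KF7": {
    "kc_source": "hammersmith",
    "description": "Liver and vertebrae classes omitted",
    "omit_classes": ["liver", "vertebrae"],
    "reclass_global": {}
  },
  "KF8": {
    "kc_source": "vumc",
    "description": "Original KF algorithm with locally derived classes",
    "reclass_global": {"vertebrae": "tumour"}
  },
  "KF9": {
    "kc_source": "vumc",
    "description": "Liver and vertebrae reclassified as tumour within the lesion mask, temporal smoothing, classification 15-60 min p.i.",
    "temporal_smoothing": true,
    "time_window_min": [15, 60],
    "reclass_global": {},
    "reclass_in_mask": {"liver": "tumour", "vertebrae": "tumour"}
  }
}
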