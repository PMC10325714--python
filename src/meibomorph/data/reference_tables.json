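{
  "description": "Published summary rows from the reference clinical cohort (children with unilateral myopia treated overnight with an orthokeratology lens in the myopic eye; contralateral untreated eyes as controls; central-10-gland deformation coefficients after 12 months). Values are transcribed at the printed 3-decimal precision; per-row n is not printed and is recovered from the SD/SE ratio.",
  "paired_differences": {
    "comment": "Per-gland paired differences, treatment minus control eye: mean, SD, SE of the mean, 95% CI for the difference, paired t, two-tailed p.",
    "rows": [
      {"gland": 1, "mean": 0.121, "sd": 0.384, "se": 0.064, "ci_lo": -0.009, "ci_hi": 0.251, "t": 1.888, "p": 0.067},
      {"gland": 2, "mean": 0.420, "sd": 1.016, "se": 0.169, "ci_lo": 0.076, "ci_hi": 0.764, "t": 2.481, "p": 0.018},
      {"gland": 3, "mean": 1.207, "sd": 1.544, "se": 0.257, "ci_lo": 0.685, "ci_hi": 1.730, "t": 4.691, "p": 0.000},
      {"gland": 4, "mean": 2.195, "sd": 2.919, "se": 0.487, "ci_lo": 1.208, "ci_hi": 3.183, "t": 4.512, "p": 0.000},
      {"gland": 5, "mean": 4.563, "sd": 3.536, "se": 0.589, "ci_lo": 3.367, "ci_hi": 5.759, "t": 7.744, "p": 0.000},
      {"gland": 6, "mean": 4.960, "sd": 5.345, "se": 0.891, "ci_lo": 3.152, "ci_hi": 6.769, "t": 5.569, "p": 0.000},
      {"gland": 7, "mean": 2.205, "sd": 2.062, "se": 0.344, "ci_lo": 1.508, "ci_hi": 2.903, "t": 6.417, "p": 0.000},
      {"gland": 8, "mean": 0.634, "sd": 1.165, "se": 0.194, "ci_lo": 0.240, "ci_hi": 1.028, "t": 3.266, "p": 0.002},
      {"gland": 9, "mean": 0.077, "sd": 0.439, "se": 0.073, "ci_lo": -0.072, "ci_hi": 0.225, "t": 1.049, "p": 0.301},
      {"gland": 10, "mean": 0.268, "sd": 0.343, "se": 0.057, "ci_lo": 0.151, "ci_hi": 0.384, "t": 4.677, "p": 0.000}
    ]
  },
  "site_anova": {
    "comment": "Per-site deformation coefficients within each group: mean, SD, 95% CI for the mean, one-way ANOVA F across the 10 sites, p, and the compressed LSD ordering string.",
    "treatment": {
      "F": 29.003,
      "p": 0.000,
      "lsd": "5, 6 > 3, 4 > 1, 2, 8, 9, 10",
      "rows": [
        {"gland": 1, "mean": 1.983, "sd": 0.454, "ci_lo": 1.830, "ci_hi": 2.137},
        {"gland": 2, "mean": 2.179, "sd": 0.963, "ci_lo": 1.853, "ci_hi": 2.505},
        {"gland": 3, "mean": 3.285, "sd": 1.270, "ci_lo": 2.855, "ci_hi": 3.714},
        {"gland": 4, "mean": 4.120, "sd": 2.894, "ci_lo": 3.141, "ci_hi": 5.099},
        {"gland": 5, "mean": 6.608, "sd": 3.424, "ci_lo": 5.449, "ci_hi": 7.767},
        {"gland": 6, "mean": 7.447, "sd": 4.500, "ci_lo": 5.925, "ci_hi": 8.970},
        {"gland": 7, "mean": 4.176, "sd": 2.136, "ci_lo": 3.453, "ci_hi": 4.899},
        {"gland": 8, "mean": 2.684, "sd": 1.248, "ci_lo": 2.261, "ci_hi": 3.106},
        {"gland": 9, "mean": 1.852, "sd": 0.469, "ci_lo": 1.693, "ci_hi": 2.011},
        {"gland": 10, "mean": 1.890, "sd": 0.457, "ci_lo": 1.736, "ci_hi": 2.045}
      ]
    },
    "control": {
      "F": 3.011,
      "p": 0.002,
      "lsd": "6 > 1, 2, 3, 4, 5, 7, 8, 9, 10; 3, 5, 8 > 10",
      "rows": [
        {"gland": 1, "mean": 1.862, "sd": 0.404, "ci_lo": 1.726, "ci_hi": 1.999},
        {"gland": 2, "mean": 1.759, "sd": 0.335, "ci_lo": 1.646, "ci_hi": 1.873},
        {"gland": 3, "mean": 2.077, "sd": 0.426, "ci_lo": 1.933, "ci_hi": 2.222},
        {"gland": 4, "mean": 1.925, "sd": 0.447, "ci_lo": 1.773, "ci_hi": 2.076},
        {"gland": 5, "mean": 2.045, "sd": 0.411, "ci_lo": 1.906, "ci_hi": 2.184},
        {"gland": 6, "mean": 2.487, "sd": 2.328, "ci_lo": 1.699, "ci_hi": 3.274},
        {"gland": 7, "mean": 1.971, "sd": 0.275, "ci_lo": 1.878, "ci_hi": 2.063},
        {"gland": 8, "mean": 2.050, "sd": 0.437, "ci_lo": 1.902, "ci_hi": 2.197},
        {"gland": 9, "mean": 1.775, "sd": 0.359, "ci_lo": 1.653, "ci_hi": 1.897},
        {"gland": 10, "mean": 1.622, "sd": 0.284, "ci_lo": 1.527, "ci_hi": 1.718}
      ]
    }
  }
}
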