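{
  "description": "Per-subject scores of the eight-subject online-feedback study this pipeline was developed for: segment accuracy (%) and confusion-matrix quality QCM (%) per run D1-D6, pairwise class separability per run, and the published derived statistics (signed-rank p-values, per-subject QCM regression coefficients) recomputed by the metrics module.",
  "subjects": ["S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8"],
  "runs": ["D1", "D2", "D3", "D4", "D5", "D6"],
  "accuracy": {
    "S1": [42.5, 46.4, 49.7, 49.6, 58.9, 55.8],
    "S2": [37.5, 45.5, 54.2, 50.1, 47.6, 52.1],
    "S3": [31.8, 32.3, 32.0, 34.8, 32.9, 36.8],
    "S4": [52.0, 59.0, 58.5, 55.1, 54.4, 54.6],
    "S5": [68.6, 70.6, 73.4, 65.8, 61.5, 61.9],
    "S6": [34.1, 34.0, 42.5, 48.3, 33.0, 58.1],
    "S7": [48.4, 52.2, 53.3, 64.9, 51.2, 63.6],
    "S8": [34.7, 30.6, 43.7, 42.6, 36.9, 30.7]
  },
  "accuracy_avg": [44.1, 46.4, 51.6, 51.0, 47.1, 52.5],
  "qcm": {
    "S1": [29.6, 39.0, 41.3, 41.4, 52.8, 36.5],
    "S2": [30.5, 33.6, 45.8, 47.1, 41.1, 44.1],
    "S3": [18.4, 18.7, 32.3, 27.9, 16.5, 19.5],
    "S4": [41.8, 50.0, 50.2, 48.0, 40.6, 31.5],
    "S5": [56.4, 54.1, 67.0, 45.5, 44.9, 41.3],
    "S6": [21.5, 27.4, 35.7, 42.8, 21.5, 50.7],
    "S7": [31.1, 21.4, 37.9, 63.8, 46.4, 42.8],
    "S8": [10.2, 14.3, 27.2, 36.1, 13.4, 11.4]
  },
  "qcm_avg": [29.9, 32.3, 42.2, 44.1, 34.6, 34.7],
  "wilcoxon_p": {
    "accuracy_vs_prev": [0.07, 0.02, 0.57, 0.96, 0.125],
    "accuracy_vs_first": [0.07, 0.003, 0.01, 0.08, 0.055],
    "qcm_vs_prev": [0.15, 0.004, 0.32, 0.98, 0.77],
    "qcm_vs_first": [0.15, 0.004, 0.02, 0.23, 0.19]
  },
  "qcm_regression": {
    "slope": [3.77, 6.19, 4.22, 1.86, -1.99, 7.2, 11.5, 9.08],
    "intercept": [28.4, 23.8, 13.8, 42.9, 60.7, 13.9, 9.5, -0.8]
  },
  "class_pairs": ["1-2", "1-3", "1-4", "2-3", "2-4", "3-4"],
  "separability": {
    "S1": {
      "scores": [
        [2.14, 2.52, 1.84, 2.24, 2.26, 2.77],
        [1.45, 1.20, 1.35, 0.79, 1.21, 1.61],
        [2.15, 1.94, 3.63, 2.38, 2.47, 3.50],
        [2.26, 2.54, 1.90, 1.45, 1.82, 3.29],
        [0.86, 1.06, 1.32, 1.12, 0.96, 1.85],
        [2.23, 1.92, 3.68, 1.51, 1.95, 4.07]
      ],
      "p_vs_prev": [0.50, 0.28, 0.97, 0.08, 0.02],
      "p_vs_first": [0.50, 0.22, 0.84, 0.72, 0.02]
    },
    "S2": {
      "scores": [
        [2.64, 1.54, 1.30, 1.88, 0.76, 1.74],
        [1.20, 0.96, 0.70, 1.14, 0.88, 1.33],
        [2.22, 2.13, 0.95, 1.52, 0.97, 0.92],
        [2.30, 1.61, 1.26, 1.02, 1.31, 2.94],
        [1.20, 1.01, 0.48, 0.38, 0.41, 0.57],
        [2.02, 2.34, 0.96, 0.86, 1.76, 1.62]
      ],
      "p_vs_prev": [0.92, 1.00, 0.22, 0.66, 0.08],
      "p_vs_first": [0.92, 1.00, 1.00, 1.00, 0.89]
    },
    "S3": {
      "scores": [
        [1.43, 1.63, 2.01, 1.51, 1.48, 1.49],
        [0.87, 1.14, 1.29, 0.86, 1.04, 1.20],
        [2.58, 1.57, 2.36, 1.32, 1.31, 1.15],
        [1.45, 1.52, 1.64, 1.49, 1.18, 1.94],
        [2.07, 1.01, 1.46, 1.11, 0.72, 0.90],
        [2.41, 1.35, 1.78, 1.19, 0.97, 1.38]
      ],
      "p_vs_prev": [0.84, 0.02, 1.00, 0.95, 0.08],
      "p_vs_first": [0.84, 0.72, 0.89, 0.95, 0.84]
    },
    "S4": {
      "scores": [
        [3.64, 3.73, 2.56, 2.66, 3.02, 3.66],
        [1.42, 1.92, 1.75, 1.70, 3.67, 1.75],
        [3.57, 3.17, 2.92, 3.45, 3.65, 3.05],
        [3.04, 5.05, 3.71, 3.41, 4.39, 3.14],
        [1.81, 1.97, 1.47, 1.64, 1.03, 1.29],
        [3.04, 4.39, 4.33, 4.52, 5.42, 2.67]
      ],
      "p_vs_prev": [0.08, 1.00, 0.22, 0.08, 0.92],
      "p_vs_first": [0.08, 0.50, 0.34, 0.16, 0.84]
    },
    "S5": {
      "scores": [
        [3.40, 2.89, 3.74, 3.46, 3.69, 4.94],
        [0.95, 1.09, 1.38, 2.02, 1.91, 2.45],
        [3.48, 3.09, 6.45, 3.57, 4.23, 5.04],
        [3.70, 2.85, 2.87, 6.39, 4.74, 6.58],
        [1.04, 0.62, 1.02, 0.86, 0.80, 1.03],
        [3.82, 3.08, 5.00, 6.67, 5.49, 6.77]
      ],
      "p_vs_prev": [0.98, 0.02, 0.34, 0.78, 0.02],
      "p_vs_first": [0.98, 0.16, 0.08, 0.03, 0.03]
    },
    "S6": {
      "scores": [
        [1.31, 2.11, 2.23, 2.67, 3.16, 2.07],
        [0.62, 1.28, 1.04, 1.44, 1.34, 0.87],
        [1.16, 1.97, 1.83, 2.24, 2.58, 1.70],
        [0.96, 2.53, 1.30, 2.78, 1.59, 1.61],
        [0.56, 1.22, 0.72, 1.37, 0.97, 0.99],
        [0.82, 2.30, 1.04, 2.28, 1.27, 1.29]
      ],
      "p_vs_prev": [0.02, 0.98, 0.02, 0.84, 0.84],
      "p_vs_first": [0.02, 0.02, 0.02, 0.02, 0.02]
    },
    "S7": {
      "scores": [
        [2.41, 3.54, 2.22, 2.09, 1.58, 3.71],
        [0.73, 0.94, 0.70, 1.02, 0.74, 2.35],
        [1.83, 3.41, 2.49, 2.20, 1.45, 3.38],
        [1.80, 1.74, 1.90, 2.01, 1.70, 3.51],
        [0.61, 0.86, 0.92, 0.59, 0.45, 0.68],
        [1.29, 1.59, 2.03, 2.02, 1.48, 3.04]
      ],
      "p_vs_prev": [0.03, 0.78, 0.78, 1.00, 0.02],
      "p_vs_first": [0.03, 0.11, 0.16, 0.89, 0.02]
    },
    "S8": {
      "scores": [
        [1.67, 1.11, 1.55, 1.06, 1.11, 0.93],
        [1.27, 0.91, 1.20, 0.65, 0.85, 0.74],
        [1.45, 0.79, 1.32, 0.90, 0.98, 0.80],
        [1.80, 1.35, 1.63, 1.08, 1.38, 1.42],
        [1.60, 0.90, 1.39, 1.16, 1.24, 1.19],
        [1.50, 0.91, 1.33, 0.87, 1.16, 1.18]
      ],
      "p_vs_prev": [1.00, 0.02, 1.00, 0.02, 0.95],
      "p_vs_first": [1.00, 1.00, 1.00, 1.00, 1.00]
    }
  }
}
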