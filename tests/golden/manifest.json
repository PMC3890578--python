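{
  "config": {
    "annotation_path": null,
    "borderline_dst": 0.9,
    "catalog_path": null,
    "cis_window": 1000000,
    "contamination_check": true,
    "count_sum_min": 10,
    "counts_path": null,
    "covariate_conditions": [
      "none",
      "known",
      "known+surrogates"
    ],
    "covariates_path": null,
    "dr_clean": 0.2,
    "dr_highconf": 0.1,
    "genotypes_path": null,
    "lambda0": 0.5,
    "log2_sum_min": 100.0,
    "n_gw_pairs": 600,
    "n_pcs": 6,
    "n_surrogates": 6,
    "normalization": "log2_depth",
    "pca_outliers": true,
    "per_gene_outliers": true,
    "rna_calls_path": null,
    "sd_threshold": 3.0,
    "seed": 20
  },
  "samples": {
    "dropped": [
      {
        "reason": "contaminated",
        "sample": "S004"
      },
      {
        "reason": "pca_outlier",
        "sample": "S016"
      }
    ],
    "initial": 24,
    "retained": 22
  },
  "stages": [
    {
      "method": "log2_depth",
      "name": "normalize"
    },
    {
      "dropped": [
        "S016"
      ],
      "n_pcs": 6,
      "name": "pca_outliers",
      "sd_threshold": 3.0,
      "variance_explained": 0.678367
    },
    {
      "borderline_dst": 0.9,
      "dr_clean": 0.2,
      "dropped": [
        "S004"
      ],
      "name": "concordance"
    },
    {
      "frac_genes_with_outlier": 0.01875,
      "n_masked_entries": 3,
      "name": "per_gene_outliers",
      "sd_threshold": 3.0
    },
    {
      "count_sum_min": 10,
      "log2_sum_min": 100.0,
      "n_analysis_genes": 160,
      "n_decomposition_genes": 160,
      "name": "filter_genes"
    },
    {
      "n_components": 6,
      "name": "surrogates"
    },
    {
      "cis_window": 1000000,
      "conditions": [
        {
          "condition": "none",
          "lambda_gw": 1.0536051891946627,
          "n_tested": 40,
          "n_untested": 0,
          "pct_p05": 0.15,
          "pct_q05": 0.025,
          "pi1": 0.25
        },
        {
          "condition": "known",
          "lambda_gw": 0.9994914025673661,
          "n_tested": 40,
          "n_untested": 0,
          "pct_p05": 0.25,
          "pct_q05": 0.05,
          "pi1": 0.25
        },
        {
          "condition": "known+surrogates",
          "lambda_gw": 1.0714110485664354,
          "n_tested": 40,
          "n_untested": 0,
          "pct_p05": 0.175,
          "pct_q05": 0.075,
          "pi1": 0.30000000000000004
        }
      ],
      "lambda0": 0.5,
      "n_genome_wide_pairs": 600,
      "name": "replication"
    }
  ]
}
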