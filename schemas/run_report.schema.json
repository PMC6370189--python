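{
  "$defs": {
    "ClusterRecord": {
      "properties": {
        "linkage": {
          "title": "Linkage",
          "type": "string"
        },
        "distance": {
          "title": "Distance",
          "type": "string"
        },
        "leaf_order": {
          "items": {
            "type": "string"
          },
          "title": "Leaf Order",
          "type": "array"
        },
        "two_cut": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Two Cut",
          "type": "object"
        },
        "tgfb_purity": {
          "title": "Tgfb Purity",
          "type": "number"
        }
      },
      "required": [
        "linkage",
        "distance",
        "leaf_order",
        "two_cut",
        "tgfb_purity"
      ],
      "title": "ClusterRecord",
      "type": "object"
    },
    "GseaRow": {
      "properties": {
        "gene_set": {
          "title": "Gene Set",
          "type": "string"
        },
        "size": {
          "title": "Size",
          "type": "integer"
        },
        "es": {
          "title": "Es",
          "type": "number"
        },
        "nes": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Nes"
        },
        "pvalue": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Pvalue"
        },
        "fdr_q": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Fdr Q"
        },
        "significant": {
          "title": "Significant",
          "type": "boolean"
        }
      },
      "required": [
        "gene_set",
        "size",
        "es",
        "nes",
        "pvalue",
        "fdr_q",
        "significant"
      ],
      "title": "GseaRow",
      "type": "object"
    },
    "OverlapRecord": {
      "properties": {
        "comparison": {
          "title": "Comparison",
          "type": "string"
        },
        "o_obs": {
          "title": "O Obs",
          "type": "integer"
        },
        "k": {
          "title": "K",
          "type": "integer"
        },
        "m": {
          "title": "M",
          "type": "integer"
        },
        "universe_size": {
          "title": "Universe Size",
          "type": "integer"
        },
        "percentage": {
          "title": "Percentage",
          "type": "number"
        },
        "bootstraps": {
          "title": "Bootstraps",
          "type": "integer"
        },
        "pvalue": {
          "title": "Pvalue",
          "type": "number"
        },
        "concordant_pct": {
          "title": "Concordant Pct",
          "type": "number"
        },
        "discordant_pct": {
          "title": "Discordant Pct",
          "type": "number"
        },
        "not_de_pct": {
          "title": "Not De Pct",
          "type": "number"
        },
        "not_measured_pct": {
          "title": "Not Measured Pct",
          "type": "number"
        }
      },
      "required": [
        "comparison",
        "o_obs",
        "k",
        "m",
        "universe_size",
        "percentage",
        "bootstraps",
        "pvalue",
        "concordant_pct",
        "discordant_pct",
        "not_de_pct",
        "not_measured_pct"
      ],
      "title": "OverlapRecord",
      "type": "object"
    },
    "PcaRecord": {
      "properties": {
        "variance_fraction": {
          "items": {
            "type": "number"
          },
          "title": "Variance Fraction",
          "type": "array"
        },
        "top3_variance_pct": {
          "title": "Top3 Variance Pct",
          "type": "number"
        }
      },
      "required": [
        "variance_fraction",
        "top3_variance_pct"
      ],
      "title": "PcaRecord",
      "type": "object"
    },
    "TierRow": {
      "properties": {
        "comparison": {
          "title": "Comparison",
          "type": "string"
        },
        "min_abs_log2fc": {
          "title": "Min Abs Log2Fc",
          "type": "number"
        },
        "total": {
          "title": "Total",
          "type": "integer"
        },
        "up": {
          "title": "Up",
          "type": "integer"
        },
        "down": {
          "title": "Down",
          "type": "integer"
        }
      },
      "required": [
        "comparison",
        "min_abs_log2fc",
        "total",
        "up",
        "down"
      ],
      "title": "TierRow",
      "type": "object"
    }
  },
  "description": "Machine-readable record of one complete pipeline run.",
  "properties": {
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "fpkm_cutoff": {
      "title": "Fpkm Cutoff",
      "type": "number"
    },
    "alpha": {
      "title": "Alpha",
      "type": "number"
    },
    "bootstraps": {
      "title": "Bootstraps",
      "type": "integer"
    },
    "n_perm": {
      "title": "N Perm",
      "type": "integer"
    },
    "perm_mode": {
      "title": "Perm Mode",
      "type": "string"
    },
    "universe": {
      "title": "Universe",
      "type": "string"
    },
    "n_genes_input": {
      "title": "N Genes Input",
      "type": "integer"
    },
    "n_genes_expressed": {
      "title": "N Genes Expressed",
      "type": "integer"
    },
    "common_de_up": {
      "items": {
        "type": "string"
      },
      "title": "Common De Up",
      "type": "array"
    },
    "common_de_down": {
      "items": {
        "type": "string"
      },
      "title": "Common De Down",
      "type": "array"
    },
    "pca": {
      "$ref": "#/$defs/PcaRecord"
    },
    "clustering": {
      "$ref": "#/$defs/ClusterRecord"
    },
    "tier_table": {
      "items": {
        "$ref": "#/$defs/TierRow"
      },
      "title": "Tier Table",
      "type": "array"
    },
    "overlaps": {
      "items": {
        "$ref": "#/$defs/OverlapRecord"
      },
      "title": "Overlaps",
      "type": "array"
    },
    "gsea_table": {
      "items": {
        "$ref": "#/$defs/GseaRow"
      },
      "title": "Gsea Table",
      "type": "array"
    },
    "gsea_excluded": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Gsea Excluded",
      "type": "object"
    }
  },
  "required": [
    "seed",
    "fpkm_cutoff",
    "alpha",
    "bootstraps",
    "n_perm",
    "perm_mode",
    "universe",
    "n_genes_input",
    "n_genes_expressed",
    "common_de_up",
    "common_de_down",
    "pca",
    "clustering",
    "tier_table",
    "overlaps",
    "gsea_table",
    "gsea_excluded"
  ],
  "title": "RunReport",
  "type": "object"
}
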