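{
  "description": "Rotated factor loadings for the four adult dietary patterns identified in the 2002 Jiangsu nutrition survey FFQ (25 merged food items). Only items with |loading| >= 0.20 are retained; cheese falls below the threshold on every pattern and therefore carries no loadings.",
  "patterns": ["traditional", "macho", "sweet_tooth", "healthy"],
  "inclusion_threshold": 0.20,
  "loadings": {
    "traditional": {
      "rice": 0.81,
      "fresh_vegetables": 0.57,
      "pork": 0.37,
      "fish": 0.21,
      "root_vegetable": -0.32,
      "wheat_flour": -0.78
    },
    "macho": {
      "poultry": 0.56,
      "beer": 0.53,
      "beef_lamb": 0.46,
      "deep_fried_products": 0.45,
      "pork": 0.44,
      "liver": 0.43,
      "alcohol": 0.43,
      "eggs": 0.38,
      "fish": 0.26,
      "nuts": 0.23,
      "fruits": 0.22,
      "tofu": 0.22
    },
    "sweet_tooth": {
      "cake": 0.60,
      "juice": 0.58,
      "beverage": 0.48,
      "milk": 0.48,
      "yoghurt": 0.44,
      "beef_lamb": 0.30,
      "nuts": 0.26,
      "poultry": 0.25,
      "fruits": 0.23,
      "pickled_vegetables": -0.20,
      "alcohol": -0.27
    },
    "healthy": {
      "whole_grains": 0.54,
      "fruits": 0.49,
      "pickled_vegetables": 0.46,
      "tofu": 0.44,
      "fresh_vegetables": 0.37,
      "root_vegetable": 0.34,
      "milk": 0.31,
      "eggs": 0.30,
      "fish": 0.24,
      "wheat_flour": 0.23,
      "milk_powder": 0.22,
      "beer": -0.21
    }
  }
}
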