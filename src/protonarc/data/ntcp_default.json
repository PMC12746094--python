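{
  "_comment": "Illustrative logistic NTCP models in the style of the Dutch national protocol for model-based patient selection in head and neck proton therapy (xerostomia and dysphagia, grades 2 and 3). Coefficients are schematic defaults for synthetic phantoms, not the published clinical models; supply a protocol coefficient file for clinical-style runs.",
  "models": [
    {
      "name": "xerostomia_G2",
      "grade": 2,
      "intercept": -1.6,
      "terms": [
        {"predictor": "parotids_mean", "transform": "sqrt", "coefficient": 0.25}
      ]
    },
    {
      "name": "xerostomia_G3",
      "grade": 3,
      "intercept": -3.2,
      "terms": [
        {"predictor": "parotids_mean", "transform": "sqrt", "coefficient": 0.25}
      ]
    },
    {
      "name": "dysphagia_G2",
      "grade": 2,
      "intercept": -3.0,
      "terms": [
        {"predictor": "constrictor_mean", "transform": "identity", "coefficient": 0.055}
      ]
    },
    {
      "name": "dysphagia_G3",
      "grade": 3,
      "intercept": -4.5,
      "terms": [
        {"predictor": "constrictor_mean", "transform": "identity", "coefficient": 0.045}
      ]
    }
  ]
}
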