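# drkex default configuration.  Every key shown here is recognized; unknown
# keys are rejected.  Values mirror the library defaults, so an empty file is
# equivalent to this one.

weights:
  alpha: 0.45            # accuracy: entity component
  beta_triplet: 0.45     # accuracy: triplet component
  gamma: 0.10            # accuracy: rare-item component
  delta: 0.70            # format: tag integrity
  epsilon_length: 0.30   # format: reasoning length
  w_acc: 0.50            # global accuracy-reward weight
  w_fmt: 0.50            # global format-reward weight
  partial_credit: 0.50   # credit for same-type boundary overlap
  length_bounds: [200, 8000]   # admissible think-content length, characters
  case_insensitive: false
  rarity_threshold: 0.05

rarity:
  threshold: 0.05
  # Reference composition used to judge rarity; defaults to the DrugReC
  # reference table shipped with the package.  Override with your own counts:
  # entity_counts: {disease: 1782, ...}
  # relation_counts: {treat: 839, ...}

compatibility:
  # canonical relation -> admissible [head_type, tail_type] pairs.
  # This default table is a reconstruction and is intended to be edited.
  treat: [[drug, disease], [treatment, disease]]
  is_target_of: [[target, drug]]
  is_side_effect_of: [[side_effect, drug]]
  is_biomarker_of: [[biomarker, disease]]
  is_examination_for: [[test, disease]]
  complication_of: [[complication, disease]]
  is_located_in: [[disease, anatomy], [complication, anatomy], [biomarker, anatomy], [symptom, anatomy]]
  is_symptom_of: [[symptom, disease]]
  increases_expression_of: [[drug, gene], [gene, gene]]

generator:
  # Document-scale defaults are order-of-magnitude choices for template
  # abstracts; real abstracts vary far more in length and mention density.
  n_docs: 100
  entities_per_doc: [10, 16]
  triplets_per_doc: [2, 4]
  sentences_per_doc: [1, 2]
  cross_sentence_fraction: 0.10
  # entity_mixture / relation_mixture default to the DrugReC reference shares.
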