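# Default semiquantitative evidence matrix (ClinGen SOP constants with the
# ARVC panel's model-phenotype gate layered on in code). All points are read
# as exact decimals; edit and pass via --matrix to override.
schema_version: "1.0"
total_max: 18
genetic:
  cap: 12
  variant_cap: 12
  variant_categories:
    proband_null:            {default: 1.5, range: [0, 3],   cap: 10}
    proband_other:           {default: 0.1, range: [0, 1.5], cap: 7}
    proband_other_de_novo:   {default: 0.5, range: [0, 3],   cap: 12}
    ar_in_trans:             {default: 2,   range: [0, 3],   cap: 12}
    ar_phase_unknown:        {default: 1,   range: [0, 3],   cap: 12}
  segregation:
    cap: 3
    bins:
      candidate_gene:
        - {min_lod: 2, points: 1}
        - {min_lod: 3, points: 2}
        - {min_lod: 5, points: 3}
      exome_genome:
        - {min_lod: 2, points: 0.5}
        - {min_lod: 3, points: 1}
        - {min_lod: 5, points: 1.5}
  case_control:
    per_study_range: [0, 6]
    cap: 12
experimental:
  cap: 6
  groups:
    function:
      cap: 2
      categories: [biochemical_function, protein_interaction, expression]
    functional_alteration:
      cap: 2
      categories: [functional_alteration_patient_cells, functional_alteration_nonpatient_cells]
    models_rescue:
      cap: 4
      categories: [model_organism, cell_culture_model, rescue_human,
                   rescue_model_organism, rescue_cell_culture, rescue_patient_cells]
  categories:
    biochemical_function:                  {default: 0.5, range: [0, 2]}
    protein_interaction:                   {default: 0.5, range: [0, 2]}
    expression:                            {default: 0.5, range: [0, 2]}
    functional_alteration_patient_cells:   {default: 1,   range: [0, 2]}
    functional_alteration_nonpatient_cells: {default: 0.5, range: [0, 1]}
    model_organism:                        {default: 2,   range: [0, 4]}
    cell_culture_model:                    {default: 1,   range: [0, 2]}
    rescue_human:                          {default: 2,   range: [0, 4]}
    rescue_model_organism:                 {default: 2,   range: [0, 4]}
    rescue_cell_culture:                   {default: 1,   range: [0, 2]}
    rescue_patient_cells:                  {default: 1,   range: [0, 2]}
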