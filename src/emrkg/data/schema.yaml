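# Conceptual layer of the clinical knowledge graph.
#
# entity_types: the eleven node labels.
# relations: directed relation inventory with domain (subject type) and
#   range (object type).  The rels_* family links a patient record to the
#   typed entities extracted from it (the multi-hop retrieval pattern
#   patient -rels_disease-> disease -accompany_with-> complication relies on
#   this orientation); the remaining relations are website/terminology facts
#   between clinical entities.  Edit here to correct an inferred pair.
entity_types:
  - patient
  - examination
  - symptom
  - diseases
  - past_history
  - operation_recording
  - treatment_options
  - physical_examination
  - food
  - drug
  - department

relations:
  has_symptom:        {domain: diseases, range: symptom}
  accompany_with:     {domain: diseases, range: diseases}
  recommand_drug:     {domain: diseases, range: drug}
  recommand_eat:      {domain: diseases, range: food}
  no_eat:             {domain: diseases, range: food}
  do_eat:             {domain: diseases, range: food}
  need_check:         {domain: diseases, range: examination}
  drugs_of:           {domain: drug, range: diseases}
  rels_diseases:      {domain: diseases, range: diseases}
  common_drug:        {domain: diseases, range: drug}
  belongs_to:         {domain: diseases, range: department}
  rels_body:          {domain: patient, range: physical_examination}
  rels_operation:     {domain: patient, range: operation_recording}
  rels_disease:       {domain: patient, range: diseases}
  rels_symptom:       {domain: patient, range: symptom}
  rels_check:         {domain: patient, range: examination}
  rels_treatment:     {domain: patient, range: treatment_options}
  rels_condition:     {domain: patient, range: past_history}
  # hub edge used when proxy category nodes are materialised; a hub carries
  # the type of its members, so both endpoints share one (arbitrary) type
  category_member:    {domain: "*", range: "*", allow_self_loop: true}

attributes:
  patient: [nation, age, sex]
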