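# Language ontology: a small synonym table mapping everyday wording in
# flow-chart action names onto hospital-vocabulary classes.  Stands in for
# the large general-purpose lexical resources a production deployment would
# consult.
ontology language

# action verbs
synonym add = AddMedication
synonym give = AddMedication
synonym increase = AddMedication
synonym reduce = ReduceMedication
synonym decrease = ReduceMedication
synonym lower = ReduceMedication
synonym stop = StopMedication
synonym discontinue = StopMedication
synonym maintain = MaintainMedication
synonym keep = MaintainMedication
synonym continue = MaintainMedication
synonym enter = EnterData
synonym input = EnterData
synonym register = EnterData
synonym record = EnterData
synonym notify = Notification
synonym reminder = Notification
synonym remind = Notification
synonym call = Notification
synonym contact = Notification
synonym calculate = CalculateParameter
synonym compute = CalculateParameter

# observations
synonym "sedation score" = RASS
synonym "body mass index" = BMI
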