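# Hospital vocabulary: medication taxonomy, action classes and patient
# attributes used when interpreting free-text action names on flow-chart
# symbols.  A documented re-creation of the ICU vocabulary: the morphine and
# Dormicum (midazolam) entries carry the preparations the translation
# examples require; the short-acting agents (propofol, remifentanil) are
# plausible ICU additions used by the short-sedation fixture charts.
ontology hospital

class Medication
class Morphine < Medication
class "Morphine IV [20mg/1ml]" < Morphine
class "Morphine IV [10mg/1ml]" < Morphine
class Dormicum < Medication
class "Dormicum IV [5mg/1ml]" < Dormicum
class Propofol < Medication
class "Propofol IV [20mg/1ml]" < Propofol
class Remifentanil < Medication
class "Remifentanil IV [2mg/1ml]" < Remifentanil

class Action
class AddMedication < Action
class ReduceMedication < Action
class StopMedication < Action
class MaintainMedication < Action
class EnterData < Action
class Notification < Action
class CalculateParameter < Action

class Observation
class RASS < Observation
class BMI < Observation

class Patient

property hasWeight : datatype Patient -> number
property hasHeight : datatype Patient -> number
property hasBMI : datatype Patient -> number

# derived-parameter rule: body-mass index from weight and height
rule derive-bmi: Patient(?x), hasWeight(?x, ?y), hasHeight(?x, ?z), swrlb:multiply(?k, ?z, ?z), swrlb:divide(?bmi, ?y, ?k) -> hasBMI(?x, ?bmi)
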