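# Diagram ontology: flow-chart symbol types, the intermediate-language
# constructs they translate to, and the mapping rules between them.
# This is a documented re-creation: it covers every symbol and construct the
# translator handles, with connection-cardinality constraints per construct.
ontology diagram

class Symbol
class UMLSymbol < Symbol
class InitialNode < UMLSymbol
class ActivityAction < UMLSymbol
class DecisionNode < UMLSymbol
class MergeNode < UMLSymbol
class JoinNode < UMLSymbol
class FinalNode < UMLSymbol

class IntermediateSymbol
class Start < IntermediateSymbol
class End < IntermediateSymbol
class Split < IntermediateSymbol
class Join < IntermediateSymbol
class TimeHandler < IntermediateSymbol
class SubProcess < IntermediateSymbol
class WorkItem < IntermediateSymbol
class Action < IntermediateSymbol
class Connection < IntermediateSymbol

property hasStereoType : datatype UMLSymbol -> string

# connection cardinality: <class> in <min> <max> out <min> <max>  ('-' = unbounded)
connections Start in 0 0 out 1 -
connections End in 1 - out 0 0
connections Split in 1 - out 2 -
connections Join in 2 - out 1 -
connections TimeHandler in 1 - out 1 -
connections SubProcess in 1 - out 1 -
connections WorkItem in 1 - out 1 -

# symbol-type to intermediate-construct mapping
rule map-start: InitialNode(?x) -> Start(?x)
rule map-end: FinalNode(?x) -> End(?x)
rule map-split: DecisionNode(?x) -> Split(?x)
rule map-merge: MergeNode(?x) -> Join(?x)
rule map-join: JoinNode(?x) -> Join(?x)

# stereotype rules for ActivityAction symbols
rule stereo-wait: ActivityAction(?x), hasStereoType(?x, ?y), stringEqualIgnoreCase(?y, "wait") -> TimeHandler(?x)
rule stereo-subprocess: ActivityAction(?x), hasStereoType(?x, ?y), stringEqualIgnoreCase(?y, "subprocess") -> SubProcess(?x)
rule plain-workitem: ActivityAction(?x), (hasStereoType = 0)(?x) -> WorkItem(?x)
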