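variant	canonical
guanidino acetic acid	guanidinoacetic acid
guanidinoacetate	guanidinoacetic acid
t4hp	trans-4-hydroxy-l-proline
trans-4-hydroxyproline	trans-4-hydroxy-l-proline
4-hydroxyproline	trans-4-hydroxy-l-proline
glutamate	glutamic acid
malate	malic acid
glucuronate	glucuronic acid
glycerate	glyceric acid
gpc	glycerophosphocholine
glycerophosphorylcholine	glycerophosphocholine
g6p	glucose-6-phosphate
d-glucose	glucose
l-lactate	lactate
lactic acid	lactate
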