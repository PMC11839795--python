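segment_name,risk_score
R. globus pallidus,1.0
L. globus pallidus,1.0
R. caudate nucleus,1.0
L. caudate nucleus,1.0
R. putamen,1.0
L. putamen,1.0
R. thalamus,1.0
L. thalamus,1.0
R. nucleus accumbens,1.0
L. nucleus accumbens,1.0
R. superior colliculus,1.0
L. superior colliculus,1.0
R. inferior colliculus,1.0
L. inferior colliculus,1.0
R. mammillary body,1.0
L. mammillary body,1.0
pineal gland,0.5
R. lateral ventricle,0.1
L. lateral ventricle,0.1
third ventricle,0.1
fourth ventricle,0.1
cerebral aqueduct,0.1
brainstem,1.0
tracts,1.0
insula- anterior,1.0
insula- posterior,1.0
hippocampus,1.0
amygdala,0.5
parahippocampal gyrus,1.0
fusiform gyrus- anterior,0.3
fusiform gyrus- posterior,0.7
temporal pole,0.3
transverse temporal gyrus,1.0
superior temporal gyrus- anterior,0.3
superior temporal gyrus- middle,0.6
superior temporal gyrus- posterior,0.7
middle temporal gyrus- anterior,0.5
middle temporal gyrus- middle,0.5
inferior temporal gyrus- anterior,0.5
lingual gyrus- anterior,0.5
lingual gyrus- posterior,0.5
cuneus- anterior,0.7
cuneus- posterior,0.7
precuneus- superior,0.5
precuneus- inferior,0.5
paracentral lobule,1.0
cingulate gyrus- anterior,0.3
cingulate gyrus- middle,0.3
cingulate gyrus- posterior,0.3
subcallosal gyrus,0.3
gyrus rectus,0.3
superior frontal gyrus- anterior,0.3
superior frontal gyrus- posterior,1.0
middle frontal gyrus- anterior,0.3
middle frontal gyrus- posterior,1.0
precentral gyrus- superior,1.0
precentral gyrus- inferior,1.0
postcentral gyrus- superior,1.0
postcentral gyrus- inferior,1.0
supramarginal gyrus- anterior,1.0
angular gyrus- anterior,1.0
superior parietal gyrus- anterior,1.0
superior parietal gyrus- posterior,1.0
superior occipital gyrus- superior,0.3
superior occipital gyrus- inferior,0.3
middle occipital gyrus- posterior,1.0
inferior occipital gyrus- anterior,1.0
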