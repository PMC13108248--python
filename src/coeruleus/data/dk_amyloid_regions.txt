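Caudal Middle Frontal
Lateral Orbitofrontal
Medial Orbitofrontal
Pars Opercularis
Pars Orbitalis
Pars Triangularis
Rostral Middle Frontal
Superior Frontal
Frontal Pole
Inferior Parietal
Precuneus
Superior Parietal
Supramarginal
Caudal Anterior Cingulate
Posterior Cingulate
Isthmus Cingulate
Rostral Anterior Cingulate
Middle Temporal
Superior Temporal
Inferior Temporal
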