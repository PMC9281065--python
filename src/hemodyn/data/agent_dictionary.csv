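raw_name,canonical
dobutamine,dobutamine
dobutrex,dobutamine
dopamine,dopamine
intropin,dopamine
epinephrine,epinephrine
adrenaline,epinephrine
levophed,norepinephrine
norepinephrine,norepinephrine
noradrenaline,norepinephrine
neosynephrine,phenylephrine
neo-synephrine,phenylephrine
phenylephrine,phenylephrine
vasopressin,vasopressin
pitressin,vasopressin
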