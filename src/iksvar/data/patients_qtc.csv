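variant,subject,sex,qtc_ms,note
G119R,IP4764,UNKNOWN,517,under QT-prolonging drugs
delF166,IP2791,FEMALE,495,
delG186_L187,IP2795,FEMALE,534,
V254L,IP2780,FEMALE,485,
V254L,father_of_IP2780,MALE,470,
L273V,IP5362,FEMALE,490,documented range 480-500
K421E,IP4622,UNKNOWN,,prolonged only during seizures; no value documented
G430fs*28,IP4317,UNKNOWN,502,occurred once and temporarily
R539L,IP4602,UNKNOWN,456,borderline
R591C,IP1393,UNKNOWN,470,
R591C,mother_of_IP1393,FEMALE,461,
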