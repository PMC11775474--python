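# Illustrative heart-failure preferred-term list (narrow-scope style).
# One PT per line, optional tab + MedDRA numeric code.
# This list is a small synthetic stand-in for a licensed SMQ PT list and is
# NOT the official "Cardiac failure (SMQ)" content; MedDRA is licensed and
# users should supply their own PT list file for real analyses. Codes are
# given only for the four terms whose codes are public in the literature.
Cardiac failure	10007554
Cardiac failure acute	10007556
Acute left ventricular failure	10063081
Acute right ventricular failure	10063082
Cardiac failure congestive
Cardiac failure chronic
Left ventricular failure
Right ventricular failure
Ventricular failure
Cardiogenic shock
Cardiopulmonary failure
Acute pulmonary oedema
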