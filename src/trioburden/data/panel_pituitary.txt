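# Pituitary-development gene panel (INCOMPLETE).
# This shipped list contains only the panel genes individually documented in
# this package's reference material; the full 42-gene screening panel used in
# cohort studies must be supplied by the user at run time.
# One symbol per line; '#' starts a comment. TPIT is aliased to TBX19 on load.
HESX1
SOX2
SOX3
TBX2
TBX3
LHX2
LHX3
LHX4
SIX1
SIX3
SIX5
SIX6
PITX1
PITX2
PROP1
POU1F1
TBX19
ARID1B
CDON
CHD7
GLI1
GLI4
PAX6
WNT5A
PROKR2
WDR11
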