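no	negated	forward	4	but|however|;
not	negated	forward	4	but|however|;
without	negated	forward	5	but|however|;
denies	negated	forward	6	but|however|;
denied	negated	forward	6	but|however|;
no evidence of	negated	forward	6	but|however|;
negative for	negated	forward	6	but|however|;
free of	negated	forward	5	but|however|;
ruled out	negated	backward	6	but|however|;
possible	uncertain	forward	5	but|;
probable	uncertain	forward	5	but|;
suspected	uncertain	forward	5	but|;
suspicion of	uncertain	forward	6	but|;
may have	uncertain	forward	6	but|;
question of	uncertain	forward	6	but|;
cannot rule out	uncertain	forward	6	but|;
if	conditional	forward	6	then|;
in case of	conditional	forward	6	;
return if	conditional	forward	6	;
should	conditional	forward	6	;
patients with	generic	forward	6	;
risk of	generic	forward	6	;
screening for	generic	forward	6	;
history of	historical	forward	6	;
past medical history of	historical	forward	8	;
h/o	historical	forward	6	;
prior	historical	forward	4	;
previous	historical	forward	4	;
status post	historical	forward	6	;
family history of	not_about_patient	forward	8	;
mother	not_about_patient	forward	6	;
father	not_about_patient	forward	6	;
brother	not_about_patient	forward	6	;
sister	not_about_patient	forward	6	;
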