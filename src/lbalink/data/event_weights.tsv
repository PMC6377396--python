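event_type	weight
Acute Illness (Self)	35
Acute Illness (Household/Family Member)	73
Attempted Suicide (Household/Family Member)	18
Attempted Suicide (Self)	32
Chronic Illness (Household/Family Member)	166
Chronic Illness (Self)	47
Criminal Act (by Self)	10
Criminal Act (against Self)	10
Criminal Act by (Household/Family Member)	19
Criminal Act (against Household/Family Member)	26
Criminal Act (outside home)	21
Death (Household/Family Member)	66
Death (Friend)	17
Disability (Household/Family Member)	11
Disability (Self)	54
Divorce/Separation (Parent/Guardian)	43
Employment Term	15
Gambling (Self)	3
Gambling (Household/Family Member)	25
Imprison/Institut (Self)	2
Imprison/Institut (Household/Family Member)	16
Mental Illness (Self)	200
Mental Illness (Household/Family Member)	250
Serious Accident (Self)	4
Serious Accident (Household/Family Member)	13
Serious Accident (Outside Home)	3
Substance Abuse (Self)	24
Substance Abuse (Household/Family Member)	119
Violent/Threatening (against Self)	80
Violent/Threatening (against Household/Family Member)	69
Violent/Threatening (by Household/Family Member)	109
Violence (outside home)	3
Verbal/Emotional (outside home)	225
Verbal/Emotional against (Self)	77
Verbal/Emotional against (Household/Family Member)	31
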