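herb_id	display_name	nature	flavors	meridians	actions
a_dahurica	A. dahurica	warm	pungent	lung, stomach, large_intestine	expel_wind, release_exterior, alleviate_pain, relieve_stuffy_nose, dry_dampness, stop_leucorrhoea
a_pubescens	A. pubescens	slightly_warm	pungent, bitter	liver, kidney, lung	dispel_wind_damp, alleviate_pain, release_exterior
a_sinensis	A. sinensis	warm	sweet, pungent	heart, liver	tonify_blood, activate_blood, alleviate_pain, regulate_menstruation, moisten_intestines
a_membranaceus	A. membranaceus	warm	sweet	lung, spleen	tonify_qi, raise_yang, secure_superficial, relieve_edema, dispel_toxin, nourish_blood
a_macrocephala	A. macrocephala	warm	sweet, bitter	spleen, stomach	tonify_spleen_qi, dry_dampness, induce_diuresis, arrest_sweating, prevent_abortion
c_pilosula	C. pilosula	neutral	sweet	lung, spleen	invigorate_qi, nourish_blood, promote_body_fluid
c_chinensis	C. chinensis	cold	bitter	heart, stomach, large_intestine, liver	clear_heat, dry_dampness, purge_fire, relieve_toxicity
c_aromatica	C. aromatica	cold	pungent, bitter	liver, gallbladder, heart	activate_blood, alleviate_pain, move_qi, relieve_depression, clear_heat, cool_blood, remove_jaundice
f_suspensa	F. suspensa	cold	bitter, pungent	lung, heart, small_intestine	clear_heat, remove_toxicity, disperse_wind_heat, clear_heart_heat
l_edodes	L. edodes	neutral	sweet	liver, stomach	tonify_deficiency, strengthen_spleen, stimulate_appetite, expel_wind, resolve_phlegm, regulate_qi, remove_toxicity
p_lactiflora	P. lactiflora	slightly_cold	bitter, sour, sweet	spleen, liver	tonify_blood, astringe_yin, emolliate_liver, alleviate_pain, suppress_liver_yang
p_amurense	P. amurense	cold	bitter	liver, gallbladder, large_intestine, kidney, bladder	clear_heat, dry_dampness, purge_fire, remove_toxicity, subdue_deficiency_heat
p_cocos	P. cocos	neutral	sweet, bland	heart, spleen, kidney	induce_diuresis, drain_dampness, invigorate_spleen, induce_tranquilization
r_glutinosa	R. glutinosa	cold	sweet, bitter	heart, liver, stomach, kidney	clear_heat, cool_blood, stop_bleeding, nourish_yin
s_baicalensis	S. baicalensis	cold	bitter	lung, stomach, gallbladder, large_intestine, bladder	clear_heat, dry_dampness, purge_fire, relieve_toxicity, cool_blood, stop_bleeding
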