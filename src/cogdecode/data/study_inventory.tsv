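study	n_contrasts	n_subjects
high_level_math_localizer	31	30
archi	30	78
brainomics	19	94
camcan	5	605
music_structure_sentence_structure	19	35
sentence_music_complexity	25	20
balloon_analog_risk	12	16
baseline_classification_learning	7	17
rhyme_judgment	3	13
mixed_gambles	4	16
mirror_reversed_text	9	14
stop_signal	6	20
conditional_stop_signal	12	13
bart_emotion_stop_discounting	23	24
weather_classification_tone	14	14
classification_stop_signal_a	11	8
classification_stop_signal_b	11	8
cross_language_priming	17	13
classification_learning	3	13
simon_task	8	7
visual_object_recognition	13	6
word_object_processing	6	49
emotion_regulation	26	34
false_belief	7	36
incidental_encoding	26	18
verb_generation_motor	11	10
auditory_visual_oddball	8	17
house_face_continuous	30	11
house_face	23	13
hcp	23	786
face_recognition	5	16
arithmetic_saccades	26	19
la5c	24	189
foreign_language_localizer_saccade	34	65
auditory_visual_compression	14	16
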