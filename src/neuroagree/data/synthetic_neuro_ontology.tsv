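concept_id	preferred_label	code	synonyms
ataxia	ataxia	C0004134	ataxic|incoordination
weakness	weakness	C9000001	weak
fatigue	fatigue	C9000002	tiredness
headache	headache	C9000003	cephalgia
dizziness	dizziness	C9000004	lightheadedness
vertigo	vertigo	C9000005
tremor	tremor	C9000006	shaking
aphasia	aphasia	C9000007
dysarthria	dysarthria	C9000008	slurred speech
diplopia	diplopia	C9000009	double vision
seizure	seizure	C9000010	convulsion
numbness	numbness	C9000011
imbalance	imbalance	C9000012	unsteadiness
drowsiness	drowsiness	C9000013	somnolence
nystagmus	nystagmus	C9000014
dysphagia	dysphagia	C9000015
tinnitus	tinnitus	C9000016	ringing in the ears
spasticity	spasticity	C9000017
clonus	clonus	C9000018
bradykinesia	bradykinesia	C9000019
paresthesia	paresthesia	C9000020	tingling
anosmia	anosmia	C9000021
ptosis	ptosis	C9000022
myoclonus	myoclonus	C9000023
dysmetria	dysmetria	C9000024
hyperreflexia	hyperreflexia	C9000025	brisk reflexes
photophobia	photophobia	C9000026
insomnia	insomnia	C9000027
leg_weakness	leg weakness	C9000028
memory_loss	memory loss	C9000029	forgetfulness
sensory_loss	sensory loss	C9000030
blurred_vision	blurred vision	C9000031
gait_instability	gait instability	C9000032	unsteady gait
facial_droop	facial droop	C9000033	facial weakness
hearing_loss	hearing loss	C9000034
neck_stiffness	neck stiffness	C9000035	stiff neck
arm_pain	arm pain	C9000036
back_pain	back pain	C9000037
muscle_cramps	muscle cramps	C9000038
foot_drop	foot drop	C9000039
hand_numbness	hand numbness	C9000040
word_finding_difficulty	word-finding difficulty	C9000041
visual_blurring	visual blurring	C9000042
urinary_urgency	urinary urgency	C9000043
low_back_pain	low back pain	C9000044
loss_of_balance	loss of balance	C9000045
decreased_visual_acuity	decreased visual acuity	C9000046
impaired_color_vision	impaired color vision	C9000047
reduced_grip_strength	reduced grip strength	C9000048
difficulty_swallowing_solids	difficulty swallowing solids	C9000049
gait_with_festination	gait with festination	C9000050
poor_tandem_gait	poor tandem gait	C9000051
rapd	relative afferent pupil defect	C9000052
decreased_range_of_motion	decreased range of motion	C9000053
loss_of_pinprick_sensation	loss of pinprick sensation	C9000054
difficulty_rising_from_chair	difficulty rising from chair	C9000055
impaired_rapid_alternating_movements	impaired rapid alternating movements	C9000056
tingling_in_both_feet	tingling in both feet	C9000057
pain_radiating_down_the_leg	pain radiating down the leg	C9000058
difficulty_walking_up_the_stairs	difficulty walking up the stairs	C9000059
inability_to_stand_without_assistance	inability to stand without assistance	C9000060
numbness_spreading_over_the_face	numbness spreading over the face	C9000061
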