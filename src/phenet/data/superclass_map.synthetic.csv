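term_id,superclass
leg_weakness,weakness
arm_weakness,weakness
hand_weakness,weakness
facial_weakness,weakness
hemiparesis,weakness
paraparesis,weakness
quadriparesis,weakness
monoparesis,weakness
foot_drop,weakness
proximal_weakness,weakness
distal_weakness,weakness
grip_weakness,weakness
hip_flexor_weakness,weakness
neck_flexor_weakness,weakness
generalized_weakness,weakness
fatigable_weakness,weakness
paresthesias,sensory
numbness,sensory
leg_numbness,sensory
arm_numbness,sensory
facial_numbness,sensory
hypoesthesia,sensory
dysesthesia,sensory
allodynia,sensory
impaired_vibration_sense,sensory
impaired_proprioception,sensory
impaired_pinprick_sensation,sensory
impaired_light_touch,sensory
lhermitte_sign,sensory
sensory_level,sensory
hemisensory_loss,sensory
band_like_sensation,sensory
brisk_reflexes,hyperreflexia
brisk_knee_jerks,hyperreflexia
brisk_ankle_jerks,hyperreflexia
brisk_biceps_reflex,hyperreflexia
brisk_triceps_reflex,hyperreflexia
brisk_brachioradialis_reflex,hyperreflexia
babinski_sign,hyperreflexia
extensor_plantar_response,hyperreflexia
hoffmann_sign,hyperreflexia
ankle_clonus,hyperreflexia
patellar_clonus,hyperreflexia
sustained_clonus,hyperreflexia
crossed_adductor_reflex,hyperreflexia
reflex_spread,hyperreflexia
brisk_jaw_jerk,hyperreflexia
hyperactive_reflexes,hyperreflexia
impaired_balance,incoordination
limb_ataxia,incoordination
truncal_ataxia,incoordination
appendicular_ataxia,incoordination
dysmetria,incoordination
dysdiadochokinesia,incoordination
impaired_finger_to_nose,incoordination
impaired_heel_to_shin,incoordination
impaired_rapid_alternating_movements,incoordination
clumsiness,incoordination
past_pointing,incoordination
rebound_phenomenon,incoordination
impaired_fine_motor_control,incoordination
poor_coordination,incoordination
impaired_tandem_stance,incoordination
ataxia,incoordination
gait_impairment,gait
spastic_gait,gait
ataxic_gait,gait
unsteady_gait,gait
impaired_tandem_gait,gait
wide_based_gait,gait
falls,gait
difficulty_walking,gait
shuffling_gait,gait
hemiparetic_gait,gait
foot_dragging,gait
reduced_walking_distance,gait
walking_aid_use,gait
gait_slowing,gait
limping,gait
fatigue,fatigue
exhaustion,fatigue
tiredness,fatigue
low_energy,fatigue
fatigability,fatigue
daytime_sleepiness,fatigue
mental_fatigue,fatigue
post_exertional_fatigue,fatigue
lassitude,fatigue
malaise,fatigue
reduced_stamina,fatigue
heat_induced_fatigue,fatigue
afternoon_fatigue,fatigue
chronic_fatigue,fatigue
easy_fatigability,fatigue
pain,pain
headache,pain
back_pain,pain
neck_pain,pain
limb_pain,pain
neuropathic_pain,pain
trigeminal_neuralgia,pain
facial_pain,pain
burning_pain,pain
migraine,pain
eye_pain,pain
shooting_pain,pain
muscle_pain,pain
joint_pain,pain
chronic_pain,pain
memory_impairment,cognitive
poor_concentration,cognitive
cognitive_impairment,cognitive
brain_fog,cognitive
slowed_processing_speed,cognitive
word_finding_difficulty,cognitive
impaired_attention,cognitive
forgetfulness,cognitive
executive_dysfunction,cognitive
impaired_short_term_memory,cognitive
confusion,cognitive
disorientation,cognitive
impaired_judgment,cognitive
impaired_recall,cognitive
difficulty_multitasking,cognitive
depression,behavior
anxiety,behavior
irritability,behavior
emotional_lability,behavior
apathy,behavior
mood_swings,behavior
pseudobulbar_affect,behavior
euphoria,behavior
agitation,behavior
insomnia,behavior
sleep_disturbance,behavior
panic_attacks,behavior
low_mood,behavior
social_withdrawal,behavior
behavioral_change,behavior
facial_palsy,cranial nerve
facial_droop,cranial nerve
hearing_loss,cranial nerve
tinnitus,cranial nerve
vertigo,cranial nerve
dizziness,cranial nerve
impaired_taste,cranial nerve
impaired_smell,cranial nerve
hyperacusis,cranial nerve
decreased_gag_reflex,cranial nerve
tongue_deviation,cranial nerve
facial_myokymia,cranial nerve
hemifacial_spasm,cranial nerve
absent_corneal_reflex,cranial nerve
dysphagia,cranial nerve
diplopia,eye movement
nystagmus,eye movement
internuclear_ophthalmoplegia,eye movement
sixth_nerve_palsy,eye movement
third_nerve_palsy,eye movement
gaze_palsy,eye movement
impaired_smooth_pursuit,eye movement
saccadic_dysmetria,eye movement
oscillopsia,eye movement
impaired_convergence,eye movement
ocular_misalignment,eye movement
gaze_evoked_nystagmus,eye movement
strabismus,eye movement
impaired_upgaze,eye movement
slow_saccades,eye movement
blurred_vision,vision
visual_loss,vision
optic_neuritis,vision
decreased_visual_acuity,vision
visual_field_defect,vision
scotoma,vision
impaired_color_vision,vision
red_desaturation,vision
afferent_pupillary_defect,vision
optic_disc_pallor,vision
monocular_visual_loss,vision
photopsia,vision
uhthoff_phenomenon,vision
dim_vision,vision
photophobia,vision
dysarthria,speech
slurred_speech,speech
scanning_speech,speech
slow_speech,speech
stuttering,speech
hypophonia,speech
aphasia,speech
dysphonia,speech
hoarseness,speech
impaired_articulation,speech
halting_speech,speech
spastic_dysarthria,speech
ataxic_dysarthria,speech
speech_difficulty,speech
word_slurring,speech
urinary_urgency,sphincter
urinary_frequency,sphincter
urinary_incontinence,sphincter
urinary_retention,sphincter
urinary_hesitancy,sphincter
nocturia,sphincter
bowel_incontinence,sphincter
constipation,sphincter
fecal_urgency,sphincter
incomplete_bladder_emptying,sphincter
neurogenic_bladder,sphincter
bladder_spasms,sphincter
urge_incontinence,sphincter
bowel_urgency,sphincter
double_voiding,sphincter
tremor,tremor
intention_tremor,tremor
postural_tremor,tremor
resting_tremor,tremor
hand_tremor,tremor
head_tremor,tremor
action_tremor,tremor
voice_tremor,tremor
leg_tremor,tremor
rubral_tremor,tremor
kinetic_tremor,tremor
titubation,tremor
fine_tremor,tremor
coarse_tremor,tremor
bilateral_hand_tremor,tremor
spasticity,hypertonia
leg_spasticity,hypertonia
arm_spasticity,hypertonia
muscle_stiffness,hypertonia
increased_muscle_tone,hypertonia
muscle_spasms,hypertonia
flexor_spasms,hypertonia
extensor_spasms,hypertonia
leg_stiffness,hypertonia
nocturnal_spasms,hypertonia
painful_spasms,hypertonia
muscle_cramps,hypertonia
clasp_knife_phenomenon,hypertonia
spastic_catch,hypertonia
hypertonia,hypertonia
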