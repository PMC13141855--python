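# Trigger vocabulary: raw curation label -> [category, subtype].
# category: kinesigenic | exercise_induced | non_kinesigenic
# subtype applies only to non_kinesigenic; use "none" otherwise.
# Lookup is case-insensitive on the stripped label. Labels not listed here
# fall back to non_kinesigenic/other with a logged warning.
kinesigenic: [kinesigenic, none]
sudden movement: [kinesigenic, none]
abrupt movement: [kinesigenic, none]
movement initiation: [kinesigenic, none]
standing up: [kinesigenic, none]
startle movement: [kinesigenic, none]
exercise: [exercise_induced, none]
exertion: [exercise_induced, none]
physical activity: [exercise_induced, none]
sport: [exercise_induced, none]
alcohol: [non_kinesigenic, alcohol]
ethanol: [non_kinesigenic, alcohol]
tobacco: [non_kinesigenic, tobacco]
smoking: [non_kinesigenic, tobacco]
nicotine: [non_kinesigenic, tobacco]
sleep deprivation: [non_kinesigenic, sleep_deprivation]
lack of sleep: [non_kinesigenic, sleep_deprivation]
fever: [non_kinesigenic, physiological_stress]
illness: [non_kinesigenic, physiological_stress]
infection: [non_kinesigenic, physiological_stress]
intercurrent illness: [non_kinesigenic, physiological_stress]
physiological stress: [non_kinesigenic, physiological_stress]
fatigue: [non_kinesigenic, fatigue]
tiredness: [non_kinesigenic, fatigue]
fasting: [non_kinesigenic, fasting]
hunger: [non_kinesigenic, fasting]
caffeine: [non_kinesigenic, caffeine]
coffee: [non_kinesigenic, caffeine]
startle: [non_kinesigenic, startle]
sudden noise: [non_kinesigenic, startle]
fright: [non_kinesigenic, startle]
heat: [non_kinesigenic, heat]
hot weather: [non_kinesigenic, heat]
hot bath: [non_kinesigenic, heat]
anxiety: [non_kinesigenic, anxiety]
nervousness: [non_kinesigenic, anxiety]
menstruation: [non_kinesigenic, menstruation]
menses: [non_kinesigenic, menstruation]
menstrual period: [non_kinesigenic, menstruation]
excitement: [non_kinesigenic, excitement]
emotional stress: [non_kinesigenic, emotional_stress]
emotion: [non_kinesigenic, emotional_stress]
stress: [non_kinesigenic, emotional_stress]
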