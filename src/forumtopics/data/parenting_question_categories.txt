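Parenting and behaviour
Child development and learning
Growth, nutrition and physical activity
Sleeping or night-time waking
Screen time and media exposure
Preventing childhood infections and other diseases
Mental health
Poverty and access to care
Oral health, vision, and hearing
Safety and injury prevention
Environmental toxins
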