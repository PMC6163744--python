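term,polarity,subjectivity,role,factor
gracias,0.8,0.9,term,
feliz,0.9,1.0,term,
alegría,0.8,0.9,term,
esperanza,0.6,0.7,term,
apoyo,0.5,0.6,term,
maravilloso,0.9,0.9,term,
mejor,0.5,0.6,term,
bueno,0.7,0.6,term,
bonito,0.7,0.8,term,
ánimo,0.6,0.8,term,
triste,-0.7,0.9,term,
dolor,-0.6,0.7,term,
miedo,-0.6,0.8,term,
crisis,-0.6,0.6,term,
difícil,-0.5,0.7,term,
peor,-0.6,0.7,term,
terrible,-0.9,0.9,term,
malo,-0.7,0.6,term,
preocupada,-0.5,0.8,term,
cansada,-0.4,0.7,term,
happy,0.8,1.0,term,
dear,0.6,0.8,term,
good,0.7,0.6,term,
great,0.8,0.8,term,
interesting,0.5,0.5,term,
thanks,0.8,0.9,term,
wonderful,0.9,0.9,term,
hope,0.5,0.6,term,
love,0.7,0.8,term,
sad,-0.7,0.9,term,
dreadful,-0.9,0.9,term,
crises,-0.6,0.6,term,
pain,-0.6,0.7,term,
awful,-0.8,0.9,term,
bad,-0.7,0.6,term,
worst,-0.9,0.8,term,
afraid,-0.6,0.8,term,
no,,,negator,
not,,,negator,
never,,,negator,
nunca,,,negator,
ni,,,negator,
muy,,,intensifier,1.5
tan,,,intensifier,1.3
very,,,intensifier,1.5
so,,,intensifier,1.3
really,,,intensifier,1.5
extremely,,,intensifier,2.0
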