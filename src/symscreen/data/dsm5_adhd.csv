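id,text,domain,source
IN1,Often fails to give close attention to details or makes careless mistakes,inattention,DSM-5
IN2,Often has difficulty in sustaining attention in tasks or play activities,inattention,DSM-5
IN3,Often does not seems to listen when spoken to directly,inattention,DSM-5
IN4,Often does not follow through on instructions and fails to finish tasks,inattention,DSM-5
IN5,Often has difficulty organizing tasks and activities,inattention,DSM-5
IN6,Often avoid of is reluctant to engage in tasks that required sustain mental effort,inattention,DSM-5
IN7,Often loses things necessary for tasks and activities,inattention,DSM-5
IN8,Is often easily distracted by extraneous stimuli,inattention,DSM-5
IN9,Is often forgetful in daily activities,inattention,DSM-5
HY1,Often fidgets with or taps hands or feet or squirms in seat,hyperactivity_impulsivity,DSM-5
HY2,Often leaves seat in situations when remaining seated is excepted,hyperactivity_impulsivity,DSM-5
HY3,Often runs about or climb in inappropriate situations,hyperactivity_impulsivity,DSM-5
HY4,Often unable to play or engage in leisure activities quietly,hyperactivity_impulsivity,DSM-5
HY5,"Is often “on the go” acting as if “driven by a motor”",hyperactivity_impulsivity,DSM-5
HY6,Often talks excessively,hyperactivity_impulsivity,DSM-5
HY7,Often blurts out answers before a question has been completed,hyperactivity_impulsivity,DSM-5
HY8,Often has difficulty waiting their turn,hyperactivity_impulsivity,DSM-5
HY9,Often interrupts or intrudes on other,hyperactivity_impulsivity,DSM-5
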