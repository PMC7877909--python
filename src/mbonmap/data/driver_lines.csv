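line_id,mbon_composition,neurotransmitter,excluded,exclusion_reason,previously_published,provenance
MB002B,betaP2mp:4;gamma5betaP2a:2,glutamatergic,False,none,True,transcribed
MB011B,gamma5betaP2a:4;betaP2mp:3;betaP2mp_bilateral:3,glutamatergic,False,none,True,transcribed
MB018B,alphaP2:4,cholinergic,False,none,True,transcribed
MB026B,alphaP1:3;alphaP3ap:2,cholinergic,False,none,True,transcribed
MB027B,alphaP3ap:5;alphaP3m:5,cholinergic,False,none,True,transcribed
MB050B,alphaP1:2;alpha2sc:4,cholinergic,False,none,True,transcribed
MB051B,alphaP2:1;gamma2alphaP1:4,cholinergic,False,none,True,transcribed
MB051C,alphaP2:1;gamma2alphaP1:3,cholinergic,False,none,True,transcribed
MB057B,betaP1:3,GABAergic,False,none,True,transcribed
MB074C,betaP2mp:4;beta2betaP2a:3;gamma5betaP2a:1,glutamatergic,False,none,True,transcribed
MB077B,gamma2alphaP1:4,cholinergic,False,none,True,transcribed
MB077C,gamma2alphaP1:3,cholinergic,False,none,True,transcribed
MB080C,alpha2sc:2,cholinergic,False,none,True,transcribed
MB082C,alphaP2:3;alpha3:5,cholinergic,False,none,True,transcribed
MB083C,gamma3:5;gamma3betaP1:5,GABAergic,False,none,True,transcribed
MB093C,alphaP2:4,cholinergic,False,none,True,transcribed
MB110C,gamma3:5;gamma3betaP1:5,GABAergic,False,none,True,transcribed
MB210B,gamma5betaP2a:1;betaP2mp:4;beta2betaP2a:3,glutamatergic,False,none,True,transcribed
MB298B,gamma4>gamma1gamma2:4,glutamatergic,False,none,True,transcribed
MB310C,alpha1:5,glutamatergic,False,none,True,transcribed
MB399B,beta2betaP2a:2,glutamatergic,False,none,True,transcribed
MB433B,beta1>alpha:3;gamma4>gamma1gamma2:4,glutamatergic,False,none,True,transcribed
MB434B,beta1>alpha:4;gamma4>gamma1gamma2:4,glutamatergic,False,none,True,transcribed
MB542B,alphaP1:1;alphaP3m:2;alpha2p3p:2,cholinergic,False,none,True,transcribed
MB549C,alphaP1:2;alphaP3m:2,cholinergic,False,none,True,inferred
MB112C,gamma1pedc>alpha/beta:3,GABAergic,True,weak_signal,True,inferred
G0239,alpha3:3,cholinergic,True,weak_signal,True,inferred
MB242A,calyx:3,mixed/unknown,True,noisy_signal,True,inferred
SS01308,gamma5betaP2a:3,glutamatergic,False,none,False,inferred
SS01143,betaP2mp:3,glutamatergic,False,none,False,inferred
SS01194,alpha2sc:3,cholinergic,False,none,False,inferred
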