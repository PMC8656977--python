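model,term,estimate,stars
m1,Z1,-0.0185,***
m1,Z2,0.0308,
m1,Z3,2.7140,***
m1,Z4,-5.3141,
m1,Z5,-0.0135,***
m1,Z6,-0.0026,**
m1,const,0.4995,***
m1,n_obs,195,
m1,n_groups,39,
m1,obs_per_group,5,
m1,wald_chi2,157.78,
m1,log_likelihood,13.4347,
m2,Z1,0.0184,***
m2,Z2,0.0332,
m2,Z3,2.9427,***
m2,Z5,-0.0135,***
m2,Z6,-0.0025,*
m2,const,0.3959,***
m2,n_obs,195,
m2,n_groups,39,
m2,obs_per_group,5,
m2,wald_chi2,153.72,
m2,log_likelihood,12.3064,
m3,Z1,-0.0215,***
m3,Z3,2.6519,***
m3,D1,-0.0097,
m3,D2,-0.1155,**
m3,D3,-0.0495,
m3,Z5,-0.0164,***
m3,Z7,-0.0215,
m3,const,0.6067,***
m3,n_obs,195,
m3,n_groups,39,
m3,obs_per_group,5,
m3,wald_chi2,163.97,
m3,log_likelihood,15.1307,
m4,Z1,-0.0218,***
m4,Z2,0.0369,
m4,Z3,2.5945,***
m4,D1,-0.0353,
m4,D2,-0.1231,***
m4,D3,-0.05844,
m4,Z5,-0.0167,***
m4,Z7,-0.0225,
m4,const,0.6372,***
m4,n_obs,195,
m4,n_groups,39,
m4,obs_per_group,5,
m4,wald_chi2,165.12,
m4,log_likelihood,15.4441,
m5,Z1,-0.0219,***
m5,Z2,0.0336,
m5,Z3,2.4396,***
m5,Z4,-4.0363,
m5,D1,-0.0312,
m5,D2,-0.1154,**
m5,D3,-0.0577,
m5,Z5,-0.0168,***
m5,Z7,-0.02316,*
m5,const,0.7129,***
m5,n_obs,195,
m5,n_groups,39,
m5,obs_per_group,5,
m5,wald_chi2,167.55,
m5,log_likelihood,16.0987,
m6,Z1,-0.0185,***
m6,Z2,0.0346,
m6,Z3,2.4384,***
m6,Z4,-4.1911,
m6,D1,-0.0298,
m6,D2,-0.1141,**
m6,D3,-0.0596,
m6,Z5,-0.0135,***
m6,Z6,-0.0025,**
m6,const,0.5857,***
m6,n_obs,195,
m6,n_groups,39,
m6,obs_per_group,5,
m6,wald_chi2,169.50,
m6,log_likelihood,16.6212,
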