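population,abundance,sd,dropout,CD3,CD4,CD7,CD8,CD11b,CD11c,CD13,CD14,CD15,CD16,CD19,CD20,CD33,CD34,CD38,CD45,CD45RA,CD56,CD61,CD62L,CD64,CD71,CD90,CD117,CD123,CD184,HLA-DR
HSC,0.015,0.25,0.01,0.1,0.1,0.1,0.1,0.1,0.1,1.0,0.1,0.1,0.1,0.1,0.1,0.8,3.0,0.2,2.0,0.3,0.1,0.1,0.1,0.1,0.8,2.2,1.6,0.6,0.8,1.6
EP,0.05,0.5,0.05,0.1,0.1,0.1,0.1,0.1,0.1,1.6,0.1,0.1,0.1,0.1,0.1,1.6,2.8,2.6,2.2,0.8,0.1,0.1,0.1,0.1,1.8,0.8,1.9,1.4,0.7,2.0
MaturingMyeloid,0.25,0.35,0.05,0.1,0.1,0.1,0.1,3.0,0.1,2.6,0.1,2.8,1.8,0.1,0.1,2.4,0.1,1.4,3.0,0.1,0.1,0.1,0.1,1.6,0.6,0.1,0.1,0.1,0.1,0.6
Monocyte,0.12,0.35,0.05,0.1,1.2,0.1,0.1,2.8,2.6,2.2,3.5,0.1,0.1,0.1,0.1,3.0,0.1,1.8,3.2,0.1,0.1,0.1,0.1,2.4,0.1,0.1,0.1,0.1,1.0,2.8
Dendritic,0.025,0.35,0.05,0.1,1.0,0.1,0.1,0.1,3.0,0.1,0.1,0.1,0.1,0.1,0.1,1.2,0.1,1.6,2.8,0.1,0.1,0.1,0.1,0.1,0.1,0.1,0.1,2.6,0.1,3.5
NK,0.08,0.35,0.05,0.1,0.1,2.6,1.0,0.1,0.1,0.1,0.1,0.1,2.8,0.1,0.1,0.1,0.1,1.8,3.5,0.1,3.2,0.1,1.2,0.1,0.1,0.1,0.1,0.1,0.1,0.1
CD4T,0.19,0.35,0.05,3.8,3.2,3.0,0.1,0.1,0.1,0.1,0.1,0.1,0.1,0.1,0.1,0.1,0.1,1.0,4.0,1.8,0.1,0.1,2.2,0.1,0.1,0.1,0.1,0.1,1.4,0.1
CD8T,0.15,0.35,0.05,3.8,0.1,3.0,3.2,0.1,0.1,0.1,0.1,0.1,0.1,0.1,0.1,0.1,0.1,1.0,4.0,2.2,0.1,0.1,1.8,0.1,0.1,0.1,0.1,0.1,1.2,0.1
B,0.12,0.35,0.05,0.1,0.1,0.1,0.1,0.1,0.1,0.1,0.1,0.1,0.1,3.4,3.2,0.1,0.1,1.2,3.6,0.1,0.1,0.1,1.4,0.1,0.1,0.1,0.1,0.1,1.6,3.0
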