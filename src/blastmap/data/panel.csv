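marker_name,channel_id,category
CD3,Er170Di,lineage
CD4,Nd145Di,lineage
CD7,Yb176Di,lineage
CD8,Nd146Di,lineage
CD11b,Sm149Di,lineage
CD11c,Tb159Di,lineage
CD13,Er167Di,blast_id
CD14,Gd160Di,lineage
CD15,Dy164Di,lineage
CD16,Nd148Di,lineage
CD19,Nd142Di,lineage
CD20,Sm147Di,lineage
CD33,Nd150Di,blast_id
CD34,Nd143Di,blast_id
CD38,Er168Di,blast_id
CD45,Sm154Di,blast_id
CD45RA,Eu153Di,other
CD56,Yb172Di,lineage
CD61,Gd155Di,other
CD62L,Dy161Di,other
CD64,Eu151Di,lineage
CD71,Dy162Di,other
CD90,Yb173Di,other
CD117,Yb171Di,blast_id
CD123,Gd158Di,blast_id
CD184,Pr141Di,blast_id
HLA-DR,Yb174Di,blast_id
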