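construct,line_id,line_type,mitral_tufted,osn,olfactory_pathway
Tbx5.0gV,Tbx5.0gV_F01,founder,True,False,True
Tbx5.0gV,Tbx5.0gV_F02,founder,True,False,True
Tbx5.0gV,Tbx5.0gV_F03,founder,True,False,True
Tbx5.0gV,Tbx5.0gV_F04,founder,True,False,True
Tbx5.0gV,Tbx5.0gV_F05,founder,True,False,True
Tbx5.0gV,Tbx5.0gV_L06,line,True,False,True
Tbx5.0gV,Tbx5.0gV_L07,line,True,False,True
Tbx5.0gV,Tbx5.0gV_L08,line,True,False,True
Tbx5.0gV,Tbx5.0gV_L09,line,True,False,True
Tbx5.0gV,Tbx5.0gV_L10,line,True,False,True
Tbx5.0gV,Tbx5.0gV_L11,line,True,False,True
Tbx5.0gV,Tbx5.0gV_L12,line,True,False,True
Tbx5.0gV,Tbx5.0gV_L13,line,True,False,True
Tbx5.0gV,Tbx5.0gV_L14,line,True,False,True
Tbx5.0gV,Tbx5.0gV_L15,line,True,False,True
Tbx5.0gV,Tbx5.0gV_L16,line,False,False,False
Tbx5.0gV,Tbx5.0gV_L17,line,False,False,False
Tbx2.6gV,Tbx2.6gV_F01,founder,False,True,True
Tbx2.6gV,Tbx2.6gV_F02,founder,False,True,True
Tbx2.6gV,Tbx2.6gV_F03,founder,False,True,True
Tbx2.6gV,Tbx2.6gV_F04,founder,False,True,True
Tbx2.6gV,Tbx2.6gV_L05,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L06,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L07,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L08,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L09,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L10,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L11,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L12,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L13,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L14,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L15,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L16,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L17,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L18,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L19,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L20,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L21,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L22,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L23,line,False,True,True
Tbx2.6gV,Tbx2.6gV_L24,line,False,False,True
Tbx2.6gV,Tbx2.6gV_L25,line,True,False,True
Tbx2.6gV,Tbx2.6gV_L26,line,True,False,True
Tbx2.6gV,Tbx2.6gV_L27,line,False,False,True
Tbx2.6gV,Tbx2.6gV_L28,line,False,False,False
Tbx2.6gV,Tbx2.6gV_L29,line,False,False,False
Tbx2.6gV,Tbx2.6gV_L30,line,False,False,False
Tbx2.6gV,Tbx2.6gV_L31,line,False,False,False
Tbx2.6gV,Tbx2.6gV_L32,line,False,False,False
Tbx2.6gV,Tbx2.6gV_L33,line,False,False,False
Tbx2.6gV,Tbx2.6gV_L34,line,False,False,False
Tbx2.6gV,Tbx2.6gV_L35,line,False,False,False
Tbx2.6gV,Tbx2.6gV_L36,line,False,False,False
Tbx2.6gV,Tbx2.6gV_L37,line,False,False,False
Tbx2.6gV,Tbx2.6gV_L38,line,False,False,False
Tbx2.6gV,Tbx2.6gV_L39,line,False,False,False
Tbx2.6gV,Tbx2.6gV_L40,line,False,False,False
Tbx2.6gV,Tbx2.6gV_L41,line,False,False,False
Tbx2.6gV,Tbx2.6gV_L42,line,False,False,False
Tbx2.6gV,Tbx2.6gV_L43,line,False,False,False
Tbx1.0gV,Tbx1.0gV_L01,line,False,False,False
Tbx1.0gV,Tbx1.0gV_L02,line,False,False,False
Tbx1.0gV,Tbx1.0gV_L03,line,False,False,False
MCE-gV,MCE-gV_F01,founder,True,False,True
MCE-gV,MCE-gV_F02,founder,False,False,False
MCE-gV,MCE-gV_F03,founder,False,False,False
MCE-gV,MCE-gV_L04,line,True,False,True
MCE-gV,MCE-gV_L05,line,True,False,True
MCE-gV,MCE-gV_L06,line,True,False,True
MCE-gV,MCE-gV_L07,line,False,False,False
MCE-gV,MCE-gV_L08,line,False,False,False
MCE-gV,MCE-gV_L09,line,False,False,False
MCE-gV,MCE-gV_L10,line,False,False,False
Tbx-spH,Tbx-spH_L01,line,True,False,True
Tbx-spH,Tbx-spH_L02,line,False,False,False
Tbx-spH,Tbx-spH_L03,line,False,False,False
Tbx-spH,Tbx-spH_L04,line,False,False,False
Tbx-spH,Tbx-spH_L05,line,False,False,False
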