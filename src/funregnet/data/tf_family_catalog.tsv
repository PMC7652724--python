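# Eukaryotic transcription-factor DNA-binding-domain family catalog.
# Two columns: family <TAB> accession (PFAM PFxxxxx or InterPro IPRxxxxxx).
# The family order in this file fixes the canonical order used for
# multi-domain combination labels. Editable: add or remove rows to tune
# the classification to a clade of interest.
family	accession
Zn2Cys6	PF00172
Zn2Cys6	IPR001138
C2H2_ZF	PF00096
C2H2_ZF	IPR013087
Homeodomain	PF00046
Homeodomain	IPR001356
bZIP	PF00170
bZIP	PF07716
bZIP	IPR004827
GATA	PF00320
GATA	IPR000679
bHLH	PF00010
bHLH	IPR011598
Myb	PF00249
Myb	IPR001005
Forkhead	PF00250
Forkhead	IPR001766
HSF	PF00447
HSF	IPR000232
APSES	PF02292
APSES	IPR003163
Copper_fist	PF00649
Copper_fist	IPR001083
CBF_NFY	PF00808
CBF_NFY	IPR003958
Sox_HMG	PF00505
Sox_HMG	IPR009071
MADS_box	PF00319
MADS_box	IPR002100
RRM	PF00076
RRM	IPR000504
CCCH_ZF	PF00642
CCCH_ZF	IPR000571
AT_hook	PF02178
AT_hook	IPR017956
BED_ZF	PF02892
BED_ZF	IPR003656
STE	PF02200
STE	IPR003120
NFX	PF01422
NFX	IPR000967
TEA	PF01285
TEA	IPR000818
GCM	PF03615
Ndt80_PhoG	PF05224
Ndt80_PhoG	IPR024061
SART1	PF03343
Zn_clus_fungal	PF04082
ARID	PF01388
ARID	IPR001606
CP2	PF04516
E2F	PF02319
GCR1_C	PF12550
HTH_APSES	IPR036887
MH1	PF03165
NDT80	IPR013722
P53	PF00870
RFX	PF02257
RFX	IPR003150
Runt	PF00853
STAT	PF02864
TBP	PF00352
TBP	IPR000814
TCP	PF03634
T_box	PF00907
WRKY	PF03106
YABBY	PF04690
Zn2C2H2_jaz	PF12171
GRF_ZF	PF06839
DM_DBD	PF00751
CENPB	PF04218
CSD	PF00313
Dof	PF02701
EIN3	PF04873
ETS	PF00178
ETS	IPR000418
FAR1	PF03101
HPD	PF05044
IRF	PF00605
LOB	PF03195
NAC_NAM	PF02365
PAX	PF00292
Pou	PF00157
Rel_HTH	PF00554
SAND	PF01342
SBP	PF03110
TCR_ZF	PF10497
Whirly	PF08536
ZF_BED_2	PF12017
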