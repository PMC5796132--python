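property	group_index	group_name	residues
hydrophobicity	1	polar	RKEDQN
hydrophobicity	2	neutral	GASTPHY
hydrophobicity	3	hydrophobic	CLVIMFW
normalized_vdw_volume	1	small	GASTPDC
normalized_vdw_volume	2	medium	NVEQIL
normalized_vdw_volume	3	large	MHKFRYW
polarity	1	low	LIFWCMVY
polarity	2	medium	PATGS
polarity	3	high	HQRKNED
polarizability	1	low	GASDT
polarizability	2	medium	CPNVEQIL
polarizability	3	high	KMHFRYW
charge	1	positive	KR
charge	2	neutral	ANCQGHILMFPSTWYV
charge	3	negative	DE
secondary_structure	1	helix	EALMQKRH
secondary_structure	2	strand	VIYCWFT
secondary_structure	3	coil	GNPSD
solvent_accessibility	1	buried	ALFCGIVW
solvent_accessibility	2	exposed	RKQEND
solvent_accessibility	3	intermediate	MSPTHY
surface_tension	1	high	GQDNAHR
surface_tension	2	medium	KTSEC
surface_tension	3	low	ILMFPWYV
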