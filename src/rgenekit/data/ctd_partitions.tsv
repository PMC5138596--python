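property	group_index	residues
hydrophobicity	1	RKEDQN
hydrophobicity	2	GASTPHY
hydrophobicity	3	CLVIMFW
normalized_vdw_volume	1	GASTPDC
normalized_vdw_volume	2	NVEQIL
normalized_vdw_volume	3	MHKFRYW
polarity	1	LIFWCMVY
polarity	2	PATGS
polarity	3	HQRKNED
polarizability	1	GASDT
polarizability	2	CPNVEQIL
polarizability	3	KMHFRYW
charge	1	KR
charge	2	ANCQGHILMFPSTWYV
charge	3	DE
surface_tension	1	GQDNAHR
surface_tension	2	KTSEC
surface_tension	3	ILMFPWYV
secondary_structure	1	EALMQKRH
secondary_structure	2	VIYCWFT
secondary_structure	3	GNPSD
solvent_accessibility	1	ALFCGIVW
solvent_accessibility	2	RKQEND
solvent_accessibility	3	MPSTHY
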