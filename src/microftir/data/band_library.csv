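# Band assignment library for whole-cell FTIR spectra of bacteria, v1.
# One row per assignment; Gram-specific centers/heights in separate columns.
# An empty center means the band is absent for that Gram group. Heights and
# FWHMs are synthetic-fixture values (relative absorbance units / cm-1), not
# measured quantities; centers are second-derivative band positions.
kind,label,center_negative,center_positive,fwhm,height_negative,height_positive,component,vibration,cell_component
band,unsat_ch,3006,3006,12,0.10,0.06,lipid,=C-H stretching,polyunsaturated lipids
band,ch3_asym_str,2960,2962,14,0.30,0.30,lipid,-C-H (CH3) stretching,mainly unsaturated lipids
band,ch2_asym_str,2925,2925,14,0.45,0.30,lipid,-C-H (CH2) stretching,lipid acyl chains
band,ch3_sym_str,2875,2875,14,0.18,0.18,lipid,-C-H (CH3) stretching,lipids
band,ch2_sym_str,2853,2853,14,0.30,0.20,lipid,-C-H (CH2) stretching,lipid acyl chains
band,ester_co,1741,1743,12,0.30,0.20,ester,>C=O stretching,acyl glycerides; esters; lipids
band,ffa_co,1714,1714,12,0.12,0.12,ester,C=O stretching,esters; carboxylic acids
band,amide1_antiparallel_hi,1693,1693,10,0.30,0.30,protein,-C=O stretching,antiparallel pleated sheets of amide I
band,amide1_antiparallel_lo,1680,1680,10,0.35,0.35,protein,-C=O stretching,antiparallel pleated sheets of amide I
band,amide1_alpha,1656,1656,6,0.90,1.00,protein,-C=O stretching,amide I of alpha-helical structures
band,amide1_beta,1636,1640,6,0.75,0.80,protein,-C=O stretching,amide I of beta-pleated sheet structures
band,coo_asym,1570,1570,12,0.25,0.25,protein,COO- asymmetric stretching,aspartate; glutamate
band,amide2,1548,1548,12,0.65,0.70,protein,CONH bending,amide II
band,aromatic_ring,1513,1513,12,0.15,0.15,protein,benzene ring stretch,aromatic amino acids (Phe; Tyr; Trp)
band,ch2_def,1466,,12,0.35,,mixed,CH2 deformation,membrane lipids; phospholipids
band,ch3_def,,1453,12,,0.35,mixed,CH3 deformation,lipids
band,coo_sym,1400,1400,12,0.35,0.45,mixed,C=O symmetric stretching of COO-,amino acids; fatty acyl chains
band,amide3,1311,1311,12,0.20,0.20,mixed,C-N stretching,amide III
band,phosphodiester_asym,1240,1243,12,0.30,0.40,mixed,P=O asymmetric stretching of PO2-,phosphodiesters; phospholipids; (lipo)teichoic acids; nucleic acids
band,phosphodiester_asym_lo,1222,1220,12,0.20,0.25,mixed,P=O asymmetric stretching of PO2-,phosphodiesters; nucleic acids
band,carb_co_1170,1170,1170,10,0.30,0.22,polysaccharide,C-O / C-C str.; C-O-H / C-O-C def.,carbohydrates; glycogen; nucleic acids
band,carb_co_1155,1155,1155,10,0.22,0.30,polysaccharide,C-O / C-C str.; C-O-H / C-O-C def.,carbohydrates; glycogen; nucleic acids
band,carb_co_1119,1119,1119,12,0.18,0.18,polysaccharide,C-O / C-C str.; C-O-H / C-O-C def.,carbohydrates; glycogen; nucleic acids
band,glycogen_po2_sym,1082,1082,12,0.50,0.50,polysaccharide,C-O stretching of glycogen; PO2- symmetric stretching,phosphodiesters; phospholipids; nucleic acids; teichoic acids; glycogen
band,phosphate_ester,1059,1058,12,0.35,0.35,polysaccharide,PO2 str. and C-O-H str.,phosphate esters; oligosaccharides
band,carb_co_1037,1037,1030,12,0.40,0.40,polysaccharide,C-O / C-C str.; C-O-H / C-O-C def.,carbohydrates
annotation,glycogen_o_str,1045-1025,1045-1025,,,,polysaccharide,O stretching,glycogen (range entry; no single center)
band,ribose_skeleton,993,993,12,0.20,0.20,polysaccharide,C-O ribose / C-C stretching,ribose skeleton; ribosomes; sugars
band,carb_co_964,964,964,12,0.25,0.25,polysaccharide,C-O / C-C str.; C-O-H / C-O-C def.,carbohydrates; nucleic acids
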