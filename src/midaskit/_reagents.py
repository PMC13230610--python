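"""Published reagent-table oligo sequences (verbatim, case as printed:
lowercase template-matching bases, UPPERCASE payload bases).

The one known typo in the printed table (the D108W forward primer is one
template base short of its 19 siblings) is preserved here verbatim and
regularized in :mod:`midaskit.fixtures`.
"""

PRINTED_PRIMERS: dict[str, str] = {
    'MIDAS-CMV-F': 'ggccagatatacgcgttgacattg',
    'MIDAS-BGH-R': 'ctttccgcctcagaagccatagag',
    'NanoLuc-D108-R': 'gatcatgttcggcgtaacc',
    'NanoLuc-D108A-F': 'ggttacgccgaacatgatcGCCtatttcggacggccgtatg',
    'NanoLuc-D108C-F': 'ggttacgccgaacatgatcTGCtatttcggacggccgtatg',
    'NanoLuc-D108D-F': 'ggttacgccgaacatgatcGACtatttcggacggccgtatg',
    'NanoLuc-D108E-F': 'ggttacgccgaacatgatcGAGtatttcggacggccgtatg',
    'NanoLuc-D108F-F': 'ggttacgccgaacatgatcTTCtatttcggacggccgtatg',
    'NanoLuc-D108G-F': 'ggttacgccgaacatgatcGGGtatttcggacggccgtatg',
    'NanoLuc-D108H-F': 'ggttacgccgaacatgatcCACtatttcggacggccgtatg',
    'NanoLuc-D108I-F': 'ggttacgccgaacatgatcATCtatttcggacggccgtatg',
    'NanoLuc-D108K-F': 'ggttacgccgaacatgatcAAGtatttcggacggccgtatg',
    'NanoLuc-D108L-F': 'ggttacgccgaacatgatcCTGtatttcggacggccgtatg',
    'NanoLuc-D108M-F': 'ggttacgccgaacatgatcATGtatttcggacggccgtatg',
    'NanoLuc-D108N-F': 'ggttacgccgaacatgatcAACtatttcggacggccgtatg',
    'NanoLuc-D108P-F': 'ggttacgccgaacatgatcCCCtatttcggacggccgtatg',
    'NanoLuc-D108Q-F': 'ggttacgccgaacatgatcCAGtatttcggacggccgtatg',
    'NanoLuc-D108R-F': 'ggttacgccgaacatgatcAGAtatttcggacggccgtatg',
    'NanoLuc-D108S-F': 'ggttacgccgaacatgatcTCCtatttcggacggccgtatg',
    'NanoLuc-D108T-F': 'ggttacgccgaacatgatcACCtatttcggacggccgtatg',
    'NanoLuc-D108V-F': 'ggttacgccgaacatgatcGTGtatttcggacggccgtatg',
    'NanoLuc-D108W-F': 'ggttacgccgaacatgatcTGGatttcggacggccgtatg',
    'NanoLuc-D108Y-F': 'ggttacgccgaacatgatcTACtatttcggacggccgtatg',
    'ACh NeuBI-L560-R': 'tttttgcaggcctgggtaacc',
    'ACh NeuBI-L560A-F': 'ggttacccaggcctgcaaaaaGCCtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560C-F': 'ggttacccaggcctgcaaaaaTGCtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560D-F': 'ggttacccaggcctgcaaaaaGACtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560E-F': 'ggttacccaggcctgcaaaaaGAGtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560F-F': 'ggttacccaggcctgcaaaaaTTCtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560G-F': 'ggttacccaggcctgcaaaaaGGGtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560H-F': 'ggttacccaggcctgcaaaaaCACtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560I-F': 'ggttacccaggcctgcaaaaaATCtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560K-F': 'ggttacccaggcctgcaaaaaAAGtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560L-F': 'ggttacccaggcctgcaaaaaCTGtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560M-F': 'ggttacccaggcctgcaaaaaATGtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560N-F': 'ggttacccaggcctgcaaaaaAACtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560P-F': 'ggttacccaggcctgcaaaaaCCCtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560Q-F': 'ggttacccaggcctgcaaaaaCAGtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560R-F': 'ggttacccaggcctgcaaaaaAGAtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560S-F': 'ggttacccaggcctgcaaaaaTCCtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560T-F': 'ggttacccaggcctgcaaaaaACCtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560V-F': 'ggttacccaggcctgcaaaaaGTGtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560W-F': 'ggttacccaggcctgcaaaaaTGGtacaatttcaaattcaagcacaccaaaagc',
    'ACh NeuBI-L560Y-F': 'ggttacccaggcctgcaaaaaTACtacaatttcaaattcaagcacaccaaaagc',
    'before linker1_R': 'cgggaaccccagaatatccacaag',
    'linker1_0aa_F': 'cttgtggatattctggggttcccg',
    'linker1_1aa_F': 'cttgtggatattctggggttcccgGGTGTGACCGGCTACCGGCTG',
    'linker1_2aa_F': 'cttgtggatattctggggttcccgGGTggaGTGACCGGCTACCGGCTG',
    'linker1_3aa_F': 'cttgtggatattctggggttcccgGGTggagggGTGACCGGCTACCGGCTG',
    'linker1_4aa_F': 'cttgtggatattctggggttcccgGGTggagggGGAGTGACCGGCTACCGGCTG',
    'linker1_5aa_F': 'cttgtggatattctggggttcccgGGTggagggGGAggtGTGACCGGCTACCGGCTG',
    'before linker2_R': 'GCTGTTGATGGTTACTCGGAACAG',
    'linker2_0aa_F': 'CTGTTCCGAGTAACCATCAACAGCgcgactactgatccagaaggtgc',
    'linker2_1aa_F': 'CTGTTCCGAGTAACCATCAACAGCggagcgactactgatccagaaggtgc',
    'linker2_2aa_F': 'CTGTTCCGAGTAACCATCAACAGCggaGGCgcgactactgatccagaaggtgc',
    'linker2_3aa_F': 'CTGTTCCGAGTAACCATCAACAGCggaGGCggagcgactactgatccagaaggtgc',
    'linker2_4aa_F': 'CTGTTCCGAGTAACCATCAACAGCggaGGCggaggtgcgactactgatccagaaggtgc',
    'linker2_5aa_F': 'CTGTTCCGAGTAACCATCAACAGCggaGGCggaggtggagcgactactgatccagaaggtgc',
    'linker1_(1)A_F': 'cttgtggatattctggggttcccgGCTGTGACCGGCTACCGGCTG',
    'linker1_(2)R_F': 'cttgtggatattctggggttcccgCGTGTGACCGGCTACCGGCTG',
    'linker1_(3)N_F': 'cttgtggatattctggggttcccgAACGTGACCGGCTACCGGCTG',
    'linker1_(4)D_F': 'cttgtggatattctggggttcccgGACGTGACCGGCTACCGGCTG',
    'linker1_(5)C_F': 'cttgtggatattctggggttcccgTGCGTGACCGGCTACCGGCTG',
    'linker1_(6)E_F': 'cttgtggatattctggggttcccgGAAGTGACCGGCTACCGGCTG',
    'linker1_(7)Q_F': 'cttgtggatattctggggttcccgCAAGTGACCGGCTACCGGCTG',
    'linker1_(8)H_F': 'cttgtggatattctggggttcccgCATGTGACCGGCTACCGGCTG',
    'linker1_(9)I_F': 'cttgtggatattctggggttcccgATCGTGACCGGCTACCGGCTG',
    'linker1_(10)L_F': 'cttgtggatattctggggttcccgCTCGTGACCGGCTACCGGCTG',
    'linker1_(11)K_F': 'cttgtggatattctggggttcccgAAAGTGACCGGCTACCGGCTG',
    'linker1_(12)M_F': 'cttgtggatattctggggttcccgATGGTGACCGGCTACCGGCTG',
    'linker1_(13)F_F': 'cttgtggatattctggggttcccgTTCGTGACCGGCTACCGGCTG',
    'linker1_(14)P_F': 'cttgtggatattctggggttcccgCCTGTGACCGGCTACCGGCTG',
    'linker1_(15)S_F': 'cttgtggatattctggggttcccgTCCGTGACCGGCTACCGGCTG',
    'linker1_(16)T_F': 'cttgtggatattctggggttcccgACCGTGACCGGCTACCGGCTG',
    'linker1_(17)W_F': 'cttgtggatattctggggttcccgTGGGTGACCGGCTACCGGCTG',
    'linker1_(18)Y_F': 'cttgtggatattctggggttcccgTACGTGACCGGCTACCGGCTG',
    'linker1_(19)V_F': 'cttgtggatattctggggttcccgGTAGTGACCGGCTACCGGCTG',
    'after SmBiT_F': 'GGCGGAAGTGGAGGTAGCTTC',
    '(1)SmBiT(-C1)_R': 'GAAGCTACCTCCACTTCCGCCAATCTCCTCGAACAGCCGGTAG',
    '(2)SmBiT(-C2)_R': 'GAAGCTACCTCCACTTCCGCCCTCCTCGAACAGCCGGTAGC',
    '(3)SmBiT(-C3)_R': 'GAAGCTACCTCCACTTCCGCCCTCGAACAGCCGGTAGCCG',
    '(4)SmBiT(L163E)_R': 'GAAGCTACCTCCACTTCCGCCCAGAATCTCCTCGAATTCCCGGTAGCCGGTCACGAAc',
    '(5)SmBiT(F164H)_R': 'GAAGCTACCTCCACTTCCGCCCAGAATCTCCTCGTGCAGCCGGTAGCCGGTCAC',
    '(6)SmBiT(F164S)_R': 'GAAGCTACCTCCACTTCCGCCCAGAATCTCCTCGCTCAGCCGGTAGCCGGTCAC',
    '(7)SmBiT(L163E,-C3)_R': 'GAAGCTACCTCCACTTCCGCCCTCGAATTCCCGGTAGCCGGTCACGAAc',
    '(8)SmBiT(F164H,-C3)_R': 'GAAGCTACCTCCACTTCCGCCCTCGTGCAGCCGGTAGCCGGTCAC',
    '(9)SmBiT(F164S,-C3)_R': 'GAAGCTACCTCCACTTCCGCCCTCGCTCAGCCGGTAGCCGGTCAC',
    'IgK_R': 'cactgcctcgcccttgctcaccatgtcaccagtggaacctggaacc',
    'mScarlet_F': 'atggtgagcaagggcgagg',
    'mScarlet_R': 'TCCggtggagtggcggc',
    'nOpuBC_F': 'tccgagggccgccactccaccGGAGGTgggagatctgcgaacgacaccgtagc',
    'OpuBC_R': 'cactgcctcgcccttgctcaccatTCCTCCGCCgtcgacctgcagaattaaacctttctc',
    'Myc_F': 'tccgagggccgccactccaccGGAgaacaaaaactcatctcagaagaggatctg',
    'SmBiT_R': 'cactgcctcgcccttgctcaccatACCGCCAGACCCTCCCTCGAACAGCCGGTAGCCG',
    'LgBiT_F': 'tccgagggccgccactccaccGGAGGCGGAAGTGGAGGTAGCTTC',
}
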