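"""Built-in synthetic germline template sequences, one set per chain.

Each template set is structurally valid by construction: the V mature region
encodes the conserved anchors (C23, W41, L89, C104) in frame 0, the leader
exon starts with ATG and contains no internal ATG, the J segment carries a
W/F-G-x-G motif at codons 9-12 and no codon-boundary GT inside the donor
search window, and C exons are stop-free with lengths divisible by three.
These are synthetic stand-ins for curated germline references and carry no
biological sequence content.
"""
TEMPLATES = {
    "IGH": {
        "v_leader": 'ATGATAGTACCCCAGTTTAGGCGACAGGAAGCGTCACCATTGCGA',
        "v_leader_tail": 'GAAGAAACC',
        "v_mature_nt": 'GACGAACCTACTGCCTTCTTCCACATAGAACTATATAGGACTCGAGGCCCTGGCAAAAAGCAGACTTGCGTGACCACGACGTTGCGATTTACTAAACGGGACCGTCCAGACTCGACTCCGTGGGAGCTAGGTACTGATGAAGCGCAGTTCGAACATAGAGCATTTCCGACAAAACCTACTCCCGGTGTTCTATTTCAATCTACTTTTTATGAAAATGAGCATGAGCATCTCCTCGGCCTTGTTTCACCGTTGGTTCCACACGTATTAGACGTAACAAAATTTAAATCGAATACTGAGAAGTTTTCGAGCTGT',
        "v_stub": 'GAACACGAATTCTAC',
        "j_nt": 'TACACAAAGTTGATCCGTGTCCCGTGGGGACAAGGCAACGGGTACAAG',
        "c_exons": ['CAAGTCAGACAGAATCAGCATGCCAATTTTACTGGGGACAGGGAAGCTATAGATGAGGCACTAACCCTGATTGACGGCGACCTTCTGACTCCCAAA', 'GATGTAATATTTTTTGAAGGAACACGCGAAGGGGGACAAGATAAAGGTCACATTGATAGAGAGAACTACCCTGACAACTTTGACGATCAGTTCGAC', 'GCCCGGCATTATCCACGGCCAACATTGGTATTTGAAATATTCGACAAGGGTGTAAAGTATACGGTTATCAAGAACAAGGAATTTGATCCCATTCAT', 'AAACTCGTCCAAGAACAAGTGATTACTAACACGGATAACATCTACCACACCTCAGCATACAAACCCTACCATTCAAAGGAACGTATCTATGGGGCT'],
    },
    "IGK": {
        "v_leader": 'ATGATACATAGGCGCCAGAATTACGACCTTTCACTCACCAATACC',
        "v_leader_tail": 'CGGTCCGAC',
        "v_mature_nt": 'TTTTTTGTGTTAGCTTTCACTAGATTCACTCATTACAACGAAAAGCATTCGGGTAATCCTGGTGGATGCGGGCAAAAGGTGGGCCCCAGCGCTGACCAGGAACCAGTTGCGGCGGAAGGTTGGATCCGGGTGAAAAATGAGTTCCTCGACCATGATGAACGTCAGCATACTCAGACTGGGGTAATCAAACATGTGAAAGGCAGAAGCCGCCGCACTCGATCGCGTCGCTCACCCATCTACACGGAGTTACAGGATGCAAAAACGTTATCCTCCAATATCCCAGAAAAGCAGGCAAACATTGCGTCTAAATGC',
        "v_stub": 'TCTAAGACCAACTAT',
        "j_nt": 'TCAGAACCGTATAAACAATCGTTCTTTGGCCAAGGAGATCCGCCAAAT',
        "c_exons": ['AAGAACCCGCAAATAAGGTTTGGGCGGCTGGGGAATCTCTACCCACCCAAAATTAATGGGTATTCTGATGCAGGACATCTTTTGAATCAGAAAAAA', 'AAAGATGGCCACGTTATACACAATGCGCATGCTAAAGATATATCCGTGTCCCCAGCATTATTTTTTGCCATTTTCGCAGAGGCGTTCTACCACCGG', 'TTAGGGCAGGTGATAACCTATAAATCCCCGTTTGAATACAGACATATCCAGGGCAATATACCTACGCCACAGGCTAGAGCTGGGTCCGAACACCGA', 'CAGGGACCACGTCGCGCGTTGACAGACTTTAGTCGGCCGAAGACCGAACGCCTAGTCATCTATAACCACGAGCATTCACCGGTCATCCCGGTCGCC'],
    },
    "IGL": {
        "v_leader": 'ATGCCTAAAGACCGTACTGTTTCTTCATTCAACGGGCTTCCGTTT',
        "v_leader_tail": 'CCAGATAAA',
        "v_mature_nt": 'CCTCCATACTCGTCGGAAGGGCACGTAAACGATAAGTCGGGCTCCGAAATTCAAGGATTCAGCGAATGCTACAAAGGACGAGAATTCCACCATGAGAGCTTCATCGTGACAAATTCGATCTGGTTCAATCACCAACAACTCGGGTTTCAAAGTTCGCAACCCCCAGTAACCTTTCATGATCTGGACCGCGGTCAAGCCAACGAACGTAGAGTACATATAAGCACCCATGATAATAGTACAGGCAGGCATTTTGACTTCCATATCTTGCTGCAGGCACAAGAATCAGTATACGTGAAGGATACTCAAGATTGC',
        "v_stub": 'GCGCACCTAACCGCT',
        "j_nt": 'ATCAAGGAGCTACTTAACAAGTCGTTTGGTCAAGGCTTAGCGGACCAA',
        "c_exons": ['GCTAAGCTTAAGCGTAGAGTCGTCATCTTGGGTGGTGCAACCCAAACATCCCCGCAATTGGAAGCAACTATAGTCGCTGGGTTTGATCCGGTGAGT', 'CATACTATAGGAGACAAGGAATTCAACGAGCCAAAGGACCACGAATATCTTTATATCTCGCCGTATGCCTTTCACCAAAGACAAGCGCGGTACGAT', 'GATAAACAAACTTTCAAAGAAACCGTGCCGACCCAGCAATTTGTTTTCCTCTACGGGTCTTTCCACAACCACCGTAGTTTCGTAGACCTGACAAAG', 'ACGGCATATCAGCAGCAGAGGGGAAAAATTAACTTTACAATTGCTGATTTTGTCTTAAGCGTTTTCTACTTTCCTTTTTATCAGGCTGTAGGTCGT'],
    },
}
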