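>Proteinase-1_ePST source_peptide=Proteinase-1
CTGCTGACCAGGCTACTGTTTGTATGCACAATCTTGACCTTCTCGACAATTCCACTGGTG
CTCCACAAGGGGATCTCACCGATCCAAGAGAAGATGGGTAGG
>Proteinase-2_ePST source_peptide=Proteinase-2
ATGATCCGGACGAGGTTCCTAGTTCGAAGAGAGGGCCTTCTCGATGTGGTCTCTCCCGGT
GAACTCTTCTCCGGAGAACACGGGGTAATCACCCCCGGGACTGAACGATATAGACTCATG
CCATGTTCCATGTCCTCTATTTGAT
>Proteinase-3_ePST source_peptide=Proteinase-3
GTGATTCTTCGTCTTTCCGAGCCCCGTATCGTCGCACCCATTAGCCGCTTCGGTGAGTGG
ACCTTGTGTCGCAGACATCTTCAAGACAAGCGATTGGTTCAGATGGTGGAATTGGAATGA
ATATTCGCGTATATTCACCAGTGTCTTTTAAT
>Proteinase-4_ePST source_peptide=Proteinase-4
TTGATGTTTTTGTTCCCGTCTCTATATCTTTATTCAGAGTCTGAACCAGTGACACTTAGA
TTGTTATCATATGATTTAAACCATGATAGGTCACCATCTGTAAATTCCTCATGGTTCATG
ATCCCGTGCTTGGCACATATCATTATCAGAAGGATGGCCTTCATCGACAGCTCCACTCTC
TGGTGGTCTCTGTCACTCACCGGCGTGCCCGGGGTCGCGTATTCCACCGCCGTGTCTCTG
TTCAAGACGGCGAGTTGGCCTCTGGGGATATCGGCCGCCGTGACGGTCAGGGAGTTGATG
AGAGAACTGGTCTCCATGTCAGTGTTTAGTCTCTGGAAGATTTCCTCAGCGGACATCTCG
GGTCCCGCTGCTAATGCGAGCCTCAGGGTTTCACGGGTAATCGATAGATGCACCCGCTTG
TGGCTATGCCGGGCGGCCGGCCTCTTTCCTCGTACACGCGGGGTTGGTTTGGGTTCGGCC
ACGTGCGCGCCCCGGCGTTCCAGTAACGTAACCGGACGCCTCGAGGGGACCCGCGCGGGC
TCGGGATCGGCCCCGATACCACCGGCCGGGACACCGATCAGTTCCAGTGGCCCGCCCGCA
GACGGTGGGTCTTCGTCCTCGCTCTCTTCGCTCTCCTCCTCGCTCTCCTCCTCCTCGCCT
CCACTCTCCGTCTCGCCCCCTTGTCTATCCTCCTCGTCCTCCTCTCGGCACACTCCATCT
CCGCGGGTGCCGTTCGAGTCCGGCACCGGATCGACACTCTCATCGTCACCCGATTCCTCA
CTGCTGAGCTCACGACCACCGGCGTACGATCCGTGGTAGT
>Proteinase-5_ePST source_peptide=Proteinase-5
TTGATGACGTCCCAGTTCGCCAGGTCGGGTCTCACCATCGAGAGAAACGACATCGCAGAA
TCCAGCTGTCTGGTCGCGACCATCGACTCCATGGCCTCGGCGAGACTCGTTCCTTGAT
>Proteinase-6_ePST source_peptide=Proteinase-6
ATGCTGACACACACCACCCCGAACAAGGCTGTACGTATCAGGTGCATCAAACCCAGGATA
CTCGCGGGGGGTGTTCCGGGTGTAGCTCTCACTACATACCGAAATTTTCCGAGGTCGGAG
AGGTCGCTGCAGCTGTTGTGCTTGGTGCCGGATTGTGTGGCCCCCTTACCGGTACTGTTG
ACAGTCAGCGTTCCGAACTCGGTGAATTCGGTACTGTTGTACACAGACCACAGGCAGTTG
ACAGGGAAGACCTTCCCGGGTTCTCTCTTTTCGGGTATCTCTAGGGATTCAATCCCAATC
TTGTTCAACCACTCGATGAAGGTGGTGGGTCCCTGTTGGTTGTAGA
>Proteinase-7_ePST source_peptide=Proteinase-7
CTGTGCGTCAGTTGCTGTAACTTGACATCCGGGTTATCGGTTGGTTTCACCGATAGATCG
ACCGTGAACGGACCCGGGGGTAAATCGGCGGGCGCGACCTGCAGGGCCGCTCCGCAAGCG
GTCGTCCCCATGAATACGTTCGAGCATATCACCGCCACATGTGCGTCCTCGAGGTAGT
>Proteinase-8_ePST source_peptide=Proteinase-8
ATGTAGATGACCATGTCCAACTTGAGAGGTCCAATGTCTACCCCCCGTGGGTCGTGGTAC
AGAATGTGTGTGTTGTACATGTTCGTTATGAAGTTGATTCCATTGTCTCGGAACGCGACG
GCGAGCGAGATGAGTTGTTTCAGGATCACGGCCCCCAGGAGGGTTCCATCGTCCGTCTCG
CCATCGAAGTTCAGCTCGGTGATGGACCTCTTGGCGGGGGTCACGTAGATCATATACCTT
TTCGTGCCATGGGCGCCCAGGGTGTAGTGGAACACCGGTACCACATATGGGATAGATTTT
TGGATCGCCTGGATCCCCTCCATCAAAGACTGTATCGCCTCGAAATCAATGGTCGGTTTC
AGCTCGAGGTAGACGATGTCATACGTAGGGGAGAATTCGGGGGGCCTGTATACCCTGATC
TCCTTCACGCCGTACTCTTTGGTGGCCACGACCGGGTACACGGAGACGAGGTCCCGGGGG
GTGAGGGTTATCAGTTTCTTCGCGGTGTGATCATCGCCCATGTCTGCGCGCGCAAGCCAT
GGCATGTATAGC
>Proteinase-9_ePST source_peptide=Proteinase-9
CTGTGAACAAATATATCTTCGAAGTTTGCCGCGAGGGTACCGACGAGGTCCCGCACGCGA
TCTACCAAGACGGTTTCCAGGACGTGTCTCACGACTGGAAGGGCCGGGCCCGGCCATATC
ACCACGATCGAACCCGGGTCGAGCGCGCACTCGATAGA
>Proteinase-10_ePST source_peptide=Proteinase-10
ATGCGTACACCGCATACGCCTTCAGCACTGCACTGTCACGGCTCAGGTCCCATTTACGAC
GTGCGGGGTAAGGCCTGTCTCCCTTCAGAAATTGCGTGAGCTCGTAGTATTCGCTCAGCA
CCCTCTGTCCCAGGAACTGGCGTATCCGAGGACAACCACCCCTCGAATGGTACACGTGTT
CGTCCAGGAAATCATCGACGAGCGTGAAGCGGATGACCTTGACACCGCAGTCTGGACACA
CGTGACGATCGCTCTTCACATCGTCCGGGATCAAACCTCCCTTGGGTCCGAAGTACAGTC
TCGTCATGAACACGAGGTTGTCATCCTGCAAGGTACCGTGGGCGACTATTGTATCGTAAT
CCAAGGTAACATCGCAAAACCACACACCTCCGTCCGCACGCCATCCGCTTGGCTTGAGCA
TTCCCCTGGGTGCCGCGGACCATCTGAACCCCCTGTCCGTGGGGTTGCTGACCCGCTCAC
CGTCTGTCACCAGGGAACCGCATTCGAAATCCATCGCCTCAGTAGTGGATTGTCAGAGAT
CGTTCTATGGGTATCTGGTCAGTGTGAATTATTGGAATGGGCGCTCGCAGTATTCTTCAA
TCGTTCTTTTTCGGGCACCATGAGACTCTCGGGATCGAGGAAGCCGCCGGCGGTCCACCG
GATGCGACACGTGAGATCCGATAACCTATAAA
>Trypsine-1_ePST source_peptide=Trypsine-1
CTGACAGCCACGGAATCATCGGGGGTGTACACAACTTCCGAATCCACGGAGTCCATCACC
GCGGTGGCGATCCCGACCATCGCACGGAGTTCGGCCTCGGTCCCGATCTTCTCAAGGAAA
AAACCAAGGTGTTCCGGGTATACCTTTAGAATTCCCTTCGTTTCCGGGTTGATGAACGCG
CAGATCATCTTGTTCTCGGGTCCTTGTATGATAGGCAGGAACGCGGCCGTCTCGTGCAAG
CTATCGAAACGATCCATATCATGGGCACCGCCGATGAGATCCATCCCGATGTTCTTGCGG
AGTGCATCCATTTCGCTCACAAGAAGATAAA
>Trypsine-2_ePST source_peptide=Trypsine-2
GTAGAGGAGGGCCCGAACCGTCTTCCTAAATGTGAGACCGGGGTGGTCTCGGAAGGACGA
CGCGTCAGTCGGGCAACCCGCCATCGTACCGGCCAAGAGGGACTTGACACAGGTGCGGAT
CATTCCCACCTTGTATCCGATCTGGATCGCCCCCTGTGTGACCTGGTTGGTCAGGCTCAT
GATCTGTTGGTACCACTGCTGGTACGCCATCACTTCCCCGAGGCGCTCGTTGGTCGTCGT
ACCCAGCTCCTTCAGGCCAGTAGCTAAACGCTTGAAGTTTGTATCCATGGCCAGCATCTG
GAGGTTTATCTGGTTTTGTAGGTCGTCCACCCTCCCGTTCACTGCCCTGATGTTGCGGTC
TAACTTGGCCGATATCAGGGCGATACTGTCTCCCAGTTCCGTGATCACATCCGCGGTCTT
GTCCAATTGTGCCTGTAAACCGTCTATTTTGGAGGCTGCCAATGTGGCGACCGCCAGTGC
TGCCGTCGACGCGACGAGTGCCGCGCTGGACATGGTTATCGCGGCCACCGATAACCCGAA
TTTATCGCTCGTGGGCACCGATCCGCCCGAGGCGGGCGCGAACATCTTAACCTTTTCGTG
TTCGAGGTCCAGGTCAACGAGGCTATTTTTCAATAGTTCGTTACTCCGCTGGAAGTCCAG
GAGTATCGCCGCCGTCTGAT
>Trypsine-3_ePST source_peptide=Trypsine-3
CTGTGAAGCCGGCCGTGAGGGACAAGCGCAACGAACATGTGCCTACCCCAGCGCTGGTTT
ACTTCAAGCATCACAAGGCCGAGCTGGCCAAGGCGCTGGTTGAG
>Trypsine-4_ePST source_peptide=Trypsine-4
CTGCGTAAGACGGAGGAGACCGTGCTCGCGGACGAGCGGTTCCGGGGCCTGCTCGGGCCG
GAGATGGTGGCACGGCTATTGAA
>Trypsine-5_ePST source_peptide=Trypsine-5
TTGGGTATCAGCTTCCGTCCGCCCCCGGAGCCGCACTCGGGACACTCCCGGGGGGTGCAG
AAGAAACAGAACACGTGTTTACACGATGCCCGGTTGGAGGGAAACACGGCCTCCCCCTGG
CAGAAACAACACGGAAAGACTGGAGACATGAT
>Trypsine-6_ePST source_peptide=Trypsine-6
CTGGAAAGGCTGAAAAGTCCACCGGGACTGCGAAAGTGAC
>Trypsine-7_ePST source_peptide=Trypsine-7
CTGGAAACAGAACTTCTCGAGGCCATCCGAGACGGTGTCGCGGGTGAAGAGTTTCGCGTG
GCAGCCCCTCCGCGCGGGAATGACCACGACGCTGCACTCCAGTATCACCTCGTTGAGGCC
CACATCGAGGGTTCCGAGGCTCAGTGCACATGGTATGTCCGCTTCCGTGAACGTCTCCAC
GCATCTCTTGCCGGTGTCCTCGGACTCATCTATCCCTCCTATCATGTTCAGGTAGACTCG
GTCTTCCATGTGGACATGCCAGTAACCGAGGACCTTGCCCATGGGGATCTGGTGCGAGTA
CTTGAGCGTGCCCGGAGCGACCTGTACCATTGTTTGGTGGGCCTCGATCGGCTGCTGGTA
CTTGCGCATGTGCGCGGGGATGGAGGGGTCGTCGACCGGGTCGCCCGGGGAGAAGATGCA
ACATGTCCCAACGACAAAGGTTCCGAACCCCGTGAGTGGAACCTCGTATAGC
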