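>NH_synthetic synthetic specificity stand-in for Neoporphyra haitanensis, seed=0
GAAATTGTGTTATATATGACAAGGGCTTGGGCATGCCTTCGCGCCTAGATTATACACTAA
CCTTCCAGACCTAACTGATGAACCAAGAGATCAGTCTCCGTTCTCGTCTTTATTTATTTA
TTTCATTAGCTATGATATGTATACCTGAATAAAGGTGACTGTCGGCTCATATTGGGAATT
ATGGGGATACTATCTACAGATTATACCCTTCATTGCTCATTGTTTTAAGTACTGGAGGAT
GATTGCAGGTGCATGGCCGTTCTTAGTGAGGTACTACATACTCTTTAAATGCAGCTCGTA
GATCTATTCTGGTATCCTGCTAAATAGGTGCGCGCACTTCCTATTTCTACCGACATTATT
TTCTTGTTCTTATGACACCCGATGTTGATGTGTTCA
>NT_synthetic synthetic specificity stand-in for Neopyropia tenera, seed=0
CTCGATAATGCTAGCAGCCTAGAATTGAGATTGGAAGCTTAGGACTTCATGCAAAGATAC
CTACTTGAAAGCGAAACAGATATACATGTACGCAATATTCCTGTTGTTATACCATAACTA
TAGTTTGTTTTGCGATAGGGTAGCGGGTGCAAGGATGGTCCAATTGCGGTCATTAAGTGA
AGTAAGAATTCAACGGCGGGCGGCCGGGCGGTTCTTCAGTTTGGTGGTGGTCTATTAACA
TTTGGTGATCTGAAGAACTGCTCTTTAAACGATTCGGTAATGTCCCAGAGGTGCATGGCC
GTTCTTAGTTAGGGTAAAAGATACCACAATCCGGGAGTTGAACTCTCTCTCTAATGGGCT
GCTAAATAGGTGCGCGCAGAGAACCACGCTAATGCAGTAGCTTATAAATGCATAATCTGT
ACCCCTATTAAACTATCA
>NY_synthetic synthetic specificity stand-in for Neopyropia yezoensis, seed=0
CCAACTCTAAAGAGTCATCAATTTGAACTGATCTCTATCCATAGGTCTGTTTTTAAGACA
GCTGTTAAAGCTCTTCGCTTGTTAGCTCTGTCTCATAGGAATTATAATTTATCCTTCATT
ATATTAAGCTGAGAAACATAACTCCATCAGTCACCTTGAGTACCGGACTACCCTCTGCAT
GAAATCTTAAATAGATCGACATTTCTAGTCTAGCGAAGCATTGTCTTTAAGCTTGCTTGT
GGGTCTGACAGCCTGAAAGGCGGTCTTGATTTACGTTGTCTTGACATGTACGCCGACACG
AATTCTATGCGAAAGTGTAATCGGGATAGCCGGTGCATGGCCGTTCTTAGTGCATGTGTG
AGATGTGAGTTCGTGCTTTAATAAGTGCGAGTACACATCCCTGCTAAATAGGTGCGCGCA
GTAAAAAAGAATAATGTGATCCAAGGGGTGCACGTCAAACGGGCAAGCATCTATATAATC
>ND_synthetic synthetic specificity stand-in for Neoporphyra dentata, seed=0
TTTCTCATTATGTAATGACTCCCTCTCTATAAATCCAGAATAAGAATCTTAAACCTCGCT
GAGCAAATTAATAAGCAGCTTACTTACGGTCATCGTTTAGATTAATGTTGGATCAGCGAA
GGAGTAGTTATCTCTTTTCTAAGTAACTATCGTAGATTATACACCGCGGTAAAGTGGACC
CTAACGATGCTCGGACGTTCAAAGCGGCCATAAAATACATCTTTACTGTGGCAGATAGGA
GTGGTATCGATGCGAATAAGTTTTCGTAACCAGCTCGGACCAAAAAAACAAATAAGGCTT
CCGAACGAATCGAGACGACCTGCTAACGAGCCAGACGACTTCCTAATTTCATTTATCGTA
TAACTTTTCCGGTGTCTTATTTTACGTAGTATGTGGTGCATGGCCGTTCTTAGTTTATTT
GCGATTCTTCTCCATAAGTATATAATGAACCGGACATCGAAAACTGCTAAATAGGTGCGC
GCAGTAATGTCCATACGTTATTCGCACTGAGGTGATATGTTCAGAAAGTACCTGCTGGTG
CTG
>PS_synthetic synthetic specificity stand-in for Pyropia suborbiculata, seed=0
CAATTAAGAGACCATCTATAATATAGTACGGCATATAATTGAAATCTTCTGGCCCACCAA
CAGGTGCAACTGCTAATAAAGTGCTCTAAATTCTTCGTTAGTGCTCGATTTTCTCAACTC
AAGAGACACGGATTAAACAAGAATAATTCTCGACATATGCAGCTAAAACTTGTGGACTTT
TCATGATCTTGTCATGACACCCGATAAGGCTAATCGTCTACAAGGCACATGTGACTGGGT
GCATGGCCGTTCTTAGTATTTGTCCTATACTACGCTAGCAATCCTTGAATCTCTGAGTAA
CCTGGTCTGCTAAATAGGTGCGCGCACGATCCAATGATGTTCACCGACATAGATAATAAG
AGACCAAGATCATAGACCATGATACA
>NS_synthetic synthetic specificity stand-in for Neoporphyra seriata, seed=0
CCTGCAACAAGACATTAGCTAATACACCGGTTTACCAAACCTGTAATCGACATGATCGAC
CTGGTAAAAATTATGGAAGAGTGGTGCCTCCACCAAAGACAAAATATTTTATTCCAATAT
ATACGAAATTATTTCAGTGAGATGCAAGGGAGAGGCATAAGGAAATACACTTCATGTAAC
CGGGGCAGATTATACATGACTATAAGTCCACAGCATTTATCTATATTTATGAAATCTTAA
ACGTAACGGCCGCGACAGCCACAGCAACATAGTTCCACGCACAGCTAGACTCCTTCACAT
GGATAGCATCGAATAGGTGCATGGCCGTTCTTAGTAGATAACTAACCCATTCTTATCGAG
AGCTAGAATGATCACCGCGTTGCTCTGCTAAATAGGTGCGCGCATAATGAGAACGTTCTA
GATCAAAAGCGGACGTTCGTATCTATTGACGCTGATCAGTACTC
>Porphyra_koreana_synthetic synthetic specificity stand-in for Porphyra koreana, seed=0
CGTGATCTGATTGAAAGACTGCACAGCCCCCCTGACAGTTAGCCCGAAGACTATCATGAT
GGTGCATGGCCGTTCTTAGTCGCATTAGATACTAGAGTGTGCAGTCTGGATACCCCTTAA
CTGGCTAGTCTGCTAAATAGGTGCGCGCACCCCGAAGAACGTATTGACATATGCAGCAAC
AATTTTATAGATTGCCTTTGACTACTATA
>Neopyropia_katadae_synthetic synthetic specificity stand-in for Neopyropia katadae, seed=0
CATTGTCTTTATTCCAACCTTCATAGGCAGTATGTGAAAACCTCCATCTGGATGGTAGTT
GGTGCATGGCCGTTCTTAGTTGAGTACAATGGTAGTTTTCCAGTCTTTCTGTATCAATAT
CTCGCCGTACTGCTAAATAGGTGCGCGCAAAAATTGTAACTATCTGATATGGAATAAAAT
GTTAATGTTTTCGAAGACACTAATGCGAC
>Pyropia_kuniedae_synthetic synthetic specificity stand-in for Pyropia kuniedae, seed=0
AACACGTACAATCTACCGGCATCAGATGGACGTCTCACTACTACCCGGCACAGTACTTTT
GGTGCATGGCCGTTCTTAGTACTTCGGTGTTTCGGAGCAGTGTCTAGATTATCTTCTTTA
TCAAATGAGCTGCTAAATAGGTGCGCGCAAGCTCTCCAGTAGGTCGAGTAGATGGCCATA
GGAAAACCATAACACACGAAACGCATAGA
>Pyropia_ishigecola_synthetic synthetic specificity stand-in for Pyropia ishigecola, seed=0
AGAGGGTCTGTCGTGGAATACCTAACTAGTCTCTAAGCGGACTAGTATACACTATCCATA
GGTGCATGGCCGTTCTTAGTTGCGTTAAACAAATCGGTGTGACAAGTTCCACCTACTGCT
TTTGCATATCTGCTAAATAGGTGCGCGCAGCCATGTGTAGTCACATTTCTCCCTCGTTGG
TCCTATTTAGTATTGGTCCCGTCCAGAGT
>Undaria_pinnatifida_synthetic synthetic specificity stand-in for Undaria pinnatifida, seed=0
CATCCTTCTAAGCGTCTATTAGTCCTTCTTAGTTCAATCTGACTTCTAGATGCTACCTAG
GGTGCATGGCCGTTCTTAGTAGCTTTCACAAGAAGTATCGGGGAGTATATCATTGCTACC
ACCAATAATCTGCTAAATAGGTGCGCGCATCAGCTATAACATACATGAAGCCGTCAGGAT
GGCCATAACTGATAATTTACACATATGGT
>Costaria_costata_synthetic synthetic specificity stand-in for Costaria costata, seed=0
GTACGATCGTTTACTCCAGAATAGACTTTAATCTCGACCACCATGCGCCAGAAGAATTGA
GGTGCATGGCCGTTCTTAGTGTAAATTTCTGCCATTAGAAAGCTGTTACCCATATCGGGA
CCTGCAAATCTGCTAAATAGGTGCGCGCAAGTATATTTCAGGTACACAACTGGTGCGATC
TCGCAGTAATCGGGTCGATGCAGACGCGT
>Undaria_crenata_synthetic synthetic specificity stand-in for Undaria crenata, seed=0
ACATGTGCGCCGCTTCGCATAGTGAAGATCGGCCTATACGTGCTCATGACAGATGTATAA
GGTGCATGGCCGTTCTTAGTGGCGACGTTTTCCACGGTACCTGTACATTCGATTATGGGG
GAACACAATCTGCTAAATAGGTGCGCGCAAGCTTACCGCGTCGTTTTTAGAAATGGACTC
ACAATTAGCTCTTTAATTTACCCAATTAA
>Saccharina_japonica_synthetic synthetic specificity stand-in for Saccharina japonica, seed=0
TAATTACCACATTGAGCTTGAAACTATCCTATCTTAATTAATTCTTTCTCAATACGAGAA
GGTGCATGGCCGTTCTTAGTGTCACCCTGAAAGTCCTATGTTTACGAGTGAATATTATTT
TTTTACTTTCTGCTAAATAGGTGCGCGCATGGACTATATACCCTATCATTCGGCGCCTCC
TACCATCCAAGATTAACAAACTTCCGCTT
>Saccharina_sculpera_synthetic synthetic specificity stand-in for Saccharina sculpera, seed=0
GGTGCGAAGCTAATCTATGGGATCGGTTGAGTAATTATTGTGGAAACAATAAAAACATCT
GGTGCATGGCCGTTCTTAGTTCATGATAGTAGATTACACGATAATATGCACACAACTTAT
TTCGATGCCCTGCTAAATAGGTGCGCGCACCAAATACAACAACCAAAGCGGTCGAACCGC
AACCGCTGTAACGATCTGAGTTCACGGAA
>Sargassum_fusiforme_synthetic synthetic specificity stand-in for Sargassum fusiforme, seed=0
CTATGTCTGAATCACGGAAAAGCATGGTAAGTGTCTGCGACGTATATGAGTATGGGCACT
GGTGCATGGCCGTTCTTAGTGAAGTAACTGGTAGCTTTGTAGTGGGAATATATCTATCTA
CGTGTTTGTCTGCTAAATAGGTGCGCGCATATCGAATTGACAAAGCTTATACGGATTTGA
CAAGGACGGATTTGTTCACGTAACTAAAT
>Gracilaria_vermiculophylla_synthetic synthetic specificity stand-in for Gracilaria vermiculophylla, seed=0
TAATCATACATCTGACTATTAAGATAGAAGGAATTATACTGCTGGTTCGGCAGCTTGACT
GGTGCATGGCCGTTCTTAGTCATTGGGGTCGAGTATACGTGGGCTTAAAATCTGATATAA
CGTTAAGGCCTGCTAAATAGGTGCGCGCATTCAACTATATACCTCTCCGGAATGCCTAAT
CGATTTAAACCTTTCGCCATGGGATGCCA
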