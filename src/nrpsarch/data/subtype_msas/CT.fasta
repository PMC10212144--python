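>CT_0
NCVEGEWVLFYFLHYQRMAVSFAQERLAAHCVCSQIFWTQFCGHGLFPMSVIMSPILVMY
RHELSRTCKCVHMCALEVESYVEPNPNCYFGVLVMGSENGFVGEVKQMIMHHATIDGVSD
QRKSSQPQDTIPEVYDPRIAPWWSQNQVQKTVLYWTAEKGHSNTKLCGWYLDFAVWWNEL
SQVPPASWLVEPQEIRIADRANRFIMRNQHMPWQSLQDNENSEKPRCSVKSWLSLFYWYK
IIGDFVNTLANRPIMYGRYVCGWKRSYNWHDTVDDSLNKFPDSFSKVEIELRETIFPHQD
VPFEAQWFDKGSRSAKCFDTPASQLVRQRNHDWTWYETTVIQFLLSPQGRGAFQWKAIAP
METRRDLSRNPLENRTACCIGDPALKGKPRACAFQGAHYMYITDLTFIWQRI
>CT_1
FVVEGLWVLFYFLHYQRMAVSFDQECLWGLCVCGQIFWTVFCGHELFPMSVIMMPILVMY
RHELLRTCNCGHMCSLSVESYVDPNPLCQFGVLVMGSSNGFVGEVKQMIMHHAISDGVSY
QRKSSQPPDTIPEVYDPRIAPWSSQNQVQCTVLYWTAEKGHSNTLLCGWHLDFVVWWNWL
IQVYPAQWLVEPQKIIIADRAVRFITRNQHMPEQSLQDNPDSEKPQMLMKSWLSLFYLMK
IIGDFVNTLANRPIMMGRIVCDAKRSDNWHDIVDDSTNKVPYSSSKVLIEEWCTIFPHQD
VYFEAQWFYKGSRSCKCFDTPASILVRQRNHDWTWYETDVIQFLLSPQGRGFFQWKAIAR
METRRDLSRNPLENRTKMCIGDPALKGKPRAVATQGWHYMYDTDLTFIWQRI
>CT_2
NTVEGEWVLFYFLHYQMMAVSKAQERLWRLCVCTQIFWTQFCGHDLFPMSVIMSRILVMY
RHELLTTCFCVHMCALFVETYVLPNPNCEFGVLVMGAENGFVGEVKQMIMHHAISDGVSD
QRKSSQGPDTYNEVYDPRIAPWWSQNQVKCTVLYWTAEKGHSNTLLCMWYLDFAVWHNWL
SQVYPASWLVEPQGIIIADRANRFCYRNQHVPWQSLQDNAVSEKPQCSMKSWLSLFYLMK
IIGDGVNTLGNRYIMYGRYVCDAKRSYNWHDTVDDSTNKFPYSSSKVEIELWETIFPHQD
VMFEAQWFYKGSRSAKCFDTPASRLVRQRNHDWTWYEYDVEQFLLSPQGRGFFQWKAIAY
METRRDLSRNPLENRTWCCDGDPALKGKPRAVAFQGWHYMYIPDLVFIWQRI
>CT_3
NCVEGEWVLFYFLHYQRMAVSHAQERLWALCVCSQIFWTQFCGHELFPMSVIMSPILYMY
PHELLRTCFCNHMCALSVESYVLPNPNCQFGVLVMGSENGFVGEVKQMIMHHAISDGVSD
QRKSSQPPDTIPEVYDPRIAPWVSQNQVQCTVLYPTAEKGHSNTLLCGWYLDFAVWWNWL
SQVYPASNLVEPQKIVIADDANRFIYRNQHMPWQSLQDNPDSEKPMCSMKSWLSLFYLQK
IIGDFVYTLANSPIMKGRYICDAKRSYNWHNTTDDSTNKFPYSSSKVEITLWEIIFPHQD
VPFEAQWFYKGSRSAKCEDTPAFRLVRQRNNDWTWYETDVSQWLLSPQGRGFFQWKAIAW
METRRDLSRNPLENRTKCCIGDPASKGCPRAVAFQGWHYMYITRLTFIWQRI
>CT_4
NCVAGEWVLFYFLHYQRMAVSFAQERLWALCVCSQIFWTQFCGHELFPMSVIMSPILVMY
RHELLRSCFCVHMCAWSVFSYVLPNPNCQFHTLVMGSEIGFVIEVKQMIMHHAISDGVTD
QRKSSQPPDTIPEVYDPRIAPWWSQNWVQMLCLYWTAEKGHSATLLRGWGLDFAVYWNWL
MQVYPALWLVEPQKIIIADRAERFIYRNQHMPWQSLQDNPDSEKPQVSMKSWLSLFYLMK
RIGDFWDTLANRPIMYGRYVCDAKESLNWHDLVDDSTNKFPYSSSKVEIELWETIFPHQD
VPFEAQWFYKGSRSAKCFDTPASRLVRQRVHDWTWYETDVIQFLLSPQGRGFFQWKAIAW
METRRDLSRNPLENRTKCCIVDPALKGKPRAVALQGWHYMYITDLTFIWQRI
>CT_5
NCVEGERVLFYFLHYQRMAVPFAQEREWALCVCSQIFWTQFCGHELFPMSVIMSPILVMY
RHELLRTCFCVHMCALSVESYVIPNPNCDFGVLVMGSENGFVGIVKQMIMHHAISDGVSD
QHKVSQPPDTIPEVYDPRIRPWWSQNQVQCKVLYCTAEKGHSNTLLCGWYMDFAVWWNWL
SQVYPASWLVEPQKIIIWDRANRFRYRNQHMPWQSLQDNPDSGYPQCSMMSWFSLFYLMK
IIGDSVNTLANRPIMYYRYVCFAKRSYNWMDTVDDSTNKPPYSSSKVEIELWETIFPHQD
VPFEAPMTYKGSRSAKCFDTPASRLVRQRNHDWTWYETDVIQFLLSPQGRVFFQWKAGAW
METRRDTSRNPLENRTKCCIGDPALKGKPRAVAFQGWHYMYITDLTFIRQRI
>CT_6
NCVEGEWVLFYFLHYQRIAVSFAQERLWALCVCYQIFWTQFCGHELIPMSVIYSPILVMY
RHELLRTCFGVLMCALSVESYVLPNPNCQFMVLVMGSENGFVREVKQMIMHHAISDGESD
QRKSSQPPDTIPEVYDLRIAPWWSQNRVQCTVLYWTAEKGHSNTLLCGWYRDFAVWWNWL
SQWYPASWLVEPCKIIIADRINRFIYRNQHMPWQSLQDNPDSEKPQCFMKSWLSLFYLMK
IIGDFVNTLANRPIMYGRYVCDAKRSYNWHDTVDDSTNKFPSLSSKQEIFLWETIFPHQD
VEFQAQLFYKGFRGAKIFDTPASRLVRQMNHDWTWYETDVIQFLLSPQGRGFFQWKAIAW
METPRDLSINPLENRTKCCIGDPALKGKPRAVAFQGWHYMYITDLTFIWIRI
>CT_7
NIVLGEWVLFYFLHYQRMAVSFAFERLWALCVCSQIPWKQFVGHELFPMSVIMSPIFVMD
RHELLRPCYCFHMCALSVEVYVLPNPNCQFGVLVMGSENGFVGEVKQMIMHHAISDVVSD
QRKSSQPPWTIPEVTTPRIAPRWCINQVQCTVLYWTGEKRHSNCLLCGWYLDFAVWWNWL
SQVYSASTLVEPWKIIIADRANRFIYSWQHMPWQSLQDNPDSEKPQCSMKSWLSLFYLMK
IIGDFVNTLANACIMLGRYVQDAKRSYNWHDTVDDSTNKFPYSSGKVEIELWETIFPHQD
VPFEAQQFYKGSRSAKCFRTPASRLVAQRNHDWTWYETDVIQFLLSPQGKGFFQWKAIAW
METRRDLSRNPLENRTKCCIGDPAAKGKPRAYATFGWHAMYIWDLTFIWQRI
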